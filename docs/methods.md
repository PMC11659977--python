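# Methods

## The bias model

A sequenced cfDNA fragment is characterized by its length *f* and the GC
fraction of the reference sequence across its interval. GC bias is modeled as
a multiplicative recovery factor on the joint (f, GC-bin) grid, estimated by
comparing two distributions counted over the same reference regions:

* **Expected E[f, b]** — for every sampled region and every modeled length
  *f*, every start position whose fragment lies inside the region contributes
  one count to (f, bin(GC)). This is the composition of the genome itself: the
  fragment population an unbiased library would sample uniformly. Interval GC
  is computed from per-chromosome prefix sums over G/C and N counts, so each
  (region, length) pass is a vectorized O(region length) scan.
* **Observed O[f, b]** — the sample's fragments whose midpoints fall inside
  the same regions (counted once even where regions overlap), reconstructed
  from proper pairs via TLEN or from single-end spans.

The correction weight is the ratio of the two as densities,
`w[f,b] = (E[f,b]/ΣE) / (O[f,b]/ΣO)`, so a fragment class the library
over-recovers gets weight < 1 and vice versa. Weighted data then reproduce
the expectation. Three numerical guards apply, in order:

1. **Sparse-cell backoff.** Cells with `O < min_count` cannot support a
   stable ratio. They back off to the pooled ratio of *the sparse cells of
   their GC bin*: within a bin, the supported cells already reproduce their
   share of the expectation, so correcting the pooled residual with its own
   aggregate ratio makes the corrected GC marginal match the expected
   marginal by construction. (Pooling with the whole-bin marginal instead
   leaves a systematic tail residual, because supported and sparse cells
   occupy different length shares in E and O.) If a bin's sparse pool is
   itself below `min_count`, those cells stay neutral (weight 1). A
   `fallback="neutral"` mode keeps all sparse cells at 1. Cells with E = 0
   but observed support describe fragments the reference says should not
   exist; they get the lower clip bound rather than being deleted.
2. **Clipping** to `[w_lo, w_hi]` (default 0.1–10) bounds the influence of
   any single fragment.
3. **Global rescaling.** One factor applied to the whole grid enforces
   `Σ O·w = Σ O` exactly, for any clip/backoff settings, so correction
   preserves total coverage; the mean weight over the fragments the model was
   built on is exactly 1.

Because densities are normalized by grid totals, the weights also reweight
the fragment-length marginal toward the uniform length enumeration; the
rescale step keeps this globally neutral, and within each length the GC
composition is corrected exactly. Optional locally weighted smoothing of the
log-ratio along GC within each length is available behind a flag; the raw
ratio is the default behavior.

`bias_slope` summarizes a model as the count-weighted within-length
regression slope of log pre-rescale weight on GC-bin centers. For a
log-linear acceptance bias `exp(β·gc)` this estimates −β independently of the
fragment-length law.

## Region sampling

Bias-estimation regions are drawn uniformly along the genome (chromosomes
weighted by length), redrawing regions whose N fraction exceeds 0.5.
Regions are non-overlapping by default: E counts each region separately while
O counts fragments once, so overlapping samples would weight the overlapped
sequence inconsistently between the two distributions — at the scales used
here this measurably destabilized the recovered bias slope. An `exclude`
list blacklists intervals from sampling; passing the signal regions under
study is recommended, since genuine coverage structure there (e.g., an
accessibility dip) would otherwise be absorbed into the bias estimate.

## Coordinates, fragments, filters

All coordinates are 0-based half-open; BED is native and SAM's 1-based
convention is converted at the pysam boundary. Fragment GC always comes from
the reference interval, not read bases, keeping expected and observed
commensurable. One fragment per template: proper pairs span
`[min(pos, mate pos), +|TLEN|)`; unpaired (e.g., merged) reads use their
aligned span; secondary/supplementary alignments never form fragments;
cross-chromosome and TLEN-inconsistent pairs are skipped and tallied so that
`emitted + filtered + skipped = templates` always holds. Default filters:
MAPQ ≥ 20, fragment length in [30, model f_max], duplicates dropped,
fragments with > 10% N excluded from distributions — all configurable.
Defaults for the genome-scale grid are f ∈ [70, 500], 101 GC bins,
`min_count` 50, 1000 sampled regions of 10 kb: wide enough to span the cfDNA
length spectrum with stable per-cell counts at typical whole-genome depths.

## Tagging

`tag_alignments` writes every input record back out unchanged plus a float
tag (default `GW`) carrying its fragment's weight; both mates receive the
identical value because each mate derives the fragment from
(min(pos, mate pos), |TLEN|) independently — no mate buffering is needed.
Records that form no valid fragment are tagged with weight 1 and tallied as
defaulted. Output record count always equals input record count, preserving
the original coverage and fragmentation patterns for any downstream tool.

## Composite signals

Coverage is fragment-level: a fragment covers every base of its insert,
matching the fragment basis of the weights. Each region contributes a
(2W+1)-long vector anchored at its midpoint (floor for even widths);
minus-strand regions are reversed; windows exceeding chromosome bounds are
skipped and tallied; overlapping regions contribute independently.
Normalization divides by the mean over the outer `flank_fraction` of the
window on each side (default W = 1000 bp, flank 0.25, i.e., offsets with
|offset| ≥ 750), chosen over a global mean so the normalization is anchored
in locally representative background coverage. The GC-profile table reports
expected, observed, and weighted-observed GC densities (marginalized over
length) and their log2 ratios with a 0.5-count pseudocount. Case-control
tables are long-format per-sample curves with each class's mean appended as
a `<class>::mean` pseudo-sample; with a single class the table is produced
with a notice flag, since no cross-class comparison is possible.

## The simulator

The generator emulates the data regime the method targets, not sequencing
chemistry:

* **Genome** — blocks of fixed length with per-block GC target θ drawn
  uniformly from a range; bases i.i.d. within a block. Defaults: 2 × 1.5 Mb,
  600 bp blocks, θ ∈ [0.30, 0.60]. Block length is comparable to the
  composite window so site-local GC contrast exists, and the θ range covers
  the GC span real cfDNA fragments occupy.
* **Sites** — non-overlapping intervals with a minimum spacing, optionally
  restricted to high-GC positions (`site_min_gc`), emulating high-GC
  transcription-factor binding sites. Default 400 sites of half-width 150 bp
  with a dip depth a = 0.5. The half-width must be ≥ half the maximum
  fragment length: the dip rejects fragments by *midpoint*, so narrower
  sites let fragments covering the center escape the dip and the attainable
  center coverage exceeds 1 − a.
* **Fragments** — uniform starts (chromosomes weighted by length), Gaussian
  lengths (default N(167, 35) truncated to [90, 260]: the mononucleosomal
  peak) and acceptance probability `b(gc)·d(site)` with
  `b(gc) = exp(β(gc−0.5)) / max exp(β(gc−0.5))` and `d = 1 − a` for
  midpoints inside a site. The log-linear family is the minimal monotone
  bias able to mimic both low-GC-enriched (β < 0) and high-GC-enriched
  (β > 0) libraries by sign alone. Accepted fragments are emitted as proper
  pairs (or single spanning reads in merged mode) with MAPQ 60, reference
  sequence and no errors — downstream operations use only coordinates and
  reference GC. Everything is byte-deterministic under the seed, and a
  ground-truth table records every accepted fragment.

What the simulator does **not** model: sequencing errors and quality
variation, mappability structure, duplicates, copy-number variation,
chimeric fragments, and real chromatin footprints. Passing tests therefore
demonstrate the correctness of the estimation/correction/signal machinery
under a known monotone GC bias, not performance on any particular real
library.

## Study conditions used by tests and the acceptance script

Simulation-based checks run at 200,000 fragments on the 3 Mb default genome
(≈ 11× coverage) with β ∈ {−2, 0, +2} and high-GC sites; the model grid for
this scale uses f ∈ [90, 260] (the simulated bounds), 26 GC bins,
`min_count` 20, and 400 sampled regions of 3 kb excluding the sites — sized
so typical cells near the length mode hold tens of observed counts. The
case-control check uses two classes of two samples (50,000 fragments each)
whose site dip is 0.5 (controls) versus 0.25 (cases). Hand-checkable
examples (the two-cell weight grid), exhaustive-enumeration oracles on
kilobase genomes, and exact conservation identities run alongside at small
scale. The acceptance script reruns all of the above from scratch at the
given seed and reports only quantities it just computed.

## Known limitations

* The expected grid enumerates every (position, length) pair; for
  genome-scale runs with wide length ranges this is the dominant cost
  (linear in regions × lengths), mitigated by prefix sums and sampling.
* Weights are estimated per sample, not per read group.
* Fragment GC uses the reference, so individual-specific variants shift a
  fragment's bin only through alignment, not sequence.
* Single-end data are supported only as already-merged spanning reads.
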