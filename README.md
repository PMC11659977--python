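# cfgc — fragment-length-aware GC-bias correction and coverage signals for cfDNA

Cell-free DNA (cfDNA) sequencing libraries are systematically distorted by GC
bias: fragments are over- or under-recovered as a function of their GC
content, and the distortion differs between samples. Because cfDNA
fragmentation is driven by natural degradation, libraries contain fragments
over a wide length range, so a single-length bias model is not enough. This
distortion directly corrupts the coverage signals cfDNA analysis relies on —
for example, the characteristic coverage dip at accessible transcription-factor
binding sites can be over- or under-estimated depending on the direction of a
sample's bias, which matters for anyone comparing cases against controls in
liquid-biopsy studies.

`cfgc` is a small library (plus a thin CLI) for researchers who have
coordinate-sorted cfDNA alignments and want bias-corrected coverage signals:

1. **Estimate** a per-sample bias model over the joint (fragment length *f*,
   GC bin *b*) grid. The *expected* distribution E counts every possible
   fragment of every modeled length in regions sampled along the reference;
   the *observed* distribution O counts the sample's fragments in the same
   regions. The correction weight is the ratio of the two as densities,

       w[f, b] = (E[f, b] / ΣE) / (O[f, b] / ΣO),

   clipped to configurable bounds, with sparse cells backed off to the pooled
   ratio of their GC bin, and finally rescaled by one global factor so that
   Σ O·w = Σ O exactly — correction never changes total coverage.
2. **Tag** every read with its fragment's weight as a float auxiliary tag
   (default `GW`). Coordinates, flags, sequences, and record counts are
   untouched; both mates of a pair carry the identical fragment weight.
3. **Extract** composite ("overlay") coverage signals around user-defined
   region sets (BED), raw and weight-corrected, normalized to the window
   flanks, and aggregate them across samples into case-control tables.
4. **Simulate** fully deterministic synthetic datasets — block-GC genome,
   planted accessibility dips, log-linear GC acceptance bias of either sign —
   with complete ground truth, so the whole pipeline is testable end to end.

## Worked example

```python
import cfgc

# synthetic sample with a known high-GC acceptance bias (beta = +2) and
# 60 high-GC sites carrying a 50% coverage dip
config = cfgc.SimulationConfig(n_chroms=1, chrom_length=500_000, n_sites=60,
                               dip_depth=0.5, n_fragments=30_000, beta=2.0,
                               site_min_gc=0.52, seed=1)
paths = cfgc.simulate_dataset(config, "sim")

genome = cfgc.GenomeSequence.from_fasta(paths["fasta"])
sites = cfgc.read_bed(paths["bed"])
lengths = cfgc.FragmentLengthRange(90, 260)
binning = cfgc.GCBinning(26)
regions = cfgc.sample_regions(genome, n_regions=100, region_length=3000,
                              seed=5, exclude=sites)
expected = cfgc.expected_distribution(genome, regions, lengths, binning)
observed = cfgc.observed_distribution(
    cfgc.iterate_fragments(paths["bam"], genome, min_mapq=0,
                           min_length=90, max_length=260),
    regions, lengths, binning)
model = cfgc.compute_weights(expected, observed, min_count=10)

cfgc.tag_alignments(paths["bam"], "tagged.bam", model, genome)
stream = cfgc.iterate_fragments("tagged.bam", genome, min_mapq=0,
                                min_length=1, max_length=10**6, weight_tag="GW")
sig = cfgc.normalize_composite(
    cfgc.composite_signal(stream, sites, genome.chrom_lengths, window=1000))
print(f"raw center {sig.center_value(weighted=False):.3f}, "
      f"corrected {sig.center_value(weighted=True):.3f}")
```

Output:

```
raw center 0.626, corrected 0.492
```

The simulated dip depth is 0.5, so the true flank-normalized coverage at the
site center is 0.50. The high-GC bias inflates the raw value at these
high-GC sites to 0.626 (the sites look less accessible than they are); the
corrected value lands at 0.492, within noise of the truth. A low-GC-enriched
sample shows the mirror-image distortion. The `examples/` directory contains
this and three more narrative scripts (simulation, estimation, case-control
aggregation), each printing the numbers it computes.

The same steps are available from the shell:

```bash
cfgc simulate --out-dir sim --seed 1
cfgc estimate --bam sim/fragments.bam --fasta sim/genome.fa --out model
cfgc tag --bam sim/fragments.bam --fasta sim/genome.fa --model model --out tagged.bam
cfgc signal --bam tagged.bam --fasta sim/genome.fa --bed sim/sites.bed --out composite.tsv
cfgc profile --model model --out gc_profile.tsv
cfgc report --manifest samples.tsv --out-dir report
```

Every subcommand writes a run manifest (effective parameters, seed, output
checksums) for byte-level reproducibility.

## Scope

`cfgc` deliberately covers only the bias-estimation/correction/signal core:
read merging, adapter trimming, alignment, duplicate marking, copy-number
estimation, and report rendering are jobs for the standard external tools
that usually surround this step.
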