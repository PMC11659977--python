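"""Synthetic cfDNA data with full ground truth.

The generator emulates the data regime the correction method targets:

* a genome with block-structured GC composition (blocks drawn uniformly from
  a GC range), standing in for the mosaic of isochores and regulatory regions;
* paired-end fragments with a mononucleosomal Gaussian length law;
* a monotone log-linear GC acceptance bias ``b(gc) ~ exp(beta * (gc - 0.5))``
  (``beta < 0`` enriches low-GC fragments, ``beta > 0`` high-GC ones — the two
  directions seen in real plasma libraries);
* planted "binding sites" where coverage dips by a known depth ``a``
  (fragments whose midpoint falls in a site are rejected with probability
  ``a``), mimicking transcription-factor accessibility footprints.

Every accepted fragment is recorded in a ground-truth table, so estimation,
correction, and signal extraction are all testable against known truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .errors import ConfigError
from .refio import GenomeSequence, Region, interval_gc, write_bed

_MAX_ABS_BETA = 50.0


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of genome, sites, bias, and fragment sampler.

    Defaults describe the reference study conditions used throughout the test
    suite: a 3 Mb two-chromosome genome whose 600 bp GC blocks span the GC
    range cfDNA fragments actually occupy, 400 accessibility sites with a 50%
    coverage dip, and 200,000 mononucleosomal fragments.
    """

    # genome
    n_chroms: int = 2
    chrom_length: int = 1_500_000
    gc_block_length: int = 600
    gc_block_range: tuple[float, float] = (0.30, 0.60)
    # sites; halfwidth must be >= length_max / 2 for the midpoint-based dip
    # to reach its full depth (1 - dip_depth) at the site center
    n_sites: int = 400
    site_halfwidth: int = 150
    dip_depth: float = 0.5
    min_spacing: int = 1500
    site_min_gc: float | None = None  # place sites only where interval GC >= this
    # fragments
    n_fragments: int = 200_000
    length_mean: float = 167.0
    length_sd: float = 35.0
    length_min: int = 90
    length_max: int = 260
    # bias & reads
    beta: float = 0.0
    read_length: int = 60
    paired: bool = True
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.gc_block_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError(f"gc_block_range {self.gc_block_range} outside [0, 1]")
        if not (0.0 <= self.dip_depth < 1.0):
            raise ConfigError("dip_depth must be in [0, 1)")
        if abs(self.beta) > _MAX_ABS_BETA:
            raise ConfigError(f"|beta| > {_MAX_ABS_BETA} underflows acceptance")
        if not (1 <= self.length_min <= self.length_max):
            raise ConfigError("invalid fragment length bounds")
        if self.n_chroms < 1 or self.chrom_length < self.length_max:
            raise ConfigError("genome too small for the fragment length bounds")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generation stage
    return np.random.default_rng([config.seed, stream])


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def make_genome(config: SimulationConfig) -> GenomeSequence:
    """Block-structured random genome: per block, P(G or C) = block theta.

    Within a block bases are i.i.d. with G/C and A/T split evenly, so the
    realized block GC fluctuates binomially around its target theta.
    """
    rng = _rng(config, 0)
    lo, hi = config.gc_block_range
    sequences: dict[str, str] = {}
    for ci in range(config.n_chroms):
        L = config.chrom_length
        n_blocks = -(-L // config.gc_block_length)
        thetas = rng.uniform(lo, hi, size=n_blocks)
        theta_per_base = np.repeat(thetas, config.gc_block_length)[:L]
        u = rng.random(L)
        is_gc = u < theta_per_base
        # second draw picks within {A,T} or {C,G} evenly
        pick = rng.integers(0, 2, size=L)
        codes = np.where(is_gc, 1 + pick, 3 * pick)  # C/G or A/T
        sequences[f"chr{ci + 1}"] = _BASES[codes].tobytes().decode("ascii")
    return GenomeSequence(sequences)


def make_sites(genome: GenomeSequence, config: SimulationConfig) -> list[Region]:
    """Plant non-overlapping sites with pairwise gaps >= min_spacing.

    With ``site_min_gc`` set, candidate sites are kept only when their
    interval GC reaches the threshold — emulating high-GC binding sites.
    """
    if config.n_sites == 0:
        return []
    rng = _rng(config, 1)
    width = 2 * config.site_halfwidth
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_names}
    sites: list[Region] = []
    chroms = genome.chrom_names
    weights = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    max_attempts = max(2000, config.n_sites * 500)
    attempts = 0
    while len(sites) < config.n_sites:
        attempts += 1
        if attempts > max_attempts:
            raise ConfigError(
                f"could not place {config.n_sites} sites with spacing "
                f"{config.min_spacing} (placed {len(sites)})"
            )
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        L = genome.chrom_lengths[chrom]
        if L < width:
            continue
        start = int(rng.integers(0, L - width + 1))
        end = start + width
        if any(
            start < e + config.min_spacing and end > s - config.min_spacing
            for s, e in placed[chrom]
        ):
            continue
        region = Region(chrom, start, end, name=f"site{len(sites) + 1}")
        if config.site_min_gc is not None:
            gc, _ = interval_gc(genome, region)
            if not gc >= config.site_min_gc:
                continue
        placed[chrom].append((start, end))
        sites.append(region)
    sites.sort(key=lambda r: (r.chrom, r.start))
    return [
        Region(r.chrom, r.start, r.end, name=f"site{i + 1}")
        for i, r in enumerate(sites)
    ]


def _site_membership(sites: list[Region], chrom_names: list[str]):
    """Per-chrom sorted (starts, running-max ends) for midpoint-in-site tests."""
    lookup = {}
    for chrom in chrom_names:
        pairs = sorted((r.start, r.end) for r in sites if r.chrom == chrom)
        if pairs:
            starts = np.array([p[0] for p in pairs], dtype=np.int64)
            ends = np.maximum.accumulate(np.array([p[1] for p in pairs], dtype=np.int64))
            lookup[chrom] = (starts, ends)
    return lookup


def draw_fragments(
    genome: GenomeSequence,
    sites: list[Region],
    config: SimulationConfig,
) -> pd.DataFrame:
    """Acceptance-rejection sampling of fragments; returns the ground truth.

    Candidates get a uniform start (chrom weighted by length) and a Gaussian
    length truncated to the configured bounds; acceptance probability is
    ``b(gc) * d(site)`` where ``b`` is the normalized log-linear GC bias and
    ``d = 1 - dip_depth`` when the midpoint falls inside a planted site.
    Sampling continues until exactly ``n_fragments`` are accepted.  The
    returned frame is coordinate-sorted with columns
    (chrom, start, end, length, gc, hit_site).
    """
    rng = _rng(config, 2)
    chroms = genome.chrom_names
    chrom_lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=np.int64)
    weights = chrom_lengths / chrom_lengths.sum()
    site_lookup = _site_membership(sites, chroms)
    b_norm = np.exp(abs(config.beta) * 0.5)  # max of exp(beta*(gc-0.5)) on [0,1]
    out: list[pd.DataFrame] = []
    accepted = 0
    batch = max(20_000, int(config.n_fragments * 1.5))
    while accepted < config.n_fragments:
        ci = rng.choice(len(chroms), size=batch, p=weights)
        lens = np.rint(rng.normal(config.length_mean, config.length_sd, size=batch))
        lens = np.clip(lens, config.length_min, config.length_max).astype(np.int64)
        max_start = chrom_lengths[ci] - lens
        starts = np.floor(rng.random(batch) * (max_start + 1)).astype(np.int64)
        u = rng.random(batch)
        gcs = np.empty(batch)
        hit = np.zeros(batch, dtype=bool)
        for k, chrom in enumerate(chroms):
            m = ci == k
            if not m.any():
                continue
            gp = genome.gc_prefix[chrom]
            np_ = genome.n_prefix[chrom]
            s, e = starts[m], starts[m] + lens[m]
            non_n = lens[m] - (np_[e] - np_[s])
            with np.errstate(invalid="ignore"):
                gcs[m] = np.where(non_n > 0, (gp[e] - gp[s]) / non_n, np.nan)
            lk = site_lookup.get(chrom)
            if lk is not None:
                mids = (s + e) // 2
                idx = np.searchsorted(lk[0], mids, side="right") - 1
                inside = (idx >= 0) & (mids < lk[1][np.clip(idx, 0, None)])
                hit[m] = inside
        p = np.exp(config.beta * (np.nan_to_num(gcs, nan=0.5) - 0.5)) / b_norm
        p = np.where(hit, p * (1.0 - config.dip_depth), p)
        keep = u < p
        out.append(
            pd.DataFrame(
                {
                    "chrom": np.array(chroms, dtype=object)[ci[keep]],
                    "start": starts[keep],
                    "end": starts[keep] + lens[keep],
                    "length": lens[keep],
                    "gc": gcs[keep],
                    "hit_site": hit[keep].astype(int),
                }
            )
        )
        accepted += int(keep.sum())
    frags = pd.concat(out, ignore_index=True).iloc[: config.n_fragments]
    frags = frags.sort_values(["chrom", "start", "end"], kind="stable").reset_index(
        drop=True
    )
    return frags


def write_alignments(
    genome: GenomeSequence,
    fragments: pd.DataFrame,
    bam_path: str | Path,
    config: SimulationConfig,
) -> None:
    """Emit fragments as a coordinate-sorted, indexed BAM.

    Paired mode writes proper pairs: two mates of ``read_length`` (clamped to
    the fragment length) with correct flags, MAPQ 60, and TLEN equal to the
    signed fragment length.  Merged mode writes one single-end read spanning
    the whole fragment.  Reads copy the reference sequence (no errors):
    downstream operations use coordinates and reference GC only.
    """
    bam_path = str(bam_path)
    chroms = genome.chrom_names
    tid = {c: i for i, c in enumerate(chroms)}
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": genome.chrom_lengths[c]} for c in chroms],
    }
    records: list[tuple[int, int, int, pysam.AlignedSegment]] = []
    with pysam.AlignmentFile(bam_path, "wb", header=header) as bam:
        for i, row in enumerate(fragments.itertuples(index=False)):
            chrom, start, end = row.chrom, int(row.start), int(row.end)
            flen = end - start
            name = f"frag{i:08d}"
            if config.paired:
                rl = min(config.read_length, flen)
                for mate in (0, 1):
                    a = pysam.AlignedSegment(bam.header)
                    a.query_name = name
                    a.mapping_quality = 60
                    a.reference_id = tid[chrom]
                    if mate == 0:
                        a.flag = 99  # paired, proper, mate reverse, first
                        a.reference_start = start
                        a.next_reference_start = end - rl
                        a.template_length = flen
                        seq = genome.fetch(chrom, start, start + rl)
                    else:
                        a.flag = 147  # paired, proper, reverse, second
                        a.reference_start = end - rl
                        a.next_reference_start = start
                        a.template_length = -flen
                        seq = genome.fetch(chrom, end - rl, end)
                    a.next_reference_id = tid[chrom]
                    a.query_sequence = seq
                    a.cigarstring = f"{rl}M"
                    a.query_qualities = pysam.qualitystring_to_array("I" * rl)
                    records.append((a.reference_id, a.reference_start, mate, a))
            else:
                a = pysam.AlignedSegment(bam.header)
                a.query_name = name
                a.flag = 0
                a.mapping_quality = 60
                a.reference_id = tid[chrom]
                a.reference_start = start
                a.query_sequence = genome.fetch(chrom, start, end)
                a.cigarstring = f"{flen}M"
                a.query_qualities = pysam.qualitystring_to_array("I" * flen)
                records.append((a.reference_id, a.reference_start, 0, a))
        records.sort(key=lambda t: (t[0], t[1], t[2]))
        for _, _, _, a in records:
            bam.write(a)
    pysam.index(bam_path)


def simulate_dataset(
    config: SimulationConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Run the full generator and write FASTA, BED, BAM, and ground truth.

    Byte-deterministic for a fixed config (including seed).  Returns paths
    keyed by artifact name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = make_genome(config)
    sites = make_sites(genome, config)
    fragments = draw_fragments(genome, sites, config)
    paths = {
        "fasta": out_dir / "genome.fa",
        "bed": out_dir / "sites.bed",
        "bam": out_dir / "fragments.bam",
        "truth": out_dir / "ground_truth.tsv",
        "config": out_dir / "sim_config.yaml",
    }
    genome.to_fasta(paths["fasta"])
    write_bed(sites, paths["bed"])
    write_alignments(genome, fragments, paths["bam"], config)
    fragments.to_csv(paths["truth"], sep="\t", index=False, float_format="%.8g")
    with open(paths["config"], "w") as fh:
        for key, value in dataclasses.asdict(config).items():
            fh.write(f"{key}: {list(value) if isinstance(value, tuple) else value}\n")
    return paths
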