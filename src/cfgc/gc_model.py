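"""Fragment-length-aware GC-bias model: expected vs. observed distributions.

cfDNA libraries carry fragments over a wide length range, so GC bias is
modeled jointly over (fragment length, GC-content bin) rather than at a single
representative length.  The expected distribution counts *every possible*
fragment of every modeled length inside regions sampled along the reference;
the observed distribution counts the sample's fragments in the same regions.
Correction weights are the ratio of the two (as densities), clipped and then
globally rescaled so that weighted coverage is conserved exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    CoordinateError,
    DegenerateDistributionError,
    GridMismatchError,
)
from .refio import FragmentRecord, GenomeSequence, Region

DEFAULT_F_MIN = 70
DEFAULT_F_MAX = 500
DEFAULT_N_BINS = 101
DEFAULT_MIN_COUNT = 50
DEFAULT_CLIP = (0.1, 10.0)
DEFAULT_N_REGIONS = 1000
DEFAULT_REGION_LENGTH = 10_000
DEFAULT_MAX_N_FRACTION = 0.1


@dataclass(frozen=True)
class FragmentLengthRange:
    """Closed range of modeled fragment lengths in bp."""

    f_min: int
    f_max: int

    def __post_init__(self):
        if not (1 <= self.f_min <= self.f_max):
            raise ConfigError(f"invalid length range [{self.f_min}, {self.f_max}]")

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(self.f_min, self.f_max + 1)

    @property
    def n_lengths(self) -> int:
        return self.f_max - self.f_min + 1


@dataclass(frozen=True)
class GCBinning:
    """Partition of [0, 1] into ``n_bins`` equal GC bins.

    ``gc`` maps to ``floor(gc * n_bins)`` with gc == 1 assigned to the last
    bin, so the mapping is total and monotone.
    """

    n_bins: int

    def __post_init__(self):
        if self.n_bins < 1:
            raise ConfigError("n_bins must be >= 1")

    def bin_of(self, gc):
        b = np.floor(np.asarray(gc, dtype=float) * self.n_bins).astype(np.int64)
        return np.clip(b, 0, self.n_bins - 1)

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) / self.n_bins

    @property
    def edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) / self.n_bins


@dataclass
class SampledRegions:
    """Reference regions used for both expected and observed distributions."""

    regions: list[Region]
    seed: int | None
    region_length: int
    n_regions: int


@dataclass
class FragmentDistribution:
    """Count grid over (fragment length, GC bin); either expected or observed."""

    counts: np.ndarray  # (n_lengths, n_bins)
    lengths: FragmentLengthRange
    binning: GCBinning
    provenance: str  # "expected" | "observed"
    regions: SampledRegions | None = None

    def __post_init__(self):
        expected_shape = (self.lengths.n_lengths, self.binning.n_bins)
        if self.counts.shape != expected_shape:
            raise GridMismatchError(
                f"counts shape {self.counts.shape} != grid {expected_shape}"
            )

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def degenerate(self) -> bool:
        return self.total == 0

    def density(self) -> np.ndarray:
        if self.degenerate:
            raise DegenerateDistributionError(f"{self.provenance} distribution is empty")
        return self.counts / self.total

    def gc_marginal_density(self) -> np.ndarray:
        """GC density marginalized over fragment length."""
        return self.density().sum(axis=0)

    def same_grid(self, other: "FragmentDistribution") -> bool:
        return self.lengths == other.lengths and self.binning == other.binning


def _overlap_lookup(regions: Sequence[Region]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chrom (sorted starts, running-max ends) for fast overlap queries."""
    lookup: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {r.chrom for r in regions}:
        pairs = sorted((r.start, r.end) for r in regions if r.chrom == chrom)
        starts = np.array([p[0] for p in pairs], dtype=np.int64)
        ends = np.maximum.accumulate(np.array([p[1] for p in pairs], dtype=np.int64))
        lookup[chrom] = (starts, ends)
    return lookup


def _overlaps_any(lookup, chrom: str, start: int, end: int) -> bool:
    entry = lookup.get(chrom)
    if entry is None:
        return False
    starts, ends = entry
    i = int(np.searchsorted(starts, end, side="left")) - 1
    return i >= 0 and ends[i] > start


def sample_regions(
    genome: GenomeSequence,
    n_regions: int = DEFAULT_N_REGIONS,
    region_length: int = DEFAULT_REGION_LENGTH,
    seed: int | None = 0,
    max_n_fraction: float = 0.5,
    max_retries: int = 1000,
    exclude: Sequence[Region] | None = None,
    allow_overlap: bool = False,
) -> SampledRegions:
    """Draw regions uniformly along the genome, chrom-weighted by length.

    Regions whose N fraction exceeds ``max_n_fraction`` are redrawn (bounded
    retries), so assembly gaps do not dominate the expected distribution.
    By default regions are also redrawn when they overlap an already-sampled
    region: the expected grid counts every region separately while observed
    fragments are counted once, so overlapping samples would weight the
    overlapped sequence inconsistently between the two distributions.
    ``exclude`` blacklists intervals (e.g., the signal regions under study)
    from bias sampling: regions of interest carry real coverage structure
    that would otherwise be absorbed into the bias estimate.
    """
    if n_regions < 1:
        raise ConfigError("n_regions must be >= 1")
    eligible = [c for c in genome.chrom_names if genome.chrom_lengths[c] >= region_length]
    if not eligible:
        raise CoordinateError(f"no chromosome is >= region_length {region_length}")
    rng = np.random.default_rng(seed)
    weights = np.array([genome.chrom_lengths[c] for c in eligible], dtype=float)
    weights /= weights.sum()
    excluded = _overlap_lookup(exclude) if exclude else {}
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in eligible}
    regions: list[Region] = []
    for _ in range(n_regions):
        for _attempt in range(max_retries):
            chrom = eligible[rng.choice(len(eligible), p=weights)]
            start = int(rng.integers(0, genome.chrom_lengths[chrom] - region_length + 1))
            end = start + region_length
            if _overlaps_any(excluded, chrom, start, end):
                continue
            if not allow_overlap and any(
                start < e and end > s for s, e in taken[chrom]
            ):
                continue
            _, n_cnt = genome.gc_count(chrom, start, end)
            if n_cnt / region_length <= max_n_fraction:
                regions.append(Region(chrom, start, end))
                taken[chrom].append((start, end))
                break
        else:
            raise DegenerateDistributionError(
                f"could not place a region with N fraction <= {max_n_fraction} "
                f"in {max_retries} tries"
            )
    return SampledRegions(regions, seed, region_length, n_regions)


def regions_as_sampled(regions: Sequence[Region]) -> SampledRegions:
    """Wrap explicit regions so they can stand in for sampled ones."""
    if not regions:
        raise ConfigError("empty region list")
    return SampledRegions(list(regions), None, len(regions[0]), len(regions))


def expected_distribution(
    genome: GenomeSequence,
    regions: SampledRegions,
    lengths: FragmentLengthRange | None = None,
    binning: GCBinning | None = None,
    max_n_fraction: float = DEFAULT_MAX_N_FRACTION,
) -> FragmentDistribution:
    """Count all possible fragments of each modeled length in the regions.

    For every region and every length ``f``, every start ``s`` with
    ``[s, s + f)`` inside the region contributes one count to the cell
    ``(f, bin(gc of [s, s + f)))``.  Fragments whose N fraction exceeds
    ``max_n_fraction`` are excluded.  GC prefix sums make each (region,
    length) pass a vectorized O(region length) scan.
    """
    lengths = lengths or FragmentLengthRange(DEFAULT_F_MIN, DEFAULT_F_MAX)
    binning = binning or GCBinning(DEFAULT_N_BINS)
    if not regions.regions:
        raise DegenerateDistributionError("no regions to enumerate")
    counts = np.zeros((lengths.n_lengths, binning.n_bins), dtype=np.int64)
    for region in regions.regions:
        gc = genome.gc_prefix[region.chrom]
        nn = genome.n_prefix[region.chrom]
        span = region.end - region.start
        for fi, f in enumerate(lengths.lengths):
            if f > span:
                continue
            starts = np.arange(region.start, region.end - f + 1)
            gc_cnt = gc[starts + f] - gc[starts]
            n_cnt = nn[starts + f] - nn[starts]
            ok = n_cnt <= max_n_fraction * f
            non_n = f - n_cnt[ok]
            usable = non_n > 0
            frac = gc_cnt[ok][usable] / non_n[usable]
            counts[fi] += np.bincount(binning.bin_of(frac), minlength=binning.n_bins)
    return FragmentDistribution(counts, lengths, binning, "expected", regions)


def observed_distribution(
    fragments: Iterable[FragmentRecord],
    regions: SampledRegions,
    lengths: FragmentLengthRange | None = None,
    binning: GCBinning | None = None,
    max_n_fraction: float = DEFAULT_MAX_N_FRACTION,
) -> FragmentDistribution:
    """Count the sample's fragments whose midpoints fall in the regions.

    A fragment contributes once (first matching region) iff its midpoint lies
    inside a region and its length is within the modeled range.
    """
    lengths = lengths or FragmentLengthRange(DEFAULT_F_MIN, DEFAULT_F_MAX)
    binning = binning or GCBinning(DEFAULT_N_BINS)
    # first-match midpoint lookup: per chrom, sorted region starts with the
    # running max end so overlapping regions still answer membership
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {r.chrom for r in regions.regions}:
        rs = sorted(
            ((r.start, r.end) for r in regions.regions if r.chrom == chrom)
        )
        starts = np.array([s for s, _ in rs], dtype=np.int64)
        ends = np.maximum.accumulate(np.array([e for _, e in rs], dtype=np.int64))
        by_chrom[chrom] = (starts, ends)
    counts = np.zeros((lengths.n_lengths, binning.n_bins), dtype=np.int64)
    for frag in fragments:
        f = frag.length
        if f < lengths.f_min or f > lengths.f_max:
            continue
        if frag.n_fraction > max_n_fraction or math.isnan(frag.gc):
            continue
        lookup = by_chrom.get(frag.chrom)
        if lookup is None:
            continue
        starts, ends = lookup
        mid = frag.midpoint
        i = int(np.searchsorted(starts, mid, side="right")) - 1
        if i < 0 or mid >= ends[i]:
            continue
        counts[f - lengths.f_min, int(binning.bin_of(frag.gc))] += 1
    if counts.sum() == 0:
        raise DegenerateDistributionError("no fragment fell inside the sampled regions")
    return FragmentDistribution(counts, lengths, binning, "observed", regions)


@dataclass
class CorrectionModel:
    """Per-(length, GC-bin) correction weights with conservation rescaling.

    ``weights`` is the stored (post-rescale) grid; ``pre_rescale`` divides it
    by ``rescale_factor``.  Cells without enough observed support carry the
    neutral weight ``rescale_factor * 1``.
    """

    weights: np.ndarray
    lengths: FragmentLengthRange
    binning: GCBinning
    min_count: int
    clip: tuple[float, float]
    rescale_factor: float
    expected_counts: np.ndarray | None = None
    observed_counts: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def pre_rescale(self) -> np.ndarray:
        return self.weights / self.rescale_factor

    def lookup(self, length, gc):
        """Vectorized weight lookup with length clamping; NaN gc -> neutral."""
        length = np.asarray(length)
        gc = np.asarray(gc, dtype=float)
        li = np.clip(length, self.lengths.f_min, self.lengths.f_max) - self.lengths.f_min
        nan = np.isnan(gc)
        bi = self.binning.bin_of(np.where(nan, 0.0, gc))
        w = self.weights[li, bi]
        return np.where(nan, self.rescale_factor, w)

    def to_files(self, prefix: str | Path) -> tuple[Path, Path]:
        """Serialize as <prefix>.model.tsv plus <prefix>.model.json sidecar."""
        prefix = Path(prefix)
        table = prefix.with_suffix(prefix.suffix + ".model.tsv")
        sidecar = prefix.with_suffix(prefix.suffix + ".model.json")
        edges = self.binning.edges
        n_bins = self.binning.n_bins
        lens = np.repeat(self.lengths.lengths, n_bins)
        lo = np.tile(edges[:-1], self.lengths.n_lengths)
        hi = np.tile(edges[1:], self.lengths.n_lengths)
        exp_c = (
            self.expected_counts.ravel()
            if self.expected_counts is not None
            else np.zeros(lens.size)
        )
        obs_c = (
            self.observed_counts.ravel()
            if self.observed_counts is not None
            else np.zeros(lens.size)
        )
        pd.DataFrame(
            {
                "length": lens,
                "gc_bin_low": lo,
                "gc_bin_high": hi,
                "expected_count": exp_c,
                "observed_count": obs_c,
                "weight": self.weights.ravel(),
            }
        ).to_csv(table, sep="\t", index=False, float_format="%.10g")
        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "f_min": self.lengths.f_min,
                    "f_max": self.lengths.f_max,
                    "n_bins": n_bins,
                    "min_count": self.min_count,
                    "clip": list(self.clip),
                    "rescale_factor": self.rescale_factor,
                    "expected_total": float(exp_c.sum()),
                    "observed_total": float(obs_c.sum()),
                    **self.meta,
                },
                fh,
                indent=2,
            )
        return table, sidecar

    @classmethod
    def from_files(cls, prefix: str | Path) -> "CorrectionModel":
        prefix = Path(prefix)
        table = prefix.with_suffix(prefix.suffix + ".model.tsv")
        sidecar = prefix.with_suffix(prefix.suffix + ".model.json")
        with open(sidecar) as fh:
            meta = json.load(fh)
        df = pd.read_csv(table, sep="\t")
        lengths = FragmentLengthRange(meta["f_min"], meta["f_max"])
        binning = GCBinning(meta["n_bins"])
        shape = (lengths.n_lengths, binning.n_bins)
        return cls(
            weights=df["weight"].to_numpy().reshape(shape),
            lengths=lengths,
            binning=binning,
            min_count=meta["min_count"],
            clip=tuple(meta["clip"]),
            rescale_factor=meta["rescale_factor"],
            expected_counts=df["expected_count"].to_numpy().reshape(shape),
            observed_counts=df["observed_count"].to_numpy().reshape(shape),
            meta={
                k: v
                for k, v in meta.items()
                if k
                not in {
                    "f_min",
                    "f_max",
                    "n_bins",
                    "min_count",
                    "clip",
                    "rescale_factor",
                }
            },
        )


def compute_weights(
    expected: FragmentDistribution,
    observed: FragmentDistribution,
    min_count: int = DEFAULT_MIN_COUNT,
    clip: tuple[float, float] = DEFAULT_CLIP,
    smooth: bool = False,
    smooth_frac: float = 0.3,
    fallback: str = "marginal",
) -> CorrectionModel:
    """Derive correction weights from expected and observed distributions.

    Raw weight ``w[f, b] = (E[f, b] / sum E) / (O[f, b] / sum O)`` wherever the
    observed count reaches ``min_count``.  Sparse cells back off according to
    ``fallback``: ``"marginal"`` (default) uses the length-marginalized GC
    ratio for the cell's bin when that bin has enough pooled support — bias is
    primarily a function of GC, so partial pooling corrects the distribution
    tails instead of leaving them biased; ``"neutral"`` leaves sparse cells at
    weight 1.  Cells the expectation says cannot exist (E == 0, observed
    support present) get the lower clip bound.  After clipping to ``clip``,
    one global rescale factor makes ``sum(O * w) == sum(O)`` exactly, so
    tagging preserves total coverage.

    With ``smooth=True`` the log-ratio is locally-weighted-smoothed along GC
    within each length before clipping (off by default: the raw ratio is the
    reference behavior).
    """
    if not expected.same_grid(observed):
        raise GridMismatchError("expected and observed use different grids")
    if expected.degenerate or observed.degenerate:
        raise DegenerateDistributionError("cannot build weights from an empty grid")
    if fallback not in ("marginal", "neutral"):
        raise ConfigError(f"unknown fallback {fallback!r}")
    w_lo, w_hi = clip
    if not (0 < w_lo <= 1 <= w_hi):
        raise ConfigError(f"clip bounds {clip} must bracket 1")
    e = expected.density()
    o = observed.density()
    O = observed.counts
    supported = O >= max(min_count, 1)
    w = np.ones_like(e)
    if fallback == "marginal":
        # pool the sparse cells of each GC bin and correct them with their
        # aggregate ratio: the supported cells already reproduce their share
        # of the expectation, so pooling only the residual makes the
        # corrected GC marginal match the expected marginal by construction
        E_resid = np.where(supported, 0, expected.counts).sum(axis=0).astype(float)
        O_resid = np.where(supported, 0, O).sum(axis=0).astype(float)
        e_resid = E_resid / expected.total
        o_resid = O_resid / observed.total
        m_ok = (O_resid >= max(min_count, 1)) & (E_resid > 0)
        w_marg = np.ones(e.shape[1])
        w_marg[m_ok] = e_resid[m_ok] / o_resid[m_ok]
        w[:] = w_marg[np.newaxis, :]
    ratio_ok = supported & (e > 0)
    w[ratio_ok] = e[ratio_ok] / o[ratio_ok]
    w[supported & (e == 0)] = w_lo
    if smooth:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        centers = observed.binning.centers
        for fi in range(w.shape[0]):
            row_ok = ratio_ok[fi]
            if row_ok.sum() >= 5:
                sm = lowess(
                    np.log(w[fi, row_ok]), centers[row_ok], frac=smooth_frac,
                    return_sorted=False,
                )
                w[fi, row_ok] = np.exp(sm)
    w = np.clip(w, w_lo, w_hi)
    rescale = float(O.sum() / (O * w).sum())
    return CorrectionModel(
        weights=w * rescale,
        lengths=expected.lengths,
        binning=expected.binning,
        min_count=min_count,
        clip=(w_lo, w_hi),
        rescale_factor=rescale,
        expected_counts=expected.counts,
        observed_counts=observed.counts,
        meta={"fallback": fallback, "smooth": smooth},
    )


def weight_lookup(model: CorrectionModel, length: int, gc: float) -> float:
    """Scalar convenience wrapper around :meth:`CorrectionModel.lookup`."""
    return float(model.lookup(length, gc))


def bias_slope(model: CorrectionModel) -> float:
    """Count-weighted slope of log pre-rescale weight vs. GC.

    Within each fragment length, regress log(w) on GC-bin centers over cells
    with observed support, then average slopes weighted by observed counts.
    For a log-linear acceptance bias exp(beta * gc) this recovers -beta,
    independent of the fragment-length distribution.
    """
    centers = model.binning.centers
    O = model.observed_counts
    pre = model.pre_rescale
    supported = O >= max(model.min_count, 1)
    slopes, weights = [], []
    for fi in range(pre.shape[0]):
        ok = supported[fi] & (pre[fi] > 0)
        if ok.sum() < 3:
            continue
        x, y, cw = centers[ok], np.log(pre[fi, ok]), O[fi, ok].astype(float)
        xm = np.average(x, weights=cw)
        ym = np.average(y, weights=cw)
        var = np.average((x - xm) ** 2, weights=cw)
        if var <= 0:
            continue
        slopes.append(np.average((x - xm) * (y - ym), weights=cw) / var)
        weights.append(cw.sum())
    if not slopes:
        raise DegenerateDistributionError("no length has enough supported GC bins")
    return float(np.average(slopes, weights=weights))
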