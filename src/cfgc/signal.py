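"""Composite coverage signals around centered regions and GC-profile tables.

A composite ("overlay") signal averages fragment coverage across many regions
aligned at their midpoints.  Coverage is fragment-level: a sequenced fragment
covers every base of its insert, which matches the fragment-based weighting
and standard cfDNA accessibility analysis.  Weighted coverage adds each
fragment's correction weight instead of 1, so a flat weighted composite at
bound transcription-factor sites reflects true accessibility rather than GC
bias.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CfgcError,
    DegenerateNormalizationError,
    EmptySignalError,
    GridMismatchError,
)
from .gc_model import CorrectionModel, FragmentDistribution
from .refio import FragmentRecord, Region

DEFAULT_WINDOW = 1000
DEFAULT_FLANK_FRACTION = 0.25


@dataclass
class CompositeSignal:
    """Mean raw and weighted fragment coverage per offset around midpoints."""

    offsets: np.ndarray  # -W..+W
    raw_mean: np.ndarray
    weighted_mean: np.ndarray
    n_sites: int
    n_skipped: int = 0
    flank_norm_raw: float | None = None
    flank_norm_weighted: float | None = None
    flank_fraction: float | None = None

    @property
    def window(self) -> int:
        return (len(self.offsets) - 1) // 2

    @property
    def normalized_raw(self) -> np.ndarray:
        if self.flank_norm_raw is None:
            raise DegenerateNormalizationError("signal has not been normalized")
        return self.raw_mean / self.flank_norm_raw

    @property
    def normalized_weighted(self) -> np.ndarray:
        if self.flank_norm_weighted is None:
            raise DegenerateNormalizationError("signal has not been normalized")
        return self.weighted_mean / self.flank_norm_weighted

    def center_value(self, weighted: bool = True) -> float:
        arr = self.normalized_weighted if weighted else self.normalized_raw
        return float(arr[self.window])

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "offset": self.offsets,
            "raw_mean": self.raw_mean,
            "weighted_mean": self.weighted_mean,
        }
        if self.flank_norm_raw is not None:
            cols["normalized_raw"] = self.normalized_raw
            cols["normalized_weighted"] = self.normalized_weighted
        return pd.DataFrame(cols)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")


def composite_signal(
    fragments: Iterable[FragmentRecord],
    regions: Sequence[Region],
    chrom_lengths: Mapping[str, int],
    window: int = DEFAULT_WINDOW,
    use_weights: bool = True,
) -> CompositeSignal:
    """Average fragment coverage across regions anchored at their midpoints.

    Each region contributes a length-(2W+1) coverage vector; a fragment adds
    its weight (or 1 for the raw track) to every offset its interval covers.
    Minus-strand regions are reversed before averaging.  Regions whose window
    exceeds chromosome bounds are skipped and tallied.  Overlapping regions
    each contribute independently.
    """
    if not regions:
        raise EmptySignalError("no regions given")
    if window < 1:
        raise CfgcError("window must be >= 1")
    frags: dict[str, list[tuple[int, int, float]]] = {}
    for f in fragments:
        frags.setdefault(f.chrom, []).append((f.start, f.end, f.weight))
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, int]] = {}
    for chrom, triples in frags.items():
        arr = np.array(triples, dtype=float)
        order = np.argsort(arr[:, 0], kind="stable")
        starts = arr[order, 0].astype(np.int64)
        ends = arr[order, 1].astype(np.int64)
        weights = arr[order, 2]
        max_len = int((ends - starts).max())
        by_chrom[chrom] = (starts, ends, weights, max_len)

    width = 2 * window + 1
    raw_sum = np.zeros(width)
    wgt_sum = np.zeros(width)
    n_sites = 0
    n_skipped = 0
    for region in regions:
        center = region.midpoint
        win_start = center - window
        win_end = center + window + 1
        chrom_len = chrom_lengths.get(region.chrom)
        if chrom_len is None or win_start < 0 or win_end > chrom_len:
            n_skipped += 1
            continue
        raw_vec = np.zeros(width + 1)
        wgt_vec = np.zeros(width + 1)
        entry = by_chrom.get(region.chrom)
        if entry is not None:
            starts, ends, weights, max_len = entry
            i_lo = int(np.searchsorted(starts, win_start - max_len, side="left"))
            i_hi = int(np.searchsorted(starts, win_end, side="left"))
            sel = slice(i_lo, i_hi)
            overlap = ends[sel] > win_start
            s = np.clip(starts[sel][overlap] - win_start, 0, width)
            e = np.clip(ends[sel][overlap] - win_start, 0, width)
            w = weights[sel][overlap]
            np.add.at(raw_vec, s, 1.0)
            np.subtract.at(raw_vec, e, 1.0)
            np.add.at(wgt_vec, s, w)
            np.subtract.at(wgt_vec, e, w)
        raw_cov = np.cumsum(raw_vec[:-1])
        wgt_cov = np.cumsum(wgt_vec[:-1])
        if region.strand == "-":
            raw_cov = raw_cov[::-1]
            wgt_cov = wgt_cov[::-1]
        raw_sum += raw_cov
        wgt_sum += wgt_cov if use_weights else raw_cov
        n_sites += 1
    if n_sites == 0:
        raise EmptySignalError("every region's window exceeded chromosome bounds")
    return CompositeSignal(
        offsets=np.arange(-window, window + 1),
        raw_mean=raw_sum / n_sites,
        weighted_mean=wgt_sum / n_sites,
        n_sites=n_sites,
        n_skipped=n_skipped,
    )


def normalize_composite(
    signal: CompositeSignal, flank_fraction: float = DEFAULT_FLANK_FRACTION
) -> CompositeSignal:
    """Set flank normalization divisors so flank mean coverage becomes 1.

    The flank is the outermost ``flank_fraction`` of the window on each side
    (offsets with ``|offset| >= (1 - flank_fraction) * W``), far enough from
    the midpoint that site accessibility does not depress it.
    """
    if not (0 < flank_fraction < 0.5):
        raise CfgcError("flank_fraction must be in (0, 0.5)")
    W = signal.window
    flank = np.abs(signal.offsets) >= (1 - flank_fraction) * W
    norm_raw = float(signal.raw_mean[flank].mean())
    norm_wgt = float(signal.weighted_mean[flank].mean())
    if norm_raw <= 0 or norm_wgt <= 0:
        raise DegenerateNormalizationError("flank coverage is zero")
    return replace(
        signal,
        flank_norm_raw=norm_raw,
        flank_norm_weighted=norm_wgt,
        flank_fraction=flank_fraction,
    )


def gc_profile(
    expected: FragmentDistribution,
    observed: FragmentDistribution,
    model: CorrectionModel,
) -> pd.DataFrame:
    """Global GC-bias profile: expected, observed, and corrected GC densities.

    Densities are marginalized over fragment length and sum to 1; the
    corrected density reweights observed counts by the model.  Log2 ratios
    against the expected density use a 0.5-count pseudocount so empty bins
    stay finite.
    """
    if not expected.same_grid(observed) or model.binning != expected.binning:
        raise GridMismatchError("profile inputs use different grids")
    E = expected.counts.sum(axis=0).astype(float)
    O = observed.counts.sum(axis=0).astype(float)
    OW = (observed.counts * model.weights).sum(axis=0)
    exp_d = E / E.sum()
    obs_d = O / O.sum()
    cor_d = OW / OW.sum()

    def _log2_ratio(num_counts, num_total, den_counts, den_total):
        num = (num_counts + 0.5) / (num_total + 0.5 * len(num_counts))
        den = (den_counts + 0.5) / (den_total + 0.5 * len(den_counts))
        return np.log2(num / den)

    edges = expected.binning.edges
    return pd.DataFrame(
        {
            "gc_bin_low": edges[:-1],
            "gc_bin_high": edges[1:],
            "expected_density": exp_d,
            "observed_density": obs_d,
            "corrected_density": cor_d,
            "log2_ratio_observed": _log2_ratio(O, O.sum(), E, E.sum()),
            "log2_ratio_corrected": _log2_ratio(OW, OW.sum(), E, E.sum()),
        }
    )


@dataclass(frozen=True)
class SampleManifest:
    """One sample's identity, class label, and alignment path."""

    sample_id: str
    class_label: str
    path: str


def read_manifest(path: str | Path) -> list[SampleManifest]:
    """Read a tab-separated manifest with columns sample_id, class, path."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "class", "path"}
    if not required.issubset(df.columns):
        raise CfgcError(f"manifest needs columns {sorted(required)}")
    entries = [
        SampleManifest(str(sid), str(cls), str(p))
        for sid, cls, p in df[["sample_id", "class", "path"]].itertuples(index=False)
    ]
    ids = [e.sample_id for e in entries]
    if len(set(ids)) != len(ids):
        raise CfgcError("duplicate sample_id in manifest")
    return entries


@dataclass
class CaseControlResult:
    table: pd.DataFrame
    single_class: bool  # notice flag: no cross-class comparison possible


def case_control_table(
    entries: Sequence[tuple[SampleManifest, CompositeSignal]],
) -> CaseControlResult:
    """Long-format table of normalized composites, with per-class mean curves.

    Rows are (sample_id, class_label, offset, normalized_raw,
    normalized_weighted); each class's mean curve is appended as a
    pseudo-sample named ``<class>::mean``.  With a single class the notice
    flag is set: the table stands alone without a comparison class.
    """
    if not entries:
        raise CfgcError("no samples given")
    ids = [m.sample_id for m, _ in entries]
    if len(set(ids)) != len(ids):
        raise CfgcError("duplicate sample_id")
    rows = []
    for manifest, sig in entries:
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": manifest.sample_id,
                    "class_label": manifest.class_label,
                    "offset": sig.offsets,
                    "normalized_raw": sig.normalized_raw,
                    "normalized_weighted": sig.normalized_weighted,
                }
            )
        )
    per_sample = pd.concat(rows, ignore_index=True)
    means = (
        per_sample.groupby(["class_label", "offset"], sort=True)[
            ["normalized_raw", "normalized_weighted"]
        ]
        .mean()
        .reset_index()
    )
    means["sample_id"] = means["class_label"] + "::mean"
    table = pd.concat(
        [per_sample, means[per_sample.columns]], ignore_index=True
    )
    classes = {m.class_label for m, _ in entries}
    return CaseControlResult(table=table, single_class=len(classes) == 1)


def write_bedgraph(
    fragments: Iterable[FragmentRecord],
    region: Region,
    path: str | Path,
    use_weights: bool = True,
) -> None:
    """Per-base (optionally weighted) fragment coverage of one interval."""
    span = region.end - region.start
    diff = np.zeros(span + 1)
    for f in fragments:
        if f.chrom != region.chrom or f.end <= region.start or f.start >= region.end:
            continue
        s = max(f.start, region.start) - region.start
        e = min(f.end, region.end) - region.start
        diff[s] += f.weight if use_weights else 1.0
        diff[e] -= f.weight if use_weights else 1.0
    cov = np.cumsum(diff[:-1])
    with open(path, "w") as fh:
        run_start = 0
        for i in range(1, span + 1):
            if i == span or cov[i] != cov[run_start]:
                fh.write(
                    f"{region.chrom}\t{region.start + run_start}\t"
                    f"{region.start + i}\t{cov[run_start]:.6g}\n"
                )
                run_start = i
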