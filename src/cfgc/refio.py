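"""Readers, writers, and coordinate-safe primitives for FASTA, BED, and BAM.

All coordinates are 0-based half-open throughout the package.  BED is native;
SAM's 1-based coordinates are converted at the pysam boundary.  Interval GC
content is computed in constant time from per-chromosome prefix sums over G/C
and N counts, so scanning millions of candidate fragments stays cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pysam
from pyfaidx import Fasta

from .errors import (
    BedParseError,
    ChromosomeNotFoundError,
    CoordinateError,
    InputContractError,
)

_BASE_TO_CODE = np.zeros(256, dtype=np.uint8)  # 0=A/T, 1=G/C, 2=N/other
for _b in b"GCgc":
    _BASE_TO_CODE[_b] = 1
for _b in b"NnRYSWKMBDHVryswkmbdhv":
    _BASE_TO_CODE[_b] = 2


@dataclass(frozen=True)
class Region:
    """A 0-based half-open genomic interval, optionally named and stranded."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in (None, "+", "-", "."):
            raise CoordinateError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class FragmentRecord:
    """One sequenced cfDNA fragment reconstructed from an alignment template.

    ``gc`` is the G+C fraction of the *reference* sequence across the fragment
    interval (NaN when the interval is entirely N), making observed fragments
    commensurable with expected fragments enumerated from the reference.
    """

    chrom: str
    start: int
    end: int
    gc: float
    n_fraction: float = 0.0
    mapq: int = 60
    duplicate: bool = False
    weight: float = 1.0

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class GenomeSequence:
    """In-memory reference genome with O(1) interval GC via prefix sums.

    ``gc_prefix[c][i]`` is the number of G/C bases in bases ``[0, i)`` of
    chromosome ``c``; ``n_prefix`` counts N (and other ambiguity codes).
    """

    def __init__(self, sequences: Mapping[str, str]):
        self.chrom_names: list[str] = list(sequences)
        self._seq: dict[str, bytes] = {}
        self.chrom_lengths: dict[str, int] = {}
        self.gc_prefix: dict[str, np.ndarray] = {}
        self.n_prefix: dict[str, np.ndarray] = {}
        for chrom, seq in sequences.items():
            raw = seq.upper().encode("ascii")
            codes = _BASE_TO_CODE[np.frombuffer(raw, dtype=np.uint8)]
            self._seq[chrom] = raw
            self.chrom_lengths[chrom] = len(raw)
            gc = np.zeros(len(raw) + 1, dtype=np.int64)
            nn = np.zeros(len(raw) + 1, dtype=np.int64)
            np.cumsum(codes == 1, out=gc[1:])
            np.cumsum(codes == 2, out=nn[1:])
            self.gc_prefix[chrom] = gc
            self.n_prefix[chrom] = nn

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
            return cls({name: str(fa[name][:]) for name in fa.keys()})

    def _check(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self.chrom_lengths:
            raise ChromosomeNotFoundError(chrom)
        if not (0 <= start < end <= self.chrom_lengths[chrom]):
            raise CoordinateError(
                f"{chrom}:{start}-{end} outside [0, {self.chrom_lengths[chrom]}]"
            )

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Uppercase base string for the 0-based half-open interval."""
        self._check(chrom, start, end)
        return self._seq[chrom][start:end].decode("ascii")

    def gc_count(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """(G+C count, N count) over the interval, via prefix sums."""
        self._check(chrom, start, end)
        gc = self.gc_prefix[chrom]
        nn = self.n_prefix[chrom]
        return int(gc[end] - gc[start]), int(nn[end] - nn[start])

    def to_fasta(self, path: str | Path, line_width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom in self.chrom_names:
                fh.write(f">{chrom}\n")
                seq = self._seq[chrom].decode("ascii")
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")


def interval_gc(genome: GenomeSequence, region: Region) -> tuple[float, float]:
    """GC fraction over non-N bases and N fraction of a region.

    Returns ``(gc, n_fraction)``; ``gc`` is NaN when every base is N.
    """
    gc, nn = genome.gc_count(region.chrom, region.start, region.end)
    span = region.end - region.start
    n_fraction = nn / span
    if nn == span:
        return math.nan, 1.0
    return gc / (span - nn), n_fraction


def read_bed(path: str | Path) -> list[Region]:
    """Parse BED3/BED6 text into Regions, preserving half-open coordinates."""
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise BedParseError(f"expected >= 3 columns, got {len(cols)}", lineno)
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise BedParseError(f"non-integer coordinates: {exc}", lineno)
            if start >= end:
                raise BedParseError(f"start {start} >= end {end}", lineno)
            name = cols[3] if len(cols) >= 4 and cols[3] != "." else None
            strand = cols[5] if len(cols) >= 6 and cols[5] in ("+", "-") else None
            regions.append(Region(cols[0], start, end, name=name, strand=strand))
    return regions


def write_bed(regions: Iterable[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            if r.strand is not None:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name or '.'}\t0\t{r.strand}\n")
            elif r.name is not None:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


@dataclass
class FragmentTally:
    """Conservation accounting: emitted + filtered + skipped == templates."""

    emitted: int = 0
    filtered_mapq: int = 0
    filtered_length: int = 0
    filtered_duplicate: int = 0
    skipped_cross_chrom: int = 0
    skipped_improper: int = 0
    counts: dict = field(default_factory=dict)

    @property
    def filtered(self) -> int:
        return self.filtered_mapq + self.filtered_length + self.filtered_duplicate

    @property
    def skipped(self) -> int:
        return self.skipped_cross_chrom + self.skipped_improper

    @property
    def templates(self) -> int:
        return self.emitted + self.filtered + self.skipped


class FragmentStream:
    """Iterate fragments from a coordinate-sorted BAM/SAM with filtering.

    One FragmentRecord per template: proper pairs span leftmost start to
    rightmost end (reconstructed from TLEN on the leftmost mate); unpaired or
    merged single-end reads use their aligned span.  Secondary and
    supplementary alignments never yield fragments.  The tally on the
    ``tally`` attribute satisfies the conservation property
    ``emitted + filtered + skipped == templates``.
    """

    def __init__(
        self,
        path: str | Path,
        genome: GenomeSequence,
        min_mapq: int = 20,
        min_length: int = 30,
        max_length: int = 500,
        drop_duplicates: bool = True,
        weight_tag: str | None = None,
    ):
        self.path = str(path)
        self.genome = genome
        self.min_mapq = min_mapq
        self.min_length = min_length
        self.max_length = max_length
        self.drop_duplicates = drop_duplicates
        self.weight_tag = weight_tag
        self.tally = FragmentTally()

    def _open(self) -> pysam.AlignmentFile:
        mode = "r" if self.path.endswith(".sam") else "rb"
        af = pysam.AlignmentFile(self.path, mode)
        so = (af.header.get("HD") or {}).get("SO")
        if so not in (None, "coordinate"):
            af.close()
            raise InputContractError(f"{self.path}: expected coordinate-sorted input, SO={so}")
        return af

    def __iter__(self) -> Iterator[FragmentRecord]:
        tally = self.tally
        with self._open() as af:
            for read in af.fetch(until_eof=True):
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                if read.is_paired:
                    if read.mate_is_unmapped:
                        # the unmapped mate never reaches here, so the template
                        # is counted exactly once
                        tally.skipped_improper += 1
                        continue
                    if read.reference_id != read.next_reference_id:
                        if read.is_read1:
                            tally.skipped_cross_chrom += 1
                        continue
                    tlen = read.template_length
                    if tlen == 0:
                        if read.is_read1:
                            tally.skipped_improper += 1
                        continue
                    if tlen < 0:
                        continue  # template counted at its leftmost mate
                    if not read.is_proper_pair:
                        tally.skipped_improper += 1
                        continue
                    start = read.reference_start
                    end = start + tlen
                    if end < read.reference_end:  # TLEN inconsistent with span
                        tally.skipped_improper += 1
                        continue
                else:
                    start, end = read.reference_start, read.reference_end
                if self.drop_duplicates and read.is_duplicate:
                    tally.filtered_duplicate += 1
                    continue
                if read.mapping_quality < self.min_mapq:
                    tally.filtered_mapq += 1
                    continue
                length = end - start
                if length < self.min_length or length > self.max_length:
                    tally.filtered_length += 1
                    continue
                chrom = read.reference_name
                gc_cnt, n_cnt = self.genome.gc_count(chrom, start, end)
                non_n = length - n_cnt
                gc = gc_cnt / non_n if non_n else math.nan
                weight = 1.0
                if self.weight_tag is not None and read.has_tag(self.weight_tag):
                    weight = float(read.get_tag(self.weight_tag))
                tally.emitted += 1
                yield FragmentRecord(
                    chrom,
                    start,
                    end,
                    gc=gc,
                    n_fraction=n_cnt / length,
                    mapq=read.mapping_quality,
                    duplicate=read.is_duplicate,
                    weight=weight,
                )


def iterate_fragments(
    path: str | Path,
    genome: GenomeSequence,
    min_mapq: int = 20,
    min_length: int = 30,
    max_length: int = 500,
    drop_duplicates: bool = True,
    weight_tag: str | None = None,
) -> FragmentStream:
    """Convenience constructor for :class:`FragmentStream`."""
    return FragmentStream(
        path,
        genome,
        min_mapq=min_mapq,
        min_length=min_length,
        max_length=max_length,
        drop_duplicates=drop_duplicates,
        weight_tag=weight_tag,
    )
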