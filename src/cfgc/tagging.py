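"""Attach correction weights to alignments as auxiliary tags.

Tagging never alters coordinates, flags, sequence, or qualities and never
drops a record, so the original read coverage and fragmentation patterns are
preserved; downstream tools simply multiply by the tag.  Both mates of a pair
carry the identical fragment weight, derived from the fragment's (length,
reference GC) — the same basis the model was estimated on.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import pysam

from .errors import InputContractError
from .gc_model import CorrectionModel
from .refio import GenomeSequence

_SAM_TAG_TYPES = set("AifZHB")


@dataclass(frozen=True)
class TagPolicy:
    """How the weight tag is written.

    ``tag_name`` must satisfy the SAM auxiliary-tag grammar (two characters,
    letter first).  Records that form no valid fragment receive
    ``untaggable_weight`` so every record carries the tag.
    """

    tag_name: str = "GW"
    untaggable_weight: float = 1.0

    def __post_init__(self):
        if len(self.tag_name) != 2 or not self.tag_name[0].isalpha():
            raise ValueError(f"invalid SAM tag code {self.tag_name!r}")


@dataclass
class TagTally:
    tagged: int = 0
    defaulted: int = 0
    overwritten: int = 0

    @property
    def total(self) -> int:
        return self.tagged + self.defaulted

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "tagged": self.tagged,
                    "defaulted": self.defaulted,
                    "overwritten": self.overwritten,
                    "total": self.total,
                },
                fh,
                indent=2,
            )


def _open_alignments(path: str, mode_read: bool) -> pysam.AlignmentFile:
    path = str(path)
    if path.endswith(".sam"):
        return pysam.AlignmentFile(path, "r" if mode_read else "wh")
    raise ValueError("caller must pass template for BAM output")


def _fragment_interval(read: pysam.AlignedSegment) -> tuple[int, int] | None:
    """Fragment interval for a primary record, or None if untaggable.

    Proper pairs: ``[min(pos, mate pos), + |TLEN|)`` — both mates agree
    without any buffering, so a single streaming pass suffices.
    """
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return None
    if not read.is_paired:
        return read.reference_start, read.reference_end
    if read.mate_is_unmapped or read.reference_id != read.next_reference_id:
        return None
    tlen = abs(read.template_length)
    if tlen == 0:
        return None
    start = min(read.reference_start, read.next_reference_start)
    return start, start + tlen


def tag_alignments(
    bam_in: str | Path,
    bam_out: str | Path,
    model: CorrectionModel,
    genome: GenomeSequence,
    policy: TagPolicy = TagPolicy(),
) -> TagTally:
    """Write every input record back out with a fragment-weight tag.

    Output record count equals input record count; records that form no
    valid fragment (unmapped, mate-unmapped, cross-chromosome pairs,
    secondary/supplementary) receive ``policy.untaggable_weight``.  A
    pre-existing tag with the same code is overwritten and counted.
    """
    bam_in, bam_out = str(bam_in), str(bam_out)
    tally = TagTally()
    read_mode = "r" if bam_in.endswith(".sam") else "rb"
    with pysam.AlignmentFile(bam_in, read_mode) as src:
        so = (src.header.get("HD") or {}).get("SO")
        if so not in (None, "coordinate"):
            raise InputContractError(f"{bam_in}: expected coordinate-sorted input")
        write_mode = "wh" if bam_out.endswith(".sam") else "wb"
        with pysam.AlignmentFile(bam_out, write_mode, template=src) as dst:
            for read in src.fetch(until_eof=True):
                if read.has_tag(policy.tag_name):
                    tally.overwritten += 1
                interval = _fragment_interval(read)
                if interval is None:
                    weight = policy.untaggable_weight
                    tally.defaulted += 1
                else:
                    start, end = interval
                    chrom = read.reference_name
                    length = end - start
                    gc_cnt, n_cnt = genome.gc_count(chrom, start, end)
                    non_n = length - n_cnt
                    gc = gc_cnt / non_n if non_n else math.nan
                    weight = float(model.lookup(length, gc))
                    tally.tagged += 1
                read.set_tag(policy.tag_name, weight, value_type="f")
                dst.write(read)
    return tally


def filter_by_length(
    bam_in: str | Path, bam_out: str | Path, min_length: int
) -> TagTally:
    """Drop records whose aligned query length is below ``min_length``.

    Pairs lose both mates when either fails, so no orphan mates survive.
    Returns a tally whose ``defaulted`` field counts dropped records.
    """
    bam_in, bam_out = str(bam_in), str(bam_out)
    read_mode = "r" if bam_in.endswith(".sam") else "rb"
    doomed: set[str] = set()
    with pysam.AlignmentFile(bam_in, read_mode) as src:
        for read in src.fetch(until_eof=True):
            qlen = read.query_alignment_length or 0
            if qlen < min_length:
                doomed.add(read.query_name)
    tally = TagTally()
    with pysam.AlignmentFile(bam_in, read_mode) as src:
        write_mode = "wh" if bam_out.endswith(".sam") else "wb"
        with pysam.AlignmentFile(bam_out, write_mode, template=src) as dst:
            for read in src.fetch(until_eof=True):
                if read.query_name in doomed:
                    tally.defaulted += 1
                else:
                    tally.tagged += 1
                    dst.write(read)
    return tally
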