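"""Targeted pileup by direct CIGAR traversal.

For a single reference coordinate, every overlapping read is inspected by
walking its CIGAR string with parallel reference and query cursors.  The walk
reports what the read shows at that coordinate: an aligned base with its
quality, a deletion, and optionally an insertion sitting immediately before
the coordinate (insertions between reference positions ``p`` and ``p+1`` are
attributed to ``p+1``).

All coordinates in this module's public API are 1-based; the conversion to
pysam's 0-based convention happens only inside :func:`collect_observations`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pysam

log = logging.getLogger(__name__)

#: SAM/FASTQ quality encoding offset (Sanger / Illumina 1.8+).
QUALITY_OFFSET = 33

#: pysam numeric CIGAR operation codes, in order.
CIGAR_OPS = "MIDNSHP=X"

_VALID_OPS = frozenset(CIGAR_OPS)


class EncodingError(ValueError):
    """An ASCII-coded quality character below the encoding offset."""


class MalformedCigarError(ValueError):
    """A CIGAR containing an operation outside M/I/D/N/S/H/P/=/X."""


def decode_quality(q: Union[int, str]) -> int:
    """Convert an ASCII-coded quality to a Phred score (code − 33).

    Accepts either a single character or its integer character code.
    ASCII 50 ('2') decodes to Phred 17, ASCII 58 (':') to 25.
    """
    code = ord(q) if isinstance(q, str) else int(q)
    if code < QUALITY_OFFSET:
        raise EncodingError(f"ASCII code {code} below quality offset {QUALITY_OFFSET}")
    return code - QUALITY_OFFSET


def encode_quality(phred: int) -> int:
    """Inverse of :func:`decode_quality`: Phred score to ASCII code."""
    if phred < 0:
        raise EncodingError(f"negative Phred score {phred}")
    return phred + QUALITY_OFFSET


@dataclass(frozen=True)
class AlignedRead:
    """A mapped read reduced to the fields the CIGAR walk needs.

    ``ref_start`` is the 1-based leftmost aligned reference position.
    ``cigar`` is a sequence of ``(op, length)`` pairs with ``op`` one of
    M/I/D/N/S/H/P/=/X.  ``query_qualities`` are Phred integers, one per
    query base.
    """

    query_name: str
    ref_start: int
    cigar: tuple
    query_sequence: str
    query_qualities: tuple
    mapping_quality: int = 0

    def reference_span(self) -> tuple:
        """1-based inclusive (start, end) of the aligned reference span."""
        ref_len = sum(ln for op, ln in self.cigar if op in "MDN=X")
        return self.ref_start, self.ref_start + ref_len - 1


@dataclass(frozen=True)
class Observation:
    """What one read shows at one target position.

    ``kind`` is ``"base"`` or ``"deletion"``.  A single observation may
    additionally carry an insertion that sits immediately before the
    position (``inserted_seq`` / ``inserted_quals``), so base counts and
    insertion counts stay independent.
    """

    kind: str
    read_name: str = ""
    base: Optional[str] = None
    base_quality: Optional[int] = None
    inserted_seq: Optional[str] = None
    inserted_quals: Optional[tuple] = None

    def __post_init__(self):
        if self.kind == "base" and (self.base is None or self.base_quality is None):
            raise ValueError("base observation requires base and base_quality")
        if self.kind == "deletion" and self.base is not None:
            raise ValueError("deletion observation carries no base")
        if self.inserted_seq is not None:
            if self.inserted_quals is None or len(self.inserted_quals) != len(self.inserted_seq):
                raise ValueError("inserted_quals must match inserted_seq length")

    @property
    def has_insertion(self) -> bool:
        return self.inserted_seq is not None


def observe_read_at(read: AlignedRead, pos: int) -> Optional[Observation]:
    """Walk the read's CIGAR and report what it shows at ``pos`` (1-based).

    M/=/X consume reference and query and yield a base; D consumes reference
    and yields a deletion; I consumes query and, when it sits between
    reference positions ``pos−1`` and ``pos``, is attached to the
    observation at ``pos``; S consumes query only; H and P consume nothing;
    N (spliced skip) consumes reference and makes the position uncovered.
    Returns ``None`` when the read does not cover the position with an
    aligned base or deletion.
    """
    ref_pos = read.ref_start
    q = 0
    kind = None
    base = None
    base_quality = None
    inserted_seq = None
    inserted_quals = None

    for op, length in read.cigar:
        if op not in _VALID_OPS:
            raise MalformedCigarError(f"unknown CIGAR operation {op!r} in read {read.query_name}")
        if op in "M=X":
            if ref_pos <= pos < ref_pos + length:
                off = pos - ref_pos
                kind = "base"
                base = read.query_sequence[q + off]
                base_quality = read.query_qualities[q + off]
            ref_pos += length
            q += length
        elif op == "I":
            if ref_pos == pos:
                inserted_seq = read.query_sequence[q:q + length]
                inserted_quals = tuple(read.query_qualities[q:q + length])
            q += length
        elif op == "D":
            if ref_pos <= pos < ref_pos + length:
                kind = "deletion"
            ref_pos += length
        elif op == "N":
            if ref_pos <= pos < ref_pos + length:
                return None
            ref_pos += length
        elif op == "S":
            q += length
        # H and P consume nothing
        if ref_pos > pos and kind is not None:
            break

    if kind is None:
        # An insertion with no flanking aligned base/deletion at pos (read
        # ending in I) leaves the position uncovered.
        return None
    return Observation(
        kind=kind,
        read_name=read.query_name,
        base=base,
        base_quality=base_quality,
        inserted_seq=inserted_seq,
        inserted_quals=inserted_quals,
    )


def read_from_pysam(seg: pysam.AlignedSegment) -> AlignedRead:
    """Convert a pysam record to the light-weight :class:`AlignedRead`."""
    cigar = tuple((CIGAR_OPS[code], ln) for code, ln in (seg.cigartuples or ()))
    seq = seg.query_sequence or ""
    quals = tuple(seg.query_qualities) if seg.query_qualities is not None else (0,) * len(seq)
    return AlignedRead(
        query_name=seg.query_name or "",
        ref_start=seg.reference_start + 1,
        cigar=cigar,
        query_sequence=seq,
        query_qualities=quals,
        mapping_quality=seg.mapping_quality,
    )


def collect_observations(
    alignment: Union[str, Path, pysam.AlignmentFile],
    chrom: str,
    pos: int,
    mq_threshold: int = 0,
) -> list:
    """One :class:`Observation` per retained read covering ``pos`` (1-based).

    Unmapped, duplicate-flagged and secondary/supplementary records are
    dropped, as are reads with ``mapping_quality < mq_threshold`` (a read
    exactly at the threshold is kept).  A contig absent from the alignment
    header yields an empty list with a logged warning, so uncovered targets
    degrade gracefully.
    """
    own_handle = not isinstance(alignment, pysam.AlignmentFile)
    af = pysam.AlignmentFile(str(alignment)) if own_handle else alignment
    try:
        if chrom not in af.references:
            log.warning("contig %s absent from alignment header; position %s uncovered", chrom, pos)
            return []
        observations = []
        for seg in af.fetch(chrom, pos - 1, pos):
            if seg.is_unmapped or seg.is_duplicate or seg.is_secondary or seg.is_supplementary:
                continue
            if seg.mapping_quality < mq_threshold:
                continue
            if seg.cigartuples is None:
                continue
            try:
                obs = observe_read_at(read_from_pysam(seg), pos)
            except MalformedCigarError as exc:
                log.warning("skipping read: %s", exc)
                continue
            if obs is not None:
                observations.append(obs)
        return observations
    finally:
        if own_handle:
            af.close()
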