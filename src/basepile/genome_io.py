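"""Reference-genome and VCF access.

The reference is an indexed FASTA (pyfaidx builds the .fai on first open).
Known polymorphisms (e.g. a dbSNP extract) and per-sample caller output are
plain or bgzipped VCF; only records relevant to the target positions are
retained.  Records failing FILTER are kept on purpose — the whole point of
this tool is inspecting evidence at sites a caller filtered away.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pyfaidx
import pysam

log = logging.getLogger(__name__)


class ReferenceLookupError(LookupError):
    """Unknown contig or out-of-range position in the reference."""


class VcfFormatError(ValueError):
    """Unreadable or malformed VCF input."""


@dataclass(frozen=True)
class KnownVariant:
    """A catalogued polymorphism at a position (alleles stored uppercase)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple


@dataclass(frozen=True)
class CalledVariant:
    """A caller-reported variant with its assigned genotype.

    ``genotype`` is a pair of allele indices (0 = reference); phased and
    unphased separators are treated alike.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple
    genotype: tuple

    def __post_init__(self):
        n_alleles = 1 + len(self.alt_alleles)
        for idx in self.genotype:
            if not 0 <= idx < n_alleles:
                raise ValueError(f"genotype index {idx} out of range for {n_alleles} alleles")


def open_reference(path: Union[str, Path]) -> pyfaidx.Fasta:
    """Open an indexed FASTA (building the .fai index when absent)."""
    return pyfaidx.Fasta(str(path))


def fetch_reference_base(reference, chrom: str, pos: int) -> str:
    """Uppercase reference base at a 1-based coordinate."""
    fasta = reference if isinstance(reference, pyfaidx.Fasta) else open_reference(reference)
    if chrom not in fasta:
        raise ReferenceLookupError(f"contig {chrom!r} not in reference")
    contig = fasta[chrom]
    if not 1 <= pos <= len(contig):
        raise ReferenceLookupError(f"position {pos} outside {chrom} (length {len(contig)})")
    return str(contig[pos - 1]).upper()


def _iter_vcf(path: Union[str, Path]):
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfFormatError(f"cannot read VCF {path}: {exc}") from exc
    with vcf:
        yield from vcf


def _clean_alts(rec) -> Optional[tuple]:
    """Uppercase ALT alleles, or None when symbolic/breakend alleles occur."""
    if not rec.alts:
        return None
    alts = []
    for a in rec.alts:
        if a is None or any(c in a for c in "<>[]*"):
            return None
        alts.append(a.upper())
    return tuple(alts)


def load_known_variants(vcf: Union[str, Path], targets) -> dict:
    """Known variants keyed by (chrom, pos), restricted to target positions.

    Multi-allelic records are kept intact; symbolic alleles are skipped with
    a warning rather than guessed at.
    """
    wanted = {(t.chrom, t.pos) for t in targets}
    out: dict = {}
    for rec in _iter_vcf(vcf):
        key = (rec.chrom, rec.pos)
        if key not in wanted:
            continue
        alts = _clean_alts(rec)
        if alts is None:
            log.warning("skipping symbolic/empty ALT at %s:%s", rec.chrom, rec.pos)
            continue
        out.setdefault(key, []).append(
            KnownVariant(rec.chrom, rec.pos, rec.ref.upper(), alts)
        )
    return out


def load_sample_calls(vcf: Union[str, Path], targets) -> dict:
    """Caller records relevant to the targets, keyed by their own (chrom, pos).

    A record is relevant when its REF span touches a target or when it can
    anchor an insertion displayed at the following position, i.e. when
    ``rec.pos <= target_pos <= rec.pos + len(REF)``.  The genotype comes from
    the first sample column; records without a usable GT are skipped with a
    warning and the variant is treated as absent.
    """
    by_chrom: dict = {}
    for t in targets:
        by_chrom.setdefault(t.chrom, set()).add(t.pos)
    out: dict = {}
    for rec in _iter_vcf(vcf):
        positions = by_chrom.get(rec.chrom)
        if not positions:
            continue
        alts = _clean_alts(rec)
        if alts is None:
            log.warning("skipping symbolic/empty ALT at %s:%s", rec.chrom, rec.pos)
            continue
        span = len(rec.ref)
        if not any(rec.pos <= p <= rec.pos + span for p in positions):
            continue
        if not rec.samples:
            log.warning("no sample column at %s:%s; record skipped", rec.chrom, rec.pos)
            continue
        gt = rec.samples[0].get("GT")
        if gt is None or any(a is None for a in gt):
            log.warning("missing GT at %s:%s; record skipped", rec.chrom, rec.pos)
            continue
        out[(rec.chrom, rec.pos)] = CalledVariant(
            rec.chrom, rec.pos, rec.ref.upper(), alts, tuple(int(a) for a in gt)
        )
    return out
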