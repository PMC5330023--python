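"""Synthetic alignment generator for exercising the full pipeline.

Builds coordinate-sorted, indexed BAM files (plus matching reference FASTA
and minimal VCF snippets) entirely in memory: each read is 50 bp, copies the
reference around one target position, and carries exactly one event there —
a matched or substituted base, a deletion, or additionally an insertion
anchored just before the position.  Per-read categories are drawn
multinomially from user-given fractions, insertion flags independently, and
qualities from a clamped normal model per category, so a fixed seed yields
byte-identical files.

This deliberately models composition, not sequencing chemistry: no error
profiles, no fragment-size model, single-ended reads of one length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pysam

from .pileup_engine import AlignedRead

READ_LENGTH = 50
_EVENT_OFFSET = 25  # aligned reference bases before the target position

DEFAULT_QUALITY_MODEL = {"default": (35.0, 3.0)}


@dataclass(frozen=True)
class CompositionSpec:
    """The exact read composition to synthesize at one position.

    ``base_fractions`` maps A/C/G/T/deletion to fractions summing to one;
    ``insertion_fraction`` is an independent per-read probability of an
    insertion of ``inserted_seq`` immediately before ``pos`` (insertions are
    additional events, mirroring how the pileup tallies them).
    ``quality_model`` maps category (or ``"default"``) to a (mean Phred,
    spread) pair.
    """

    chrom: str
    pos: int
    coverage: int
    base_fractions: dict
    insertion_fraction: float = 0.0
    inserted_seq: str = "G"
    quality_model: dict = field(default_factory=lambda: dict(DEFAULT_QUALITY_MODEL))
    mq: int = 60
    seed: int = 0

    def validate(self) -> "CompositionSpec":
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        total = sum(self.base_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"base_fractions must sum to 1, got {total}")
        for k, v in self.base_fractions.items():
            if k not in ("A", "C", "G", "T", "deletion"):
                raise ValueError(f"unknown category {k!r}")
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"fraction {v} for {k!r} outside [0, 1]")
        if not 0.0 <= self.insertion_fraction <= 1.0:
            raise ValueError("insertion_fraction outside [0, 1]")
        if self.insertion_fraction > 0 and not self.inserted_seq:
            raise ValueError("insertion_fraction > 0 requires inserted_seq")
        return self


def random_reference(length: int, seed: int) -> str:
    """Deterministic random nucleotide sequence."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


def _draw_quals(rng, model, category, n):
    mean, sd = model.get(category, model.get("default", (35.0, 3.0)))
    q = np.rint(rng.normal(mean, sd, size=n))
    return tuple(int(v) for v in np.clip(q, 0, 60))


def simulate_position_reads(spec: CompositionSpec, reference: Optional[str] = None) -> list:
    """Generate 50 bp reads realizing the spec's composition at its position.

    Every read starts ``_EVENT_OFFSET`` reference bases before ``pos``;
    base reads are pure matches (50M) with the category base substituted at
    the position, deletion reads carry ``25M 1D 25M``, and insertion-flagged
    reads splice ``len(inserted_seq)I`` between the flanks.  ``reference``
    defaults to a seed-derived random sequence long enough for every read.
    """
    spec.validate()
    if spec.coverage == 0:
        return []
    rng = np.random.default_rng(spec.seed)
    needed = spec.pos + READ_LENGTH + 2
    if reference is None:
        reference = random_reference(needed, spec.seed)
    if len(reference) < needed:
        raise ValueError(f"reference too short: need {needed} bases, got {len(reference)}")
    if spec.pos <= _EVENT_OFFSET:
        raise ValueError(f"pos must exceed {_EVENT_OFFSET} so reads fit before it")

    categories = ("A", "C", "G", "T", "deletion")
    probs = [spec.base_fractions.get(c, 0.0) for c in categories]
    counts = rng.multinomial(spec.coverage, probs)
    per_read_cat = [c for c, n in zip(categories, counts) for _ in range(n)]
    ins_flags = rng.random(spec.coverage) < spec.insertion_fraction

    ref_start = spec.pos - _EVENT_OFFSET  # 1-based; event at index _EVENT_OFFSET
    left = reference[ref_start - 1: spec.pos - 1]            # 25 bases before pos
    ref_base = reference[spec.pos - 1]
    reads = []
    for i, (cat, has_ins) in enumerate(zip(per_read_cat, ins_flags)):
        ins = spec.inserted_seq if has_ins else ""
        if cat == "deletion":
            right_len = READ_LENGTH - _EVENT_OFFSET - len(ins)
            right = reference[spec.pos: spec.pos + right_len]  # bases after pos
            seq = left + ins + right
            cigar = [("M", _EVENT_OFFSET)]
            if ins:
                cigar.append(("I", len(ins)))
            cigar += [("D", 1), ("M", right_len)]
        else:
            right_len = READ_LENGTH - _EVENT_OFFSET - 1 - len(ins)
            right = reference[spec.pos: spec.pos + right_len]
            seq = left + ins + cat + right
            if ins:
                cigar = [("M", _EVENT_OFFSET), ("I", len(ins)), ("M", right_len + 1)]
            else:
                cigar = [("M", READ_LENGTH)]
        cigar_tuples = tuple(cigar)

        quals = list(_draw_quals(rng, spec.quality_model, "default", len(seq)))
        event_q = _draw_quals(rng, spec.quality_model, cat, 1)
        if cat != "deletion":
            quals[_EVENT_OFFSET + len(ins)] = event_q[0]
        if ins:
            iq = _draw_quals(rng, spec.quality_model, "insertion", len(ins))
            quals[_EVENT_OFFSET:_EVENT_OFFSET + len(ins)] = list(iq)

        reads.append(
            AlignedRead(
                query_name=f"sim{i:06d}",
                ref_start=ref_start,
                cigar=cigar_tuples,
                query_sequence=seq,
                query_qualities=tuple(quals),
                mapping_quality=spec.mq,
            )
        )
    return reads


def write_reference_fixture(reference: str, directory, chrom: str = "t") -> Path:
    """Write an indexed single-contig FASTA."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fasta = directory / "reference.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(reference), 60):
            fh.write(reference[i:i + 60] + "\n")
    pysam.faidx(str(fasta))
    return fasta


def write_alignment_fixture(
    reads,
    reference_seq: str,
    directory,
    chrom: str = "t",
    sample: str = "sample",
) -> tuple:
    """Write reads as a coordinate-sorted indexed BAM plus indexed FASTA.

    Returns ``(bam_path, bai_path, fasta_path)``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fasta = write_reference_fixture(reference_seq, directory, chrom)
    bam = directory / f"{sample}.bam"
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": len(reference_seq)}],
    }
    op_code = {op: i for i, op in enumerate("MIDNSHP=X")}
    with pysam.AlignmentFile(str(bam), "wb", header=header) as out:
        for read in sorted(reads, key=lambda r: (r.ref_start, r.query_name)):
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = read.query_name
            seg.reference_id = 0
            seg.reference_start = read.ref_start - 1
            seg.mapping_quality = read.mapping_quality
            seg.cigartuples = [(op_code[op], ln) for op, ln in read.cigar]
            seg.query_sequence = read.query_sequence
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in read.query_qualities)
            )
            seg.flag = 0
            out.write(seg)
    pysam.index(str(bam))
    return bam, Path(str(bam) + ".bai"), fasta


def write_vcf_fixture(records, path, sample: Optional[str] = None) -> Path:
    """Write a minimal plain-text VCF.

    ``records`` are ``(chrom, pos, ref, alts, gt)`` tuples; ``gt`` (e.g.
    ``"0/1"``) and the sample column are emitted only when ``sample`` is
    given.
    """
    path = Path(path)
    lines = ["##fileformat=VCFv4.2"]
    contigs = sorted({r[0] for r in records})
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    if sample:
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}")
    else:
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for chrom, pos, ref, alts, *rest in records:
        alt = ",".join(alts) if not isinstance(alts, str) else alts
        row = f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t."
        if sample:
            gt = rest[0] if rest else "0/1"
            row += f"\tGT\t{gt}"
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")
    return path
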