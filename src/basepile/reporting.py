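"""Textual reports: per-read bases with qualities, counts, frequencies.

Three tab-separated UTF-8 files per sample, each with a single header line.
Missing values are rendered as ``.`` (VCF convention).  Frequencies print at
two decimal places; full precision stays internal.
"""

from __future__ import annotations

from pathlib import Path

from .aggregation import ALL_CATEGORIES, PositionRecord

MISSING = "."

QUALITY_COLUMNS = (
    "sample", "chrom", "pos", "occurrence", "read_name",
    "category", "base", "base_quality", "inserted_seq", "inserted_quals",
)
COUNT_COLUMNS = (
    "sample", "chrom", "pos", "occurrence",
    "A", "C", "G", "T", "N", "deletion", "insertion", "excluded", "depth",
)
FREQUENCY_COLUMNS = (
    "sample", "chrom", "pos", "occurrence",
    "A", "C", "G", "T", "N", "deletion", "insertion", "calls",
)


def _write_rows(path, header, rows) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    return path


def write_quality_report(records, path) -> Path:
    """One row per retained observation: what each read shows, with quality."""
    rows = []
    for rec in records:
        t = rec.target
        for obs in rec.observations:
            rows.append((
                rec.sample, t.chrom, t.pos, t.occurrence_index,
                obs.read_name or MISSING,
                obs.kind,
                obs.base if obs.base is not None else MISSING,
                obs.base_quality if obs.base_quality is not None else MISSING,
                obs.inserted_seq if obs.inserted_seq is not None else MISSING,
                ",".join(str(q) for q in obs.inserted_quals) if obs.inserted_quals else MISSING,
            ))
    return _write_rows(path, QUALITY_COLUMNS, rows)


def write_count_report(records, path) -> Path:
    """One row per (sample, target) with absolute tallies; zero-depth rows kept."""
    rows = []
    for rec in records:
        t = rec.target
        rows.append(
            (rec.sample, t.chrom, t.pos, t.occurrence_index)
            + tuple(rec.counts.get(c) for c in ALL_CATEGORIES)
            + (rec.counts.excluded, rec.counts.depth)
        )
    return _write_rows(path, COUNT_COLUMNS, rows)


def format_calls(calls) -> str:
    """Render a call list as ``cat1:freq1;cat2:freq2;…`` or ``.``."""
    if not calls:
        return MISSING
    return ";".join(f"{c}:{f:.2f}" for c, f in calls)


def format_caller_record(rec) -> str:
    """Render a caller's record as ``REF>ALT,… GT`` (e.g. ``A>AG 0/1``)."""
    if rec is None:
        return MISSING
    alts = ",".join(rec.alt_alleles)
    gt = "/".join(str(i) for i in rec.genotype)
    return f"{rec.ref_allele}>{alts} {gt}"


def write_frequency_report(records, path) -> Path:
    """Relative frequencies (2 d.p.) and derived calls per (sample, target).

    When any record carries caller output, an extra ``caller_call`` column
    renders the caller's alleles and genotype.
    """
    with_caller = any(rec.caller_record is not None for rec in records)
    header = FREQUENCY_COLUMNS + (("caller_call",) if with_caller else ())
    rows = []
    for rec in records:
        t = rec.target
        row = (
            (rec.sample, t.chrom, t.pos, t.occurrence_index)
            + tuple(f"{rec.frequencies.freq.get(c, 0.0):.2f}" for c in ALL_CATEGORIES)
            + (format_calls(rec.calls),)
        )
        if with_caller:
            row += (format_caller_record(rec.caller_record),)
        rows.append(row)
    return _write_rows(path, header, rows)


def write_sample_reports(records, output_dir, sample: str) -> dict:
    """Write the three per-sample TXT reports; returns name → path."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return {
        "bases": write_quality_report(records, out / f"{sample}_bases.txt"),
        "counts": write_count_report(records, out / f"{sample}_counts.txt"),
        "frequencies": write_frequency_report(records, out / f"{sample}_frequencies.txt"),
    }
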