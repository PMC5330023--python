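"""Run configuration: target lists, sample sheets and thresholds.

Targets are given as a whitespace/tab-separated text with columns
``chrom start [end]`` (1-based inclusive; lines starting with ``#`` are
ignored).  A coordinate listed more than once gets consecutive
``occurrence_index`` values: occurrence *k* is how multi-base insertions are
displayed (the *k*-th inserted base), so duplicates are preserved, never
merged.

The sample sheet holds one sample name per line; alignment files are
discovered as ``<base_dir>/<name>.bam`` with index ``<name>.bam.bai``
(fallback ``<name>.bai``) and optional per-sample calls as ``<name>.vcf``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional


class ConfigError(ValueError):
    """Invalid run configuration (missing files, violated invariants)."""


class TargetParseError(ConfigError):
    """Unparseable target list line."""


@dataclass(frozen=True)
class TargetPosition:
    chrom: str
    pos: int
    occurrence_index: int = 1

    def __post_init__(self):
        if self.pos < 1:
            raise ConfigError(f"pos must be >= 1, got {self.pos}")
        if self.occurrence_index < 1:
            raise ConfigError(f"occurrence_index must be >= 1, got {self.occurrence_index}")


@dataclass(frozen=True)
class TargetRegion:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ConfigError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    def positions(self) -> list:
        return [TargetPosition(self.chrom, p) for p in range(self.start, self.end + 1)]


@dataclass(frozen=True)
class SampleSet:
    names: tuple
    alignment_paths: tuple
    index_paths: tuple
    calls_vcf_paths: tuple = ()  # one entry per sample; None where absent

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        calls = self.calls_vcf_paths or (None,) * len(self.names)
        return iter(zip(self.names, self.alignment_paths, self.index_paths, calls))


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and output options for one run.

    ``bq_threshold`` and the quality bounds are ASCII character codes
    (Phred + 33), following the SAM text encoding; ``mq_threshold`` is a
    plain mapping-quality floor.  ``marks`` are fractions at which
    horizontal guide lines are drawn across the plots.
    """

    mq_threshold: int = 0
    bq_threshold: int = 33
    frequency_threshold: float = 0.0
    quality_lower_bound: int = 53
    quality_upper_bound: int = 73
    marks: tuple = ()
    plot_mode: str = "per_sample"
    count_mode: str = "relative"
    output_dir: Optional[Path] = None


def _assign_occurrences(positions: list) -> list:
    seen: dict = {}
    out = []
    for tp in positions:
        key = (tp.chrom, tp.pos)
        seen[key] = seen.get(key, 0) + 1
        out.append(TargetPosition(tp.chrom, tp.pos, seen[key]))
    return out


def parse_target_spec(text: str) -> list:
    """Parse a target description into an ordered list of positions.

    Regions expand position-by-position; duplicates are preserved with
    increasing ``occurrence_index`` in input order.
    """
    positions = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) not in (2, 3):
            raise TargetParseError(f"line {lineno}: expected 'chrom start [end]', got {raw!r}")
        chrom = fields[0]
        try:
            coords = [int(f) for f in fields[1:]]
        except ValueError:
            raise TargetParseError(f"line {lineno}: non-integer coordinate in {raw!r}") from None
        if len(coords) == 1:
            positions.append(TargetPosition(chrom, coords[0]))
        else:
            start, end = coords
            if end < start:
                raise TargetParseError(f"line {lineno}: end {end} < start {start}")
            positions.extend(TargetRegion(chrom, start, end).positions())
    return _assign_occurrences(positions)


def format_target_spec(targets: list) -> str:
    """Serialize targets back to the text format (one position per line)."""
    return "\n".join(f"{t.chrom}\t{t.pos}" for t in targets) + ("\n" if targets else "")


def parse_sample_sheet(text: str, base_dir) -> SampleSet:
    """Resolve a sample sheet against ``base_dir`` by name-based discovery.

    Every sample must have an existing ``<name>.bam`` and a companion index;
    ``<name>.vcf`` is picked up as that sample's calls when present.
    """
    base = Path(base_dir)
    names = []
    for raw in text.splitlines():
        name = raw.strip()
        if not name or name.startswith("#"):
            continue
        if name in names:
            raise ConfigError(f"duplicate sample name {name!r}")
        names.append(name)
    if not names:
        raise ConfigError("no samples in sample sheet")

    alignments, indexes, calls = [], [], []
    for name in names:
        bam = base / f"{name}.bam"
        if not bam.exists():
            raise ConfigError(f"missing alignment file: {bam}")
        bai = base / f"{name}.bam.bai"
        if not bai.exists():
            fallback = base / f"{name}.bai"
            if fallback.exists():
                bai = fallback
            else:
                raise ConfigError(f"missing alignment index: {bai}")
        vcf = base / f"{name}.vcf"
        alignments.append(bam)
        indexes.append(bai)
        calls.append(vcf if vcf.exists() else None)
    return SampleSet(tuple(names), tuple(alignments), tuple(indexes), tuple(calls))


def validate_config(config: RunConfig) -> RunConfig:
    """Check every invariant; return the config unchanged when all hold."""
    if not 0.0 <= config.frequency_threshold <= 1.0:
        raise ConfigError(f"frequency_threshold must be in [0, 1], got {config.frequency_threshold}")
    if config.quality_lower_bound >= config.quality_upper_bound:
        raise ConfigError(
            f"quality_lower_bound {config.quality_lower_bound} must be below "
            f"quality_upper_bound {config.quality_upper_bound}"
        )
    if config.bq_threshold < 33:
        raise ConfigError(f"bq_threshold is an ASCII code and must be >= 33, got {config.bq_threshold}")
    if config.mq_threshold < 0:
        raise ConfigError(f"mq_threshold must be >= 0, got {config.mq_threshold}")
    for m in config.marks:
        if not 0.0 <= m <= 1.0:
            raise ConfigError(f"mark {m} outside [0, 1]")
    if config.plot_mode not in ("per_sample", "per_position"):
        raise ConfigError(f"plot_mode must be per_sample or per_position, got {config.plot_mode!r}")
    if config.count_mode not in ("absolute", "relative"):
        raise ConfigError(f"count_mode must be absolute or relative, got {config.count_mode!r}")
    return config
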