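"""Per-position tallies, frequencies, calls and genotype-derived expectations.

The frequency denominator is the number of reads spanning the position with
an aligned base or deletion, after base-quality exclusion; insertions are
extra events on those same reads and are NOT added to the denominator.  The
insertion frequency can therefore legitimately coexist with base/deletion
frequencies that already sum to one.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .config_io import RunConfig, TargetPosition
from .genome_io import (
    CalledVariant,
    ReferenceLookupError,
    fetch_reference_base,
)
from .pileup_engine import QUALITY_OFFSET, Observation, collect_observations

log = logging.getLogger(__name__)

#: Base categories tallied per position; N is counted but never called.
BASES = ("A", "C", "G", "T", "N")

#: All event categories, in the fixed tie-break order used for calls.
CATEGORIES = ("A", "C", "G", "T", "deletion", "insertion")

#: Column order used by reports and plots.
ALL_CATEGORIES = BASES + ("deletion", "insertion")


@dataclass
class PositionCounts:
    """Aggregated tallies for one position.

    ``depth`` counts reads with a retained aligned base or deletion;
    ``excluded`` counts base observations (and insertion events, by mean
    inserted-base quality) that failed the base-quality threshold.
    """

    counts: dict = field(default_factory=dict)
    excluded: int = 0
    insertion_alleles: dict = field(default_factory=dict)
    mean_quality: dict = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(self.counts.get(b, 0) for b in BASES) + self.counts.get("deletion", 0)

    def get(self, category: str) -> int:
        return self.counts.get(category, 0)


@dataclass(frozen=True)
class FrequencyTable:
    """Event fractions over the spanning-read denominator."""

    freq: dict
    denominator: int


@dataclass(frozen=True)
class ExpectedCounts:
    """Genotype-implied read counts at a call's anchor position.

    Each genotype allele contributes ``depth / ploidy`` to its category; an
    insertion allele additionally contributes to ``insertion``, displayed at
    the position following the anchor.
    """

    expected: dict
    source_genotype: tuple


def tally_position(observations, bq_threshold: int) -> PositionCounts:
    """Aggregate one position's observations under a base-quality floor.

    ``bq_threshold`` is an ASCII code; a base with Phred quality below
    ``bq_threshold − 33`` increments ``excluded`` instead of its category.
    Deletions carry no quality and are never excluded.  Insertion events are
    tallied independently of the flanking base, except that an insertion
    whose mean inserted-base quality falls below the floor is excluded.
    """
    phred_min = bq_threshold - QUALITY_OFFSET
    counts: Counter = Counter()
    insertion_alleles: Counter = Counter()
    excluded = 0
    qual_sum: Counter = Counter()
    qual_n: Counter = Counter()

    for obs in observations:
        if obs.kind == "base":
            b = obs.base.upper()
            if b not in BASES:
                b = "N"
            if obs.base_quality < phred_min:
                excluded += 1
            else:
                counts[b] += 1
                qual_sum[b] += obs.base_quality
                qual_n[b] += 1
        elif obs.kind == "deletion":
            counts["deletion"] += 1
        if obs.has_insertion:
            mean_iq = sum(obs.inserted_quals) / len(obs.inserted_quals)
            if mean_iq < phred_min:
                excluded += 1
            else:
                counts["insertion"] += 1
                insertion_alleles[obs.inserted_seq.upper()] += 1
                qual_sum["insertion"] += sum(obs.inserted_quals)
                qual_n["insertion"] += len(obs.inserted_quals)

    mean_quality = {c: qual_sum[c] / qual_n[c] for c in qual_n}
    return PositionCounts(
        counts=dict(counts),
        excluded=excluded,
        insertion_alleles=dict(insertion_alleles),
        mean_quality=mean_quality,
    )


def compute_frequencies(counts: PositionCounts) -> FrequencyTable:
    """Event fractions; insertions use the same spanning-read denominator."""
    depth = counts.depth
    if depth == 0:
        return FrequencyTable({c: 0.0 for c in ALL_CATEGORIES}, 0)
    freq = {c: counts.get(c) / depth for c in ALL_CATEGORIES}
    return FrequencyTable(freq, depth)


def derive_calls(freq: FrequencyTable, frequency_threshold: float) -> list:
    """Up to six calls: event categories at or above the frequency threshold.

    Sorted descending by fraction, ties broken by the fixed category order
    A < C < G < T < deletion < insertion.
    """
    rank = {c: i for i, c in enumerate(CATEGORIES)}
    passing = [
        (c, freq.freq.get(c, 0.0))
        for c in CATEGORIES
        if freq.freq.get(c, 0.0) >= frequency_threshold and freq.freq.get(c, 0.0) > 0
    ]
    passing.sort(key=lambda cf: (-cf[1], rank[cf[0]]))
    return passing


def _classify_allele(ref: str, allele: str) -> str:
    if len(allele) > len(ref):
        return "insertion"
    if len(allele) < len(ref):
        return "deletion"
    return allele[0]


def expected_counts(call: CalledVariant, depth: int) -> ExpectedCounts:
    """Genotype-implied counts at the call's anchor position.

    An SNV allele contributes to its base, a deletion allele to
    ``deletion``; an insertion allele contributes to its anchor base and,
    additionally, to ``insertion`` (displayed at the following position).
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    ploidy = len(call.genotype)
    w = depth / ploidy if ploidy else 0.0
    expected: Counter = Counter()
    for idx in call.genotype:
        allele = call.ref_allele if idx == 0 else call.alt_alleles[idx - 1]
        category = _classify_allele(call.ref_allele, allele)
        if category == "insertion":
            expected[allele[0]] += w
            expected["insertion"] += w
        else:
            expected[category] += w
    return ExpectedCounts(expected=dict(expected), source_genotype=call.genotype)


def expected_at_target(calls: dict, chrom: str, pos: int, depth: int, ref_base: str):
    """Overlay caller records onto one target position.

    Caller coordinates are left-anchored (an insertion REF A / ALT AG at
    ``p`` means inserted bases between ``p`` and ``p+1``) while this tool
    attributes insertions to the following position and deletions to the
    deleted bases themselves; this function performs that conversion.  Any
    genotype weight not covered by a record falls back to the reference
    base, so base/deletion expectations always sum to ``depth``.

    Returns ``(expected: dict, record: CalledVariant | None)``.
    """
    expected: Counter = Counter()
    covered = 0.0
    hit: Optional[CalledVariant] = None
    for (rchrom, rpos), rec in calls.items():
        if rchrom != chrom or not rpos <= pos <= rpos + len(rec.ref_allele):
            continue
        ploidy = len(rec.genotype)
        w = depth / ploidy if ploidy else 0.0
        touched = False
        for idx in rec.genotype:
            allele = rec.ref_allele if idx == 0 else rec.alt_alleles[idx - 1]
            la, lr = len(allele), len(rec.ref_allele)
            if idx == 0 or la == lr:
                if rpos <= pos < rpos + la:
                    expected[allele[pos - rpos]] += w
                    covered += w
                    touched = True
            elif la > lr:  # insertion allele
                if rpos <= pos < rpos + lr:
                    expected[allele[pos - rpos]] += w
                    covered += w
                    touched = True
                if pos == rpos + lr:
                    expected["insertion"] += w
                    touched = True
            else:  # deletion allele
                if rpos <= pos < rpos + la:
                    expected[allele[pos - rpos]] += w
                    covered += w
                    touched = True
                elif rpos + la <= pos < rpos + lr:
                    expected["deletion"] += w
                    covered += w
                    touched = True
        if touched:
            hit = rec
    if covered < depth:
        expected[ref_base] += depth - covered
    return dict(expected), hit


@dataclass
class PositionRecord:
    """Everything derived for one (sample, target) pair."""

    sample: str
    target: TargetPosition
    observations: list
    counts: PositionCounts
    frequencies: FrequencyTable
    calls: list
    ref_base: str
    known_alts: tuple = ()
    expected: Optional[dict] = None
    caller_record: Optional[CalledVariant] = None

    @property
    def insertion_display(self) -> dict:
        """Distribution of the k-th inserted base for occurrence index k.

        Occurrence 1 shows the first inserted base of every insertion;
        a duplicate listing of the same coordinate (occurrence k > 1) shows
        base k of insertions long enough to have one.
        """
        k = self.target.occurrence_index
        dist: Counter = Counter()
        for seq, n in self.counts.insertion_alleles.items():
            if len(seq) >= k:
                dist[seq[k - 1]] += n
        return dict(dist)


def summarize_sample(
    sample: str,
    alignment_path,
    targets,
    config: RunConfig,
    reference,
    known: Optional[dict] = None,
    calls: Optional[dict] = None,
) -> list:
    """Run the whole per-position derivation for one sample, in target order."""
    records = []
    for t in targets:
        observations = collect_observations(
            alignment_path, t.chrom, t.pos, config.mq_threshold
        )
        counts = tally_position(observations, config.bq_threshold)
        freqs = compute_frequencies(counts)
        call_list = derive_calls(freqs, config.frequency_threshold)
        try:
            ref_base = fetch_reference_base(reference, t.chrom, t.pos)
        except ReferenceLookupError as exc:
            log.warning("%s; using N", exc)
            ref_base = "N"
        known_alts: tuple = ()
        if known:
            known_alts = tuple(
                alt
                for kv in known.get((t.chrom, t.pos), [])
                for alt in kv.alt_alleles
            )
        expected = None
        caller_record = None
        if calls is not None:
            expected, caller_record = expected_at_target(
                calls, t.chrom, t.pos, counts.depth, ref_base
            )
        records.append(
            PositionRecord(
                sample=sample,
                target=t,
                observations=observations,
                counts=counts,
                frequencies=freqs,
                calls=call_list,
                ref_base=ref_base,
                known_alts=known_alts,
                expected=expected,
                caller_record=caller_record,
            )
        )
    return records
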