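"""Shared helpers: a naive alignment-expansion oracle and random read factory.

The oracle expands an alignment base-by-base into explicit
(reference position → what the read shows there) maps, with no cursor
arithmetic shared with the CIGAR walker it checks.
"""

from __future__ import annotations

import random

import pytest

from basepile.pileup_engine import AlignedRead, Observation


def expand_alignment(read: AlignedRead):
    """Expand a read into (ref_map, ins_map) by linear enumeration.

    ``ref_map``: ref position → ("base", query index) | ("deletion", None)
    | ("skip", None).  ``ins_map``: following ref position → (query start,
    length) of the inserted run.
    """
    ref_map, ins_map = {}, {}
    r, q = read.ref_start, 0
    for op, ln in read.cigar:
        if op in "M=X":
            for k in range(ln):
                ref_map[r + k] = ("base", q + k)
            r += ln
            q += ln
        elif op == "I":
            ins_map[r] = (q, ln)
            q += ln
        elif op == "D":
            for k in range(ln):
                ref_map[r + k] = ("deletion", None)
            r += ln
        elif op == "N":
            for k in range(ln):
                ref_map[r + k] = ("skip", None)
            r += ln
        elif op == "S":
            q += ln
        # H/P consume nothing
    return ref_map, ins_map


def oracle_observation(read: AlignedRead, pos: int):
    """What the oracle says the read shows at ``pos`` (None = uncovered)."""
    ref_map, ins_map = expand_alignment(read)
    entry = ref_map.get(pos)
    if entry is None or entry[0] == "skip":
        return None
    ins = None
    if pos in ins_map:
        qstart, ln = ins_map[pos]
        ins = (
            read.query_sequence[qstart:qstart + ln],
            tuple(read.query_qualities[qstart:qstart + ln]),
        )
    if entry[0] == "base":
        qi = entry[1]
        return Observation(
            kind="base",
            read_name=read.query_name,
            base=read.query_sequence[qi],
            base_quality=read.query_qualities[qi],
            inserted_seq=ins[0] if ins else None,
            inserted_quals=ins[1] if ins else None,
        )
    return Observation(
        kind="deletion",
        read_name=read.query_name,
        inserted_seq=ins[0] if ins else None,
        inserted_quals=ins[1] if ins else None,
    )


def random_read(rng: random.Random, name: str = "r") -> AlignedRead:
    """A random small alignment over ops M/I/D/S with ref span <= 30."""
    ops = []
    if rng.random() < 0.3:
        ops.append(("S", rng.randint(1, 5)))
    n_core = rng.randint(1, 5)
    prev = None
    for _ in range(n_core):
        op = rng.choice("MID")
        if op == prev and op != "M":
            op = "M"
        ops.append((op, rng.randint(1, 6)))
        prev = op
    if not any(op == "M" for op, _ in ops):
        ops.append(("M", rng.randint(1, 6)))
    if rng.random() < 0.3:
        ops.append(("S", rng.randint(1, 5)))
    qlen = sum(ln for op, ln in ops if op in "MIS")
    seq = "".join(rng.choice("ACGT") for _ in range(qlen))
    quals = tuple(rng.randint(0, 45) for _ in range(qlen))
    return AlignedRead(
        query_name=name,
        ref_start=rng.randint(1, 100),
        cigar=tuple(ops),
        query_sequence=seq,
        query_qualities=quals,
        mapping_quality=60,
    )


@pytest.fixture
def rng():
    return random.Random(20170228)
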