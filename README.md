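# basepile

Inspect the raw read evidence at genomic positions you already care about —
hotspot mutations, recurrently miscalled indels, any list of coordinates —
directly from BAM files, independent of a variant caller's internal filters.

Variant callers return the variants that survived their filtering; a hotspot
mutation present at 2–3% allele fraction, or an insertion inside a
homopolymer, is routinely dropped with no trace in the VCF. `basepile`
answers the complementary question: *what do the mapped reads actually show
at this position?* It walks each overlapping read's CIGAR string, tallies
the bases, deletions and insertions observed at every target coordinate,
applies mapping- and base-quality filters, derives allele frequencies and
calls, and renders the evidence as bar plots next to plain-text reports.

## Model

At a 1-based reference position *p*, each retained read (mapped, primary,
non-duplicate, MQ ≥ the threshold) contributes one observation obtained by
walking its CIGAR with parallel reference and query cursors: M/=/X yield the
aligned base and its Phred quality, D yields a deletion, and an I run
sitting between *p−1* and *p* is attached to the observation at *p* (so an
insertion is an *additional* event on a read that also shows a base or
deletion there). Spliced N skips leave *p* uncovered.

With counts `n_b` for bases *b* ∈ {A, C, G, T, N}, `n_del` deletions and
`n_ins` insertions (bases below the quality floor are moved to an
`excluded` tally), the spanning-read depth is

```
DP = n_A + n_C + n_G + n_T + n_N + n_del
```

and every event frequency — including insertions — uses that denominator:

```
VAF(x) = n_x / DP
```

Base and deletion frequencies sum to 1; the insertion frequency is extra,
because insertion-carrying reads already contribute a base or deletion.
Categories at or above a frequency threshold become the reported calls (up
to six: A, C, G, T, deletion, insertion). When a per-sample caller VCF is
supplied, each genotype allele contributes `DP / 2` expected reads to its
category, drawn as dashed lines in the plots; caller-anchored insertions
(`REF A, ALT AG` at *p*) are displayed at *p+1*.

Quality thresholds follow the SAM text convention: an ASCII code is
Phred + 33, so a base-quality floor of 50 means Phred 17.

## Worked example

The package ships a generator for fully specified synthetic alignments, so
the example is self-contained. Two samples are simulated at one position
(reference base G, 2000× coverage, ~30% T substitution, ~3% deletions);
UPN1 additionally carries an inserted G on ~28% of its reads, UPN2 on ~1%
— the classic signature of a real insertion versus homopolymer noise:

```python
from basepile.fixtures import (CompositionSpec, simulate_position_reads,
                               write_alignment_fixture, random_reference)

ref = random_reference(300, 99)
for i, name in enumerate(("UPN1", "UPN2")):
    spec = CompositionSpec(
        chrom="t", pos=150, coverage=2000,
        base_fractions={"G": 0.67, "T": 0.30, "deletion": 0.03},
        insertion_fraction=0.28 if name == "UPN1" else 0.01,
        inserted_seq="G", seed=60 + i)
    write_alignment_fixture(simulate_position_reads(spec, ref), ref,
                            "demo/bams", sample=name)
```

```
basepile --samples demo/samples.txt --bam-dir demo/bams \
         --targets demo/targets.txt --reference demo/bams/reference.fa \
         --mq 60 --bq 50 --freq-threshold 0.01 --q-lower 58 --q-upper 63 \
         --marks 0.2 --mode position --out demo/out
```

`demo/out/` then holds three TXT reports per sample, one PNG per position
and a JSON manifest. The frequency report reads:

```
sample  chrom  pos  occurrence  A     C     G     T     N     deletion  insertion  calls
UPN1    t      150  1           0.00  0.00  0.66  0.31  0.00  0.03      0.29       G:0.66;T:0.31;insertion:0.29;deletion:0.03
UPN2    t      150  1           0.00  0.00  0.68  0.30  0.00  0.03      0.01       G:0.68;T:0.30;deletion:0.03
```

Both samples show the 30% T substitution, but only UPN1's insertion
frequency (0.29, from 589 of 2000 spanning reads) clears the 20% mark drawn
across the plot — UPN2's 0.01 falls below the 1% calling threshold and is
not reported as a call. In `t_150.png` the same comparison is visual: a
purple-edged insertion bar towering over the mark line in one panel and
absent in the other, with the reference G hanging from the negative axis.

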