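# Methods

## Scope and procedure

`basepile` is an evidence-inspection tool, not a variant caller: it makes no
genotype-likelihood or error-model assumptions and reports raw, filtered
read counts. The pipeline per (sample, target position) is

1. fetch reads overlapping the position from an indexed BAM;
2. drop unmapped, duplicate-flagged and secondary/supplementary records,
   and reads with mapping quality strictly below the MQ floor;
3. walk each read's CIGAR to one observation (base + quality, deletion,
   optionally an attached insertion);
4. tally observations under the base-quality floor into per-category counts
   and mean qualities;
5. derive frequencies, calls, and — when caller VCFs are given —
   genotype-expected counts;
6. write three TXT reports and render bar plots.

## Coordinate and event conventions

* All user-facing coordinates are 1-based inclusive (VCF convention);
  0-based arithmetic is confined to the pysam boundary.
* An insertion between reference positions *p* and *p+1* is attributed to
  *p+1*. This keeps an insertion visually at the first position it
  displaces and makes a left-anchored caller record (`REF A, ALT AG` at
  *p*) line up with the displayed position *p+1*; the VCF overlay performs
  that shift.
* A read showing both an insertion and an aligned base (or deletion) at the
  position yields a single observation carrying both, so insertion counts
  are additional and never compete with base counts.
* Spliced alignments (CIGAR N) leave the position uncovered rather than
  counting as deletions: N is a transcript gap, not a deletion call. The
  tool targets DNA data; RNA-seq reads spanning a target via N simply do
  not contribute.
* Listing the same coordinate *k* times inspects the *k*-th inserted base:
  occurrence *k* shows the distribution of base *k* among insertions of
  length ≥ *k*. This is the mechanism for viewing multi-base insertions.

## Filters and thresholds

| parameter | meaning | default |
|---|---|---|
| `mq_threshold` | mapping-quality floor; reads with MQ strictly below are dropped | 0 |
| `bq_threshold` | base-quality floor, ASCII code (Phred + 33) | 33 (Phred 0) |
| `frequency_threshold` | minimum fraction for a reported call | 0 |
| `quality_lower_bound` / `quality_upper_bound` | ASCII codes spanning the bar-shading ramp | 53 / 73 (Phred 20–40) |
| `marks` | fractions at which horizontal guide lines are drawn | none |

The MQ comparison is *strict less-than* so that data whose maximum mapping
quality equals the chosen threshold (e.g. a uniquely-mapping-only dataset
thresholded at its ceiling) is not discarded wholesale. Base observations
failing the BQ floor move to an `excluded` tally rather than vanishing; the
count report shows them separately. Deletions carry no base quality and are
never BQ-excluded. A multi-base insertion is excluded when the *mean* of
its inserted-base qualities falls below the floor — a single weak base
inside an otherwise confident insertion should not erase the event.

## Frequencies and calls

The denominator is the number of spanning reads retained after BQ
exclusion: base counts (including N) plus deletions. Insertions share that
denominator but are not part of it, since every insertion-carrying read is
already counted through its flanking base or deletion. Consequently
base+deletion frequencies sum to exactly 1 while the insertion frequency is
reported "additionally" and can push category totals past 1 — deliberate,
and essential for insertion allele fractions to be comparable to SNV
fractions at the same site.

Calls are the event categories (A, C, G, T, deletion, insertion — N is
tallied but never called) at or above the frequency threshold, sorted by
descending fraction with ties broken in fixed category order, capped at the
six possible categories. Reports print frequencies at two decimals; full
precision is kept internally.

## Genotype expectations

Each genotype allele of an overlapping caller record contributes
`depth / ploidy` expected reads. SNV alleles map to their base, deletion
alleles to the deleted positions, insertion alleles to their anchor base
*plus* an insertion expectation at the following position. Genotype weight
not covered by any record falls back to the reference base, so expected
base+deletion counts always sum to the observed depth. Records failing the
VCF FILTER column are used anyway — inspecting filtered-out calls is the
point — and symbolic alleles (`<DEL>`, breakends) are skipped with a
warning rather than guessed at.

## Plotting

Bars rise from the positive y axis in category colors (A green, C blue,
G yellow, T red, deletion black); an insertion bar takes the inserted
base's color with a purple edge, stacked by inserted base when several
alleles occur. Mean base quality darkens the fill linearly between the two
quality bounds (clamped outside). The reference base hangs from the
negative axis at fixed unit height with known-variant alternates stacked
below it; the unit is 1 in relative mode and 15% of the tallest bar in
absolute mode, a display convention only — reference bars encode identity,
not depth. Marks are figure-wide lines in relative mode and per-panel
segments at `mark × depth` in absolute mode. Excluded bases appear in the
text reports only. Output is PNG at 150 dpi; rendering is deterministic on
a fixed matplotlib version, which the tests check by byte comparison of
repeated renders.

## Synthetic data generator

The `fixtures` module replaces read-simulator + mutation-spike tooling with
a direct compositional generator: 50 bp single-end reads, all starting 25
bases before the target, copying a supplied (or seed-derived) reference
except for one event at the position. Per-read categories are drawn
multinomially from the requested fractions; insertion flags are independent
Bernoulli draws, mirroring the tally's insertions-as-additional convention;
qualities come from a per-category clamped normal (default mean Phred 35,
sd 3, the ballpark of modern short-read data). A fixed seed yields
byte-identical BAMs.

What this emulates is *composition at a position under clean mapping*; it
deliberately omits sequencing-error profiles, soft-clipping, fragment-size
and strand structure, alignment ambiguity in repeats, and overlapping mate
double-counting. Passing tests therefore demonstrate that counting,
filtering, frequency arithmetic and display are correct — not that mapping
artifacts in real repetitive regions are handled, which is exactly the
judgment the plots exist to support.

The recovery checks run the full pipeline at coverage 4,000 with a 3%
alternate fraction (the regime where callers go quiet), repeated over 20
seeds, requiring ≥ 19 runs inside the binomial band
`4·sqrt(p(1−p)/n)`; unit-level recovery checks use coverages of 600–800 to
keep the suite fast. The acceptance script uses the same 4,000× / 3%
conditions in a single seeded run.

## Numerical and degenerate-input choices

* Zero-depth positions produce all-zero count rows, frequencies of 0 with
  denominator 0, an empty call list, and a reference-only panel — never an
  error, so uncovered targets and contigs absent from a BAM degrade
  gracefully.
* Frequency normalization is exact to 1e−9 (plain double sums at realistic
  depths).
* Mean qualities average retained contributions only; the insertion mean
  averages over inserted bases, not events.
* Ties in call ordering break by fixed category order, making output
  independent of dictionary iteration order.
* Quality encoding is fixed at offset 33; inputs below ASCII 33 raise.

## Known limitations

No realignment or indel left-shifting (a right-shifted aligner indel can
land at a neighboring coordinate), no overlapping-mate de-duplication
beyond flag filtering (fragment coverage can be double-counted in short
inserts), single-VCF-sample parsing only, and no streamed/remote BAM
access. The reports fix one particular TXT schema; other layouts exist in
comparable tools.
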