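# Methods

## Signal model

All four assays reduce to per-position count comparisons between two (or
three) sequencing libraries. Where the signal lives depends on library
chemistry: single-hit nuclease cleavage (PARS) and RT-stop chemistries
(DMS-seq, icSHAPE) place it at the 5′-most aligned nucleotide of each read,
so those methods consume 5′-end coverage; exhaustive digestion
(ds/ssRNA-seq) leaves protected fragments whose whole body is informative,
so it consumes full-read coverage. The two counting modes are kept as an
explicit tag on every coverage track and the scorers refuse a track of the
wrong mode.

### Coordinates and strand

Everything internal is 0-based, half-open (BED convention); 1-based
inclusive browser-style region strings are converted at the CLI edge only.
The biological 5′ end of a minus-strand read is its *rightmost* genomic
base; 5′-end counting uses that base, and all profile extraction reverses
minus-strand score vectors so offset 0 is always the 5′-most position of a
region in transcript orientation. Spliced alignments contribute only their
aligned blocks to full-read coverage.

### Alignment filter

Reads are kept when mismatches ≤ 2, edit distance ≤ 2, and number of mapping
locations ≤ 5 (all inclusive, all configurable). Mismatch and edit-distance
counts are read from the XM and NM tags, the convention of the spliced
aligners these libraries are typically mapped with; NH gives mapping
locations. A record missing a tag is an error under the default strict
policy; the lenient policy substitutes mismatches = 0 and n_hits = 1 and
lets a lone XM/NM tag serve both checks. Multi-mapped reads that pass the
location cutoff contribute full weight (1 per reported mapping) — fractional
weighting would change totals silently and is deliberately not done.

## Scoring

**DMS-seq.** `R_i = (D_i/D_max)/(C_i/C_max)`. The normalization scope for
the maxima is a genuine free choice: maxima over a whole library make every
score hostage to the single most extreme (often rRNA-derived) position, so
the default scope is the supplied track/region, with an explicit override
(`d_max`/`c_max` arguments; `--scope global` on the CLI) for whole-library
normalization. The chosen maxima are recorded in the output metadata.
Positions with `C_i = 0` are missing (undefined ratio); a scope whose
maximum is zero is an error, not a silently empty result.

**icSHAPE.** `R_i = (D_i − C_i)/B_i` with `B` the full-read base density of
the DMSO control library and `C` its 5′-end counts; missing where
`B_i = 0`. Negative reactivities (control exceeding treatment) are retained
by default so display inversion is information-preserving; a
`floor_at_zero` flag clips them. The upstream icSHAPE pipeline's α-scaling
and winsorization are intentionally not applied — this package implements
the plain normalized-difference score.

**PARS.** The score is a generalized log ratio of window sums:
`S_i = log2((Σ V1_j + |W_i|·c)/(Σ S1_j + |W_i|·c))` over
`W_i = [i−2, i+2] ∩ track`. Two readings of the pseudocount are possible
("one count per position", i.e. +|W| in total, versus +5 per position inside
the sum); the per-position-one reading is used because any common
per-position divisor cancels in the ratio, leaving only the total additive
constant meaningful — and that constant is exposed as
`per_position_pseudocount` (default 1). Boundary windows are truncated to
in-bounds positions with the pseudocount scaled to the actual window size,
so the first and last two nucleotides of a transcript remain scoreable. The
omission rule ("no coverage in either library") is applied to the window
sums, the most conservative reading for a window statistic. Window sums use
cumulative sums (O(n) total).

**ds/ssRNA-seq.** `S_i = log2((ONE_i + c)/(V1_i + c))`, c = 1 by default;
the pseudocount guarantees finiteness, so the score is defined at every
position.

Missing values are NaN throughout and propagate as such — never zero.
Scores are exchanged as a five-column TSV
(`chrom pos0 strand method score`) written with `repr` so floats round-trip
bit-exactly, plus bedGraph for browser use.

## Score store

An in-memory store over flat files replaces a database server: per
(chromosome, strand, method), positions are kept in sorted arrays and
interval queries are answered by binary search (O(log n + k)). Queries over
[a, b) never return b; unknown chromosomes yield an all-missing vector with
a warning rather than an error, because absence of scores at a locus is an
ordinary, reportable outcome of these sparse datasets. Duplicate
(chrom, pos, strand) within a dataset is a load-time error naming the
offending position. Exporting a loaded dataset reproduces the input records
exactly.

## Aggregation

Meta-profiles are unweighted arithmetic means of oriented scores at each
relative offset across equal-length regions; missing scores are excluded
from numerator and denominator, and the number of contributing regions per
offset is exported so users can attach their own uncertainty bands.
Overlapping or duplicate regions count independently. Feature windows are
built strand-aware: `up` is the 5′ flank in transcript orientation, so a
3-nt anchor with 9-nt flanks occupies offsets 9–11 of a 21-nt window and a
7-nt motif with 21-nt flanks occupies offsets 21–27 of a 49-nt window,
regardless of strand. Windows that would run past chromosome bounds are
dropped with a warning. The motif scanner does exact IUPAC matching on both
strands (RNA alphabets accepted, overlapping matches all reported);
PWM-threshold scanning is a known simplification and out of scope.

## Display harmonization

"Scaled and re-centered" is realized as a per-window, per-method population
z-score over the non-missing values (zero-variance windows map to 0), and
the reactivity-type methods (DMS, icSHAPE) are negated so that in every
rendered series higher = more evidence of pairing. Negation commutes with
population z-scoring, so the two operation orders agree exactly — asserted
in the tests. Harmonization is a view: the untransformed scores are always
written next to the plot and round-trip exactly. Plots are SVG with a fixed
hash salt and no embedded date, making output byte-deterministic for fixed
input. Whether to standardize per window or per dataset was an open choice;
per-window is implemented and flagged in the output metadata header.

## Synthetic data

The simulator encodes only the contract the assays share — reagent
preference by pairing state — as independent per-position Poisson counts:
means are `depth` in the reagent's non-preferred state and
`depth × signal_ratio` in the preferred one. Defaults are depth 200 and
ratio 5:1 over a 35-nt hairpin (15-bp stem, 5-nt unpaired loop, the shape
of an iron-response-element-like stem-loop), which puts the simulation in
the regime where a single profile already separates loop from stem while
leaving visible noise. Per assay: DMS-like draws the denatured control at
the *elevated* rate everywhere (denatured RNA is uniformly reactive);
icSHAPE-like draws the DMSO control flat at base depth and the background
base density at 5× base depth (full-read depth exceeds 5′-end counts
because each read covers many bases); PARS-like elevates V1 at paired and
S1 at unpaired positions; ds/ss-like does the same with full-read tracks.

Deliberately not modeled: ligation and RT sequence bias, fragment-length
effects, coverage autocorrelation along fragments, expression-driven
sparsity. Passing recovery tests therefore shows the scoring and
orientation logic is faithful to the count contrasts, not that any assay
would resolve a given real structure. The SAM generator emits fixed-length,
unspliced reads with controlled XM/NM/NH tags for exercising the filter;
the annotation generator embeds ATG codons on alternating strands in random
sequence with matching BED and FASTA coordinates.

## Problem sizes and numerical choices

Property tests run on ≤ 200-position tracks against naive per-position
oracle re-implementations at 1e-12 absolute tolerance (the vectorized and
naive paths do the same float operations in different orders only where
that tolerance absorbs it). The structure-recovery check runs 100 seeded
replicates per assay at depth 200 and requires the loop to rank below the
stem in at least 95 of them. These sizes make the full suite run in
seconds while keeping every check statistically meaningful.

## Known limitations

- Paired-end mates are treated as independent reads; no duplicate marking.
- DMS/icSHAPE winsorization and scaling schemes from the assays' own
  pipelines are not reproduced (by design; see above).
- The store holds everything in memory; it targets desk-scale datasets,
  not whole-transcriptome icSHAPE depth.
- Genomic coordinates are assumed for all datasets; transcript-space
  scores can be loaded by treating transcripts as chromosomes.
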