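# structprobe

Per-nucleotide RNA secondary-structure scores from high-throughput
structure-probing sequencing data.

Transcriptome-wide probing assays treat RNA with a reagent that reacts with
nucleotides according to their base-pairing status and read out the result by
sequencing. Four assay designs are supported, each with its own scoring rule:

| method | signal | counting mode | score | polarity |
|---|---|---|---|---|
| PARS | RNase V1 (ds) vs S1 (ss) single-hit cleavage 5′ ends | 5′-end | windowed generalized log ratio | + = paired |
| DMS-seq | RT stops at DMS-labeled unpaired A/C vs denatured control | 5′-end | max-normalized ratio | high = unpaired |
| icSHAPE | RT stops at acylated unpaired bases vs DMSO control | 5′-end | background-scaled difference | high = unpaired |
| ds/ssRNA-seq | fragments surviving exhaustive ss- or ds-specific digestion | full-read | generalized log ratio | + = paired |

The scoring formulas, with *i* indexing transcript/genome positions:

- **DMS-seq** `R_i = (D_i / D_max) / (C_i / C_max)` — treated 5′-end counts
  over denatured-control counts, each normalized by its library maximum;
  undefined (missing) where `C_i = 0`.
- **icSHAPE** `R_i = (D_i − C_i) / B_i` — treated minus DMSO-control 5′-end
  counts over the per-base background density `B` of the DMSO library;
  missing where `B_i = 0`.
- **PARS** `S_i = log2( (Σ_{j=i−2..i+2} V1_j + |W|·c) / (Σ_j S1_j + |W|·c) )`
  — a generalized log ratio over the surrounding 5-nt window with per-position
  pseudocount `c` (default 1); missing when neither library has any coverage
  in the window.
- **ds/ssRNA-seq** `S_i = log2((ONE_i + 1) / (V1_i + 1))` of full-read
  coverage, defined everywhere.

Around the scorers the package provides: alignment filtering (≤ 2 mismatches,
edit distance ≤ 2, ≤ 5 mapping locations) and strand-aware 5′-end / full-read
coverage counting from SAM/BAM; a flat-file score store with half-open
interval queries; strand-aware meta-profile aggregation across equal-length
regions (e.g. all start codons, all matches to an RNA-binding-protein motif,
found with the built-in IUPAC motif scanner); and display harmonization
(per-window z-scoring plus inversion of the reactivity-type methods so that
higher always means more paired) with SVG plots and raw-score export.
A seeded simulator generates hairpin-shaped probe counts, toy alignments and
annotations so the whole pipeline runs without external data.

## Worked example

Simulate PARS-like cleavage counts over a 35-nt hairpin (15-bp stem, 5-nt
loop), score them, and query the loop region:

```sh
structprobe simulate counts --assay pars_like --seed 7 --out hp
structprobe score pars --v1 hp.V1.tsv --s1 hp.S1.tsv --out pars.tsv
structprobe query --scores pars.tsv --region syn:14-22 --strand +
```

prints (region strings are 1-based inclusive; file positions 0-based):

```
#chrom  pos0  strand  method  score
syn     13    +       pars    1.1800954004744029
syn     14    +       pars    0.37922579753836955
syn     15    +       pars    -0.4177849673361892
syn     16    +       pars    -1.2534483570045958
syn     17    +       pars    -2.3989054028369803
syn     18    +       pars    -1.2714761797204555
syn     19    +       pars    -0.47801782066246407
syn     20    +       pars    0.34048107308117154
syn     21    +       pars    1.2063437095100982
```

Positions 15–19 are the unpaired loop: S1 (single-strand-specific) cleavage
dominates the window there and the log ratio goes negative, bottoming out at
the loop center; the paired stems on either side score positive. The same
fixtures drive `aggregate` (per-offset means across a BED of equal-length
windows, e.g. codons with 9-nt flanks occupying offsets 9–11 of a 21-nt
profile) and `plot` (harmonized multi-method SVG with raw TSV alongside).

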