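# Methods

## Problem and model

Eukaryotic genome assemblies usually contain a handful of organellar
contigs (mitochondrial; in plants and algae also plastid) among thousands
to hundreds of thousands of nuclear sequences. `orgscreen` frames their
identification as supervised multiclass classification of individual
contigs. No single rule separates the classes — organellar genome size and
gene content vary enormously across clades — so the model combines weak
signals: organellar DNA tends to be AT-rich relative to its nuclear
background, short, dense in tRNA/rRNA annotations, and carries homology
hits against curated organellar gene sets.

Each contig is summarized by a 16-dimensional feature vector:

| feature | definition |
|---|---|
| `length_bp` | contig length (bp); enters the model as log10 |
| `gc` | (#G+#C)/(#A+#C+#G+#T), ambiguity codes excluded |
| `gc_delta`, `gc_zscore`, `gc_outlier_flag` | deviation from the length-weighted assembly mean GC; z uses the length-weighted SD; flag is \|z\| > 2 |
| `repeat_density`, `repeat_frac` | repeat intervals per Mb; fraction of bases covered by the interval union |
| `rrna_density`, `trna_density` | annotated rRNA/tRNA per Mb |
| `cpg_density` | CpG islands per Mb (detected natively, below) |
| `mito_hit_density`, `plastid_hit_density`, `mito_hit_count`, `plastid_hit_count`, `best_mito_bitscore`, `best_plastid_bitscore` | homology evidence against the two organellar gene sets |

Densities are count · 10⁶ / length. Both the continuous GC z-score and the
binary outlier flag are emitted so the model can use either; which encoding
is preferable is an open modelling question and the choice is delegated to
the fitted classifier.

## CpG islands

Islands are detected with the classic sliding-window criteria
(Gardiner-Garden & Frommer): window 100 bp advanced 1 bp; a window
qualifies when G+C ≥ 50% of the window and observed/expected CpG
= #CG · w / (#C · #G) ≥ 0.6 (0 when #C·#G = 0); overlapping or abutting
qualifying windows are merged and merged regions shorter than 200 bp are
discarded. All five thresholds are exposed as parameters. The
implementation uses prefix sums (O(n) per contig); tests compare it
against an exhaustive per-window reference scan. Coordinates are 0-based
half-open internally and converted only at format boundaries (GFF3 export
is 1-based inclusive).

## Evidence ingestion

The package deliberately ingests annotator *output files* rather than
running repeat finders, rRNA/tRNA scanners, or aligners itself: the
contribution is the feature encoding and the model, and file-level
ingestion keeps the pipeline testable without external binaries. Formats:
GFF3 for repeats and rRNA; tRNA-scanner tabular output (3 header lines,
pseudogene rows counted by default, configurable); 12-column blast-style
tabular for homology hits with an e-value ceiling of 1e-5 (configurable —
no canonical threshold exists for this step). Hits are counted per query
sequence regardless of subject gene; per-gene presence/absence encoding
would tie the feature space to one specific gene database. Evidence naming
sequences absent from the assembly is dropped with a reconciliation
warning; ids are matched exactly on the first whitespace-delimited FASTA
header token.

## Training protocol

Labeled tables are split 1:5 train:test, stratified by class (the split
direction is configurable via `test_fraction`; the default keeps 1/6 for
training). Four model families are compared by stratified k-fold CV
(default k = 10, lowered with a warning when the minority class is
smaller): logistic regression, random forest (200 trees), 5-NN, and
AdaBoost (100 stumps). The selection score is the pooled multiclass MCC
averaged over folds; per-fold one-vs-rest MCCs for the organellar classes
are reported alongside. Ties go to a fixed precedence
(adaboost > random_forest > linear > knn). The winner is refit on the full
training split.

Class imbalance is handled by inverse-frequency sample weights
(`weighting="balanced"`, default; `"none"` disables). k-NN accepts no
sample weights and is fitted unweighted. Features are standardized with
train-split means/SDs stored in the model bundle; constant columns pass
through unscaled; length is log10-transformed first because contig lengths
span several orders of magnitude. Prediction is argmax over
`predict_proba` scores in the fixed class order (nuclear, mitochondrion,
plastid), which also breaks ties; scores are renormalized to sum to 1.
Every stochastic step takes an explicit seed, and a persisted bundle
(joblib archive with a format tag, schema, scaling constants, seed, and CV
report) reproduces its predictions exactly.

## Synthetic data generator

The generator emulates the kind of labeled corpus such a classifier is
trained on, at desk scale. Defaults (one assembly): 2,000 contigs, 5%
organellar split evenly between mitochondrion and plastid; nuclear GC
~ Normal(0.41, 0.02) with organellar GC shifted −0.2 (AT-rich); nuclear
lengths lognormal(μ = 9.2, σ = 1.0) (~10 kb median — far below real
chromosome scales, chosen so a full corpus is ~35 Mb); organellar lengths
uniform on [12, 160] kb, matching small mitogenomes up to plastid scale.
Residues are drawn per-base Bernoulli at the contig's GC level — window
statistics are all that matters downstream, so no Markov structure is
modelled — and CpG enrichment is injected separately by planting 1–3
CG-repeat segments (300–600 bp) in organellar contigs when enabled.
Evidence counts are Poisson at class-specific per-contig rates (nuclear:
repeat 20, rRNA 0.1, tRNA 0.5, gene hits 0; mitochondrion: 2/2/15, 5
mito-gene hits; plastid: 2/4/25, 5 plastid-gene hits; no cross-class
hits by default) and are written in the exact dialects the readers parse,
including decoy homology rows above the e-value ceiling that the reader
must drop. Each bundle also carries the feature table its ground truth
implies, enabling exact (bit-level) round-trip checks of the readers and
feature builder.

A multi-assembly mode derives per-assembly seeds from a master seed; its
sparse variant places only 0–2 organellar contigs per assembly (mean 1),
mimicking real corpora where organellar sequences are a ~5·10⁻⁴ minority.

What passing tests on this corpus show — and do not show: the synthetic
classes are separable by construction (GC shift, length range, hit rates),
so perfect held-out recovery demonstrates that the pipeline extracts and
uses the signals correctly, not that real assemblies are this easy. Real
contigs exhibit correlated composition, NUMTs/NUPTs (nuclear insertions of
organellar DNA that share both composition and homology signal),
assembly artifacts, and bacterial contamination, none of which are
simulated. The null-signal corpus (no GC shift, shared length
distribution, equal evidence rates) is the corresponding negative control:
cross-validated MCC stays near 0 there, confirming the pipeline does not
manufacture signal.

## Numerical choices

- Assembly GC statistics use `math.fsum`, making them exactly invariant
  under permutation of the input sequences.
- Feature tables serialize floats with `%.17g` and are parsed with
  pandas' round-trip float parser, so write→read is bit-exact.
- MCC is defined as 0 when any marginal factor of the denominator is 0;
  precision/sensitivity/specificity are 0 on empty denominators. Metric
  values are only rounded (2 decimals) at the presentation layer.
- GC content excludes ambiguity codes from numerator and denominator;
  window GC in the island scan divides by the full window length.
- Degenerate guards: an assembly with zero GC variance yields z = 0 for
  every contig; a window longer than the contig yields no islands; classes
  with < 2 members refuse to stratify with an explicit error.

## Known limitations

- Per-family hyperparameters are fixed sensible defaults; no search is
  performed, and no probability calibration is attempted.
- Homology evidence is reduced to counts/bitscores per query; subject gene
  identity is discarded.
- The classifier is only as good as the annotation evidence supplied;
  with a bare FASTA the model falls back on composition and length alone.
- Headline performance numbers on real multi-genome corpora require the
  corresponding assemblies and annotator runs and are outside what the
  synthetic corpus can establish.
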