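# orgscreen

Screen eukaryotic genome assemblies for organellar DNA. Assemblies routinely
contain mitochondrial and plastid contigs co-assembled with the nuclear
genome; finding them matters both for contamination screening and for
downstream organelle phylogenetics. `orgscreen` classifies every sequence of
an assembly FASTA as **nuclear**, **mitochondrion**, or **plastid** using a
supervised model over per-contig features:

- intrinsic: length, GC content, and the contig's deviation from the
  length-weighted assembly-average GC (signed delta, z-score, and an
  |z| > 2 outlier flag);
- CpG islands, detected natively by the classic sliding-window criteria
  (100 bp window, 1 bp shift, G+C ≥ 50%, observed/expected CpG ≥ 0.6,
  merged regions ≥ 200 bp, where obs/exp = #CG · w / (#C · #G));
- annotation evidence ingested from standard files — repeats and rRNA as
  GFF3, tRNA scanner tabular output, and 12-column blast-style homology
  hits against mitochondrial and plastid gene sets — reduced to densities
  per 1 Mb plus raw hit counts and best bitscores.

Model selection follows a stratified training protocol: a 1:5
train-to-test split, 10-fold stratified cross-validation over four model
families (linear classifier, random forest, k-nearest neighbors, AdaBoost)
scored by the pooled multiclass Matthews correlation coefficient

MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

and a refit of the winning family with inverse-frequency class weights
(organellar contigs are a tiny minority of real corpora). The evaluation
module reports per-class one-vs-rest TP/TN/FP/FN, MCC, F1, precision,
sensitivity, and specificity.

A seeded synthetic-assembly generator emits FASTA, evidence files, labels,
and the exact feature table they imply, so the whole pipeline is testable
without external annotators or downloads.

## Worked example

```sh
orgscreen simulate --out demo --seed 21 --n-sequences 240 --organellar-fraction 0.15
orgscreen extract --fasta demo/assembly.fasta \
    --repeats demo/repeats.gff3 --rrna demo/rrna.gff3 --trna demo/trna.tsv \
    --mito-hits demo/mito_hits.tsv --plastid-hits demo/plastid_hits.tsv \
    --out demo/features.tsv
orgscreen train --features demo/features.tsv --labels demo/labels.tsv \
    --out demo/model.joblib --seed 21
orgscreen predict --model demo/model.joblib --features demo/features.tsv \
    --out demo/preds.tsv
orgscreen evaluate --predictions demo/preds.tsv --labels demo/labels.tsv
```

The train step prints which family won cross-validation and the held-out
one-vs-rest MCC per organellar class:

```
best family: adaboost (CV mean MCC 1.000)
held-out one-vs-rest MCC (mitochondrion): 1.000
held-out one-vs-rest MCC (plastid): 1.000
```

(1.000 means every held-out organellar contig was recovered without false
positives — expected here because the synthetic corpus is strongly
separable.) The final step prints a per-class report:

```
Row                          TP       TN     FP     FN    MCC     F1    Pre    Sen    Spe
mitochondrion                18      222      0      0   1.00   1.00   1.00   1.00   1.00
plastid                      18      222      0      0   1.00   1.00   1.00   1.00   1.00
```

`evaluate --counts <tsv>` accepts raw TP/TN/FP/FN rows directly, so metric
arithmetic can be checked against any published confusion table.

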