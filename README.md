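# exonshift

Exon-level analysis of developmental alternative-splicing switches in bulk
brain transcriptomic datasets.

During human brain development, several genes switch the isoforms they
express within a short perinatal window. The canonical example is the
microtubule-associated protein tau gene *MAPT*: inclusion of exon 10 (the
fourth microtubule-binding repeat, 3R → 4R tau) and exon 2 (0N → 1N tau)
rises abruptly around birth and then stays on a stable adult plateau.
Detecting such switches from probe-level expression data — microarray probe
sets or exon-level RNA-seq summaries — requires aggregating probes into
exon- and gene-level signals, forming a splicing index, and testing for
prenatal/postnatal shifts that replicate across independently collected
cohorts. `exonshift` packages that analysis for reuse, together with a
seeded synthetic-data generator whose ground truth makes every stage
testable.

## The statistic at the core

For exon *e* of gene *g* in sample *s*,

```
SI(e, s) = mean expression of probes in e  /  mean expression of all probes of g
```

a dimensionless proxy for exon inclusion. The pipeline then provides:

- **Differential screen** — prenatal vs postnatal comparison of gene-level
  expression and per-exon splicing indices (Welch or pooled t-test), fold
  change = postnatal mean / prenatal mean, Bonferroni correction over all
  records of a run; a feature "replicates" when it is significant *and*
  changes ≥ 1.5-fold (up or down) in **every** dataset.
- **Temporal trend** — OLS of the index on log10 post-conceptual age plus
  whichever covariates a dataset provides (sex, RIN, race; unavailable
  covariates are dropped, not imputed).
- **Regional contrasts** — OLS with treatment-coded region terms against a
  chosen reference region plus age/sex/RIN, Bonferroni over regions within
  feature; neurogenic zones (CGE, LGE, MGE, URL) are flagged in the default
  vocabulary.
- **qPCR arm** — ΔΔCt relative quantification (reference gene, e.g. GAPDH;
  calibrator target, e.g. total tau), Grubbs outlier screening, exact
  Mann-Whitney group comparison.

All ages live on a single canonical axis of post-conceptual days, with term
birth at 266 days (38 weeks): `5.7 pcw → 39.9`, `84 years → 30947`.

## Worked example

Simulate a default cohort (120 donors, second-trimester fetal to adult,
tau-like gene with the exon-10 switch ψ 0.2 → 0.6 at birth among four
paralogs with flat splicing) and run the differential screen:

```sh
exonshift simulate --seed 1 --out sim/
exonshift diff --expr sim/expression.tsv --annot sim/annotation.tsv \
    --meta sim/metadata.csv --genes MAPT,MAP2,MAP4,MAP1A,MAP1B --out diff/
```

`diff/differential.tsv` (abridged):

```
 gene feature level  mean_pre  mean_post  fold_change  log2_fc  p_adj
 MAPT  exon10  exon    0.2597     0.6965       2.6818   1.4232    ~0
 MAPT   exon2  exon    0.4139     0.5847       1.4127   0.4985    ~0
 MAPT   exon3  exon    0.1934     0.1854       0.9586  -0.0609    ~0
 MAP4   exon5  exon    0.3990     0.4009       1.0047   0.0068    1.0
 MAPT    gene  gene  378.7623   395.2242       1.0435   0.0614    ~0
```

The switching exon-10 analogue is recovered at a 2.68-fold postnatal
increase (the generator's truth is 3.0 diluted by the inclusive gene mean —
see `docs/methods.md`), far beyond the 1.5-fold replication threshold. The
flat exons stay well inside it: exon 3 is statistically significant only
because the gene mean itself rises as exons 2/10 switch on (a small, real
dilution effect of the index), but its 0.96-fold change fails the effect-
size screen. The same run's temporal model gives a positive age
coefficient for exon 10 (0.224 per log10-day, p ≈ 7·10⁻⁵⁰).

`exonshift replicate --table yale=... --table lieber=...` then intersects
two such tables with the conjunction rule, and `exonshift trend`,
`exonshift regional --reference DFC` and `exonshift qpcr` cover the
temporal, regional and qPCR arms. Every run echoes its configuration
(`config.yaml`) and a file manifest into the output directory and is
byte-reproducible under a fixed seed.

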