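# Methods

This note documents the models, conventions and design choices behind
`exonshift`, in the order data flows through the pipeline.

## Age axis and cohort conventions

All sample ages are converted to **post-conceptual days (pcd)**: fetal ages
given in post-conceptual weeks are multiplied by 7; postnatal ages are
added to a birth threshold of 266 pcd (38 weeks, term birth). A sample is
*postnatal* iff age > 266 pcd, strictly; borderline perinatal samples are
assigned by this rule with no fuzz. The threshold is configurable
(`birth_pcd`) because tissue collections differ in how they record
gestational age. The 26-code region vocabulary covers transient fetal
structures and the mature sampling grid; the four neurogenic codes (CGE,
LGE, MGE, URL — ganglionic eminences and upper rhombic lip) are flagged as
such because they consist largely of neuronal precursors.

## Normalization and the splicing index

Input expression is assumed already normalized by its upstream provider;
the only transformation applied here is **unity normalization** — an affine
rescale of the whole matrix to [0, 1] by its global minimum and maximum —
and only when the matrix contains negative values (log-ratio style data),
since its purpose is to make ratios meaningful. A per-probe variant exists
behind a flag for sensitivity analysis only; it destroys between-probe
level information and is never the default.

Probe aggregation takes the arithmetic mean of a feature's probes per
sample, skipping missing cells; a feature is missing only where all its
probes are. The **gene-level mean uses all of the gene's probes**,
alternative-exon probes included. Consequently the splicing index
`SI = exon mean / gene mean` is a *diluted* inclusion proportion: with
`n_body` constitutive probes and `p` probes on each alternative exon *e*
with inclusion ψ_e,

```
SI(e) = ψ_e · n_total / (n_body + p · Σ_e ψ_e)
```

Two visible consequences, both real properties of the statistic rather
than artifacts: (1) a prenatal-to-postnatal inclusion ratio of 3.0 appears
as a fold change of ≈ 2.7 after dilution; (2) when one exon switches on,
the gene mean rises, so a *flat* exon's index drifts down slightly — such
features can reach statistical significance at large n while remaining far
inside the 1.5-fold effect-size screen, which is why the replication rule
requires both significance and effect size. A `gene_mean =
"constitutive_only"` mode removes the dilution for users who want an
undiluted inclusion proxy. Indices over denominators ≤ 1e-8 (on the
normalized scale) are reported missing, never infinite.

## Differential screen and replication

Prenatal and postnatal groups are compared per feature with a two-sample
t-test; the default is **Welch** (the variant R's `t.test` applies by
default), with the pooled-variance form available and the choice recorded
in output metadata. Specimens are treated as independent observations even
when donors contribute several. Fold change is postnatal mean / prenatal
mean and is undefined (missing, with the record retained) when the
prenatal mean is non-positive. Bonferroni correction is applied over *all*
records of a run — gene-level and exon-level together, since both are
screened on one volcano. Replication across datasets is the conjunction
rule: adjusted p < α (default 0.05) **and** fold change ≥ 1.5 or ≤ 1/1.5
in every dataset; features absent from any dataset are *untestable*, not
failed.

Whether the exon-level screen should use the splicing index or raw exon
expression is genuinely ambiguous for this family of analyses; the default
is the splicing index (consistent with the temporal models), and
`exon_statistic="exon_expression"` switches modes.

## Temporal and regional models

Both models are ordinary least squares — a Gaussian identity-link GLM is
the only defensible reading for a continuous response. Age enters as
**log10(pcd)** because the cohorts span four orders of magnitude (≈ 40 to
≈ 31 000 pcd) and perinatal dynamics would otherwise be invisible next to
adult decades; a linear-age mode exists behind a flag. Covariates (sex,
RIN, race) are included per dataset only where observed — an entirely
missing covariate is dropped rather than imputed, so e.g. an RNA-seq
cohort without RIN is modelled with age + sex only. Designs are checked
for full column rank before fitting; p-values are two-sided t-tests on the
residual degrees of freedom, and a constant response degenerates to p = 1
with a warning.

The regional model adds treatment-coded region indicators against a
user-chosen reference region (a required argument — there is no defensible
silent default) and corrects contrast p-values by Bonferroni **within
feature across regions**, matching how a per-feature regional panel is
read. Regions with under 3 samples are reported but flagged `low_n`.
Changing the reference region re-parameterizes the contrasts but leaves
fitted values identical (verified to 1e-10 in tests).

## qPCR arm

Technical replicates are averaged (arithmetic mean of Ct) first; then
ΔCt = Ct_target − Ct_reference per sample, ΔΔCt against the *same
sample's* calibrator target, and relative expression 2^−ΔΔCt with
amplification efficiency fixed at 2 (validated hydrolysis-probe assays; no
efficiency estimation). A per-group-mean calibrator mode is available. Ct
values are valid on (0, 40]; a Ct at the 40-cycle ceiling is a non-detect
and censors any quantity it touches rather than being imputed — relevant
for targets with essentially no expression in one group. Outlier screening
is a **two-sided, single-pass Grubbs test** (α = 0.05) within
(group × target) strata, removing at most one point per stratum; group
comparison is Mann-Whitney, exact by scipy's method for untied samples of
total n ≤ 20, exact by complete enumeration when small samples contain
ties, and normal-approximated (continuity + tie correction) otherwise. The
reported U is the larger of the two one-sided statistics; the p-value does
not depend on that convention.

## Synthetic-data generator

The generator emulates the *structure* the analysis assumes, with known
truth. Exon inclusion follows a logistic in log10 age,
`ψ(t) = ψ_pre + (ψ_post − ψ_pre)/(1 + exp(−k(log10 t − log10 t0)))` — a
modelling choice made for its two plateaus and tunable transition
steepness, not a claim about the biological functional form. Defaults: the
tau-like gene carries an abrupt perinatal exon-10 switch (ψ 0.2 → 0.6,
t0 = 266 pcd, k = 8 per log10-day), a slower childhood exon-2 rise
(0.3 → 0.5, t0 = 600, k = 3) and a flat exon 3; four paralogous genes
carry flat alternative exons. Each gene has 48 gene-body probes (≈ 12
constitutive exons × 4 probes, a realistic exon-array density) and 4
probes per alternative exon.

A probe's expected intensity is `mu_gene × region multiplier × ψ` (exon
probes) or `mu_gene × multiplier` (gene-body probes). Microarray mode
emits positive linear-scale intensities `expected · 2^(affinity + noise)`
with the per-probe affinity (SD 0.25) drawn once and per-cell noise (SD
0.1) drawn per observation, both on the log2 scale; counts mode draws
negative-binomial values with the same mean. Gene baselines default to
log-uniform draws on [200, 5000]. Region multipliers default to 1.0, with
0.3 used for the neurogenic set in regional experiments, emulating the low
tau expression of proliferative zones.

The default cohort is 120 donors, half in a **second-trimester fetal
stratum (40–160 pcd)** and half in a **late-infancy-to-adult stratum
(500–30 947 pcd)**, each log-uniform. The deliberate gap around birth
reflects autopsy-cohort reality (fetal material is predominantly second
trimester; immediate-perinatal sampling is sparse) and puts both groups on
the inclusion plateaus, so the prenatal/postnatal contrast measures the
full switch: closed-form expectation gives a recovered exon-10 fold change
of ≈ 2.69 (ψ ratio ≈ 2.80 × dilution ≈ 0.96), which simulation reproduces.
Setting `fetal_age_max = postnatal_age_min = birth_pcd` restores a
continuous log-uniform age distribution when the gap is unwanted.

What the generator does **not** model: donor-level random effects (all
variation is probe noise, so specimens from one donor are conditionally
independent), platform/batch structure, probe cross-hybridization, age-
dependent RNA quality, or correlation between exons beyond the shared gene
mean. Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the stated model, not robustness to those
real-data complications.

The qPCR generator writes Ct = base_ct − log2(relative level) + noise per
replicate, with the reference target pinned at relative level 1, so the
ΔΔCt analysis inverts the configured levels exactly in the noiseless case.

## Problem sizes and numerical conventions

Simulation-backed checks run at the sizes the analyses are designed for:
100 seeds for switch recovery (120 donors each), 200 features for null
calibration, 100 seeds of a 20-donor × 26-region design for regional
recovery. The full test suite and the acceptance script each complete in
well under a minute on one CPU. Numerical tolerances: probe aggregation
and splicing indices match brute-force recomputation to 1e-12; OLS matches
the normal-equations closed form to 1e-8; reference-region invariance
holds to 1e-10. Ties in Grubbs' maximal deviation resolve to the first
index; Bonferroni caps at 1; all simulation randomness flows from a single
`numpy` Generator seeded by the config.
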