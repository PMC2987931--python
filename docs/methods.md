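# Methods

## Scope and internal conventions

The package reimplements the computational pipeline of a case-control
DNA methylation study of trisomy 21 (DS) versus control leukocytes:
array-based screening, differential-methylation calling, penalized
classification, targeted validation statistics, and qPCR expression
analysis. All methylation values are fractions in [0, 1] internally;
percent appears only in pyrosequencing tables and printed reports.
Missing values are NaN, never imputed; loci with missing values are
dropped from group testing with a logged count (the behaviour of the
original array software for failed probes is not documented, so we
chose the deterministic, auditable option).

## Synthetic cohort model

The generator emulates the statistical structure the analysis assumes,
not the assay chemistry (no probe-level two-channel intensities, no
bisulfite conversion simulation, no sequence context).

**Per-locus methylation.** Each locus has group means (μ_DS, μ_ctrl)
and a dispersion φ. A sample's pre-mixture methylation is drawn from a
Beta(μφ, (1−μ)φ) distribution — mean exactly μ, support [0, 1].
Dispersion defaults follow the qualitative shape of the observed group
distributions: `dichotomous` φ = 150 (per-sample SD ≈ 2.5–4 percentage
points: groups barely overlap), `overlapping` φ = 60, `wide` φ = 15.
These are named constants; noise magnitudes per gene are not published,
so the defaults were fixed once from the qualitative descriptions and
are not tuned.

**Validated effect panel.** Nine loci carry the published group mean
percent methylation values and the published validation-series group
sizes (e.g. TMEM131 10.9% in 207 DS vs 41.1% in 73 controls; CPT1B
71.1/46.2; full table in `simulate.TABLE1_PANEL`). TMEM131 methylation
declines with age in controls; the age trend is parameterized as
μ(age) = μ_ctrl + slope·(age − mid-age) with slope −0.002/yr, centred on
the mid-age so that the group mean over a uniform age draw equals
μ_ctrl regardless of the slope. Ages are uniform over (20, 70) years in
both groups (the study sampled cases and controls "spanning the same
age range"; no age distribution is published). Expected values pushed
outside [0, 1] by the trend are clipped with a logged count.

**Mosaicism.** A mosaic individual with trisomic cell fraction f has
its expected methylation diluted linearly before noise:
μ = f·μ_DS + (1−f)·μ_ctrl, reflecting that bulk methylation averages
linearly over cells. f = 1 is complete trisomy; controls have f = 0.

**Cell-type mixture layer.** Per sample, leukocyte proportions
(PMN 0.60, lymphocyte 0.30, monocyte 0.06, NK 0.04 — a typical adult
differential) are drawn from a Dirichlet with concentration 200.
Per-cell-type methylation equals the sample's pre-mixture value plus an
optional per-gene per-type offset (default 0); the bulk value is the
proportion-weighted average, so bulk always lies within the convex hull
of the cell-type values. With zero offsets the mixture layer is
mean-neutral, keeping the planted group means exact.

**Digest-array intensities.** Each sample yields duplicate S and SH
representations and a single SM representation. Expected intensities at
informative loci: S_true; S_true·(MI·(1−leak) + leak);
S_true·leak — where `leak` (default 0.02) is the fraction of fragments
escaping either digestion. Non-informative loci (no HpaII site between
the StyI sites; 25 by default) retain full signal in all three
representations and exercise the Class-2 filter. Per-probe baselines,
per-array scales and per-replicate noise are multiplicative lognormal.
Under this model the background-subtracted MI estimator
(SH_av−SM_av)/(S_av−SM_av) is exactly unbiased for MI, while the ratio
estimator SH_av/S_av carries bias (1−MI)·leak ≤ leak; both are
provided, and the bias structure is asserted in the tests.

**Pyrosequencing.** A region has 10 CpGs (≥ 8 required for reporting);
per-CpG percent values are the sample's bulk value plus N(0, 2.5 pp)
measurement noise, clipped to [0, 100]. The region mean is the plain
arithmetic mean over CpGs.

**qPCR.** Per sample/gene, relative expression is drawn lognormally
around the group mean (CV 0.25); target CT = reference CT + base ΔCT −
log2(expression) with N(0, 0.15) cycle noise per replicate, in
triplicate. Chromosome-21 dosage genes scale with mean copy number
(2 + f)/2, giving the 3:2 = 1.5-fold ratio for complete trisomy.
5aza-dC dose-response series use expected expression
e₀·exp(sign·k·dose) with k = 0.5 per µM over doses (0, 0.1, 0.5, 1.0,
2.5) µM, three replicates per dose.

All randomness flows from one mandatory seed through
`numpy.random.default_rng`; identical configs give byte-identical
output files.

## Differential-methylation screen

Two-group "ANOVA" is the classic pooled-variance one-way F test (the
square of the pooled t statistic), matching the era's array software;
Welch is available behind a flag. The layered call requires
p < p_threshold AND fold > fold_threshold AND (when in use)
absolute difference > abs_diff_threshold. Fold is
max(mean)/min(mean) — hyper- and hypomethylation treated symmetrically,
since the source analysis reports both directions without defining the
ratio's orientation. A zero minimum mean gives infinite fold and passes
the fold criterion only if the absolute-difference criterion holds. No
multiple-testing correction is applied (the screen is raw p < .01 plus
effect filters); a Benjamini–Hochberg column is emitted for information
only. When an individual contributes several blood draws, only the
first (timepoint 0) enters group testing; later draws feed the
stability analysis. Supervised clustering is agglomerative average
linkage on 1 − Pearson correlation, both axes; constant loci are
excluded with a warning; scipy's deterministic linkage gives
reproducible orderings. The screen thresholds use strict inequalities
throughout (the boundary convention in the source material is
ambiguous between ">" and "≥" for the fold criterion; strict ">" is
implemented).

## Classifier

Penalized logistic likelihood ℓ(β) − λ‖β_slopes‖² (intercept
unpenalized), maximized by damped Newton iteration (IRLS with step
halving on the penalized objective). λ defaults to 10⁻⁸: with linearly
separable groups — the realistic regime for the dichotomous panel — the
unpenalized MLE does not exist, and the tiny ridge bounds the
coefficients so the iteration terminates at a finite optimum of
magnitude O(log(1/λ)/margin) ≈ O(100). Convergence is declared when the
largest coefficient update falls below tol·(1 + max|β|) with
tol = 10⁻¹⁰; the relative form is needed because an absolute 10⁻¹⁰ is
below float64 resolution at that coefficient scale. Non-convergence
raises an error carrying the iteration trace. Features are raw beta
fractions (no standardization), replicating the original protocol; a
`standardize` flag exposes the alternative. The exact penalty
parameterization of the original software (whether λ scales with n) is
unknowable from the available description; λ‖β‖² as stated is
implemented.

LOOCV fits n models on n−1 samples each, predicting the held-out sample
at threshold 0.5 (a probability of exactly 0.5 classifies as control,
for determinism). The default `fixed_panel` protocol uses a locus panel
selected on the full data before cross-validation — this replicates the
original study's procedure and its selection bias, which the report
flags; `nested` mode re-runs selection inside each fold for honest
error estimation, and a property test documents that the fixed protocol
is not pessimistic relative to the nested one. Mosaic scoring flags
predicted probabilities inside a configurable band ([0.25, 0.75]
default) as "intermediate".

## Validation statistics

**Age-adjusted group test.** Logistic regression group ~ methylation +
age, Wald p for methylation. The dichotomous panel genes separate the
groups almost completely, where plain maximum likelihood either
diverges or — more insidiously — converges with an exploding slope
whose Wald statistic degenerates (Hauck–Donner effect: the SE grows
faster than the coefficient, so the Wald p can be orders of magnitude
too large despite overwhelming evidence). Quasi-separation is therefore
detected by any of: non-convergence, a fitted probability within 10⁻⁶
of 0 or 1, or standardized slope |β|·sd(methylation) > 15. Detected
fits are re-estimated with Firth's bias-reduced likelihood (hat-value
modified score, hand-implemented; no Firth implementation exists in the
dependency stack) and the reported p comes from the penalized
likelihood-ratio test, which stays calibrated under separation where
the Wald statistic does not; the fallback is always flagged
(`method="firth_plrt"`). Constant age is dropped from the design
(reducing to the unadjusted fit) rather than producing a singular
matrix.

**Stability.** Per individual and gene with ≥ 2 time points: the range
and maximum pairwise difference of region means; cohort summary is the
median of ranges. Single-time-point individuals are excluded.

**Mosaic dilution.** Prediction f·μ_tri + (1−f)·μ_di; inversion
(observed − μ_di)/(μ_tri − μ_di) clipped to [0, 1]; loci with equal
state means are rejected as uninformative. The multi-gene estimator is
an inverse-variance-weighted mean of per-gene estimates (weights
(μ_tri−μ_di)²/var) — an extension beyond the purely descriptive
treatment of mosaic samples in the source study, and labelled as such.
With the default panel and dispersions the single-sample estimator has
SD ≈ 0.075, so recovery of a planted fraction is tested at a ±0.15
(2 SD) band.

**Cell-mixture explainability.** Given per-type methylation m_c, a
plausible-proportion box [l_c, u_c] and reference proportions w⁰, the
maximum achievable bulk shift is max over {l ≤ w ≤ u, Σw = 1} of
|Σw_c m_c − Σw⁰_c m_c|. The objective is linear, so the optimum sits at
a vertex of the polytope; greedy budget allocation in methylation order
(fractional-knapsack argument) reaches it exactly, and a grid-search
oracle confirms this in the tests. `explainable` is true when the
maximum reaches the observed difference; the answer is symmetric in the
observed difference's sign.

## Expression

ΔCT relative expression with amplification efficiency fixed at 2.0
(configurable; no standard-curve module). Group tests default to Welch
(the source describes only "T-test"; pooled is behind a flag), on the
linear expression scale (log behind a flag). Dose-response trends use
Spearman rank correlation (the source reports directions only; Spearman
assumes monotonicity without shape). Concordance uses promoter logic —
hypomethylation in DS predicts over-expression and vice versa — and
flags, rather than suppresses, paradoxical genes; note that a gene
whose differential methylation sits in a repressor element (the
TCF7-like configuration) is flagged paradoxical under promoter logic
even when the repressor mechanism explains it.

## Problem sizes and what the tests show

The test and acceptance runs use desk-scale problems: cohorts of tens
of samples, 500–2000 null loci, 20-seed classifier replicates, and the
published validation-series sizes (up to 207 + 73 per gene). Group-mean
recovery targets average three replicate cohorts because a single
simulated cohort at n = 73 has Monte Carlo SE up to ~0.7 percentage
points from the age-trend spread alone. The genome-wide screen counts
of the original study (tens of differentially methylated loci out of
~27,000) depend on its unreleased primary arrays and are covered by
distribution-level properties instead: null type-I-error calibration of
the caller, oracle equivalence of the filters, unbiasedness of the MI
estimator, permutation-null classifier accuracy, and agreement of both
MI modes on noiseless data.

Passing tests show that the estimators are correct under the generator's
assumptions — independent beta-distributed loci, mean-neutral mixtures,
lognormal array noise. Real data add correlated probes, batch effects,
cell-composition confounding with nonzero offsets, and genotype
artifacts at SNP-overlapping probes, none of which the defaults
emulate; the mixture layer and offsets allow constructing such
scenarios explicitly.

## Known limitations

- Cross-array normalisation is a simple equal-median scaling, a
  deterministic stand-in for model-based array normalisation, whose
  internals are out of scope.
- The Class-2 filter aggregates SM/S across samples by median; whether
  the original experiment filtered per sample or in aggregate is not
  documented.
- The ratio-mode MI carries the digestion-leak bias (1−MI)·leak by
  construction; background-subtracted mode removes it.
- The concordance table's promoter logic intentionally mislabels
  repressor-element genes (see above).
- No reference-based cell-type deconvolution; the mixture test bounds
  what composition shifts could explain, it does not estimate
  composition.
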