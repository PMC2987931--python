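# trisomethyl

Gene-specific DNA methylation analysis in trisomy 21 (Down syndrome, DS)
versus control leukocytes.

Trisomy 21 does not rewrite the blood methylome wholesale, but a small
set of genes — many with roles in lymphocyte development (*TMEM131*,
*TCF7*, *CD3Z*, *SH3BP2*, *EIF4E*, *PLD6*, *SUMO3*, *CPT1B*) — shows
recurrent, stable gains or losses of CpG methylation in DS peripheral
blood leukocytes. This package implements the complete computational
side of that analysis as a tested, reusable pipeline, driven by a
synthetic-cohort generator so every stage runs end to end with no
external data:

- **simulate** — cohorts with planted differential loci at the validated
  effect sizes, beta-distributed bounded noise, an age trend in
  controls, mosaic-trisomy dilution, a cell-type mixture layer,
  digest-array intensities, pyrosequencing tables, and qPCR tables;
- **msnp** — methylation indices from methylation-sensitive
  digest-representation arrays (S = StyI, SH = StyI+HpaII,
  SM = StyI+MspI): MI = SH_av/S_av (or background-subtracted
  (SH_av−SM_av)/(S_av−SM_av)), with the Class-2 reliability filter
  median(SM_av/S_av) < 0.5;
- **diffmeth** — per-locus one-way ANOVA plus layered effect criteria
  (PBL screen: p < .01, fold > 1.2, absolute difference > 0.1; T-cell
  screen: p < .01, fold > 1.3, absolute difference > 0.15), X/Y probes
  removed, supervised average-linkage clustering on 1 − r distance;
- **classify** — logistic ridge regression (penalized likelihood
  ℓ(β) − λ‖β‖², λ = 10⁻⁸, intercept unpenalized) with leave-one-out
  cross-validation and mosaic-sample scoring;
- **validation** — pyrosequencing region means (≥ 8 successive CpGs),
  age-adjusted logistic regression with a Firth bias-reduced fallback
  under separation, longitudinal stability, the linear mosaic dilution
  model m = f·μ_tri + (1−f)·μ_di, and an exact cell-mixture
  explainability test over the proportion polytope;
- **expression** — ΔCT relative expression 2^(−ΔCT), Welch group tests,
  the trisomic 3:2 dosage expectation, and 5aza-dC dose-response trends
  (Spearman).

## Worked example

The numbered drivers under `analysis/` run the full study on a
simulated cohort (29 DS including one 45%-trisomic mosaic and four
repeat blood draws, 20 controls, 9 planted loci + 500 null loci):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_msnp_methylation_index.py
python analysis/03_differential_methylation.py
python analysis/04_classify_loocv.py
python analysis/05_validation_stats.py
python analysis/06_expression.py
```

Output of steps 03–05 (seed 1):

```
screen (pbl criteria: p<0.01, fold>1.2, |diff|>0.1):
  7 of 509 loci called (7 genes: CD3Z, CPT1B, EIF4E, PLD6, SUMO3, TCF7, TMEM131)
  supervised clustering: leaf order splits into 2 group blocks (2 = clean DS/control separation)

LOOCV over 49 samples, 7-locus panel, lambda=1e-8:
  sensitivity 97%, specificity 100%
  mosaic sample DS29 (45% trisomic): DS probability 0.211

age-adjusted logistic regression at published series sizes:
   TMEM131: DS 10.8% vs control 40.2%, p = 1.36e-68 (firth_plrt)
   ...
  max p across genes: 7.40e-08
stability: 36 individual-gene repeat pairs, median within-individual range 2.1 points
mosaic DS29: estimated trisomic fraction 0.50 (truth 0.45, 9-gene panel)
```

Reading this: the layered screen recovers the planted panel (weakly
differential *FAM62C* and *SH3BP2* miss the 0.1 absolute-difference bar at
this cohort size); the one "missed" DS sample in cross-validation is
exactly the mosaic individual, whose methylation — and therefore DS
probability — sits toward the control side in proportion to its diploid
cell fraction; and the targeted validation statistics at the published
series sizes are all far below p = 10⁻⁴.

The same stages are exposed as a CLI
(`trisomethyl simulate|msnp-mi|call-diff|classify|validate|express|all
--config run.yaml --seed N --out DIR`), with byte-identical outputs for
identical config + seed.

## Layout

```
src/trisomethyl/    library: types, io, simulate, msnp, diffmeth,
                    classify, validation, expression, pipeline, cli
analysis/           numbered narrative drivers (write under results/)
tests/              pytest suite (unit, property, acceptance)
scripts/            acceptance.py
docs/methods.md     model, parameter and design documentation
```
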