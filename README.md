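# mrt-irt

Explanatory item response theory for mental rotation test (MRT) items.

Mental rotation tests present block figures rotated in 3-D and ask which
alternative matches (or differs from) a target. Item difficulty in such
tests varies widely, and the sources of that variation — how many cubes the
figure has, whether distractors are mirror images, whether parts of the
figure are occluded, and so on — are of direct interest to test developers,
as are gender differences in how those features play out. This package
implements the complete analysis chain a psychometrician would run on a
dichotomously scored MRT:

1. **Classical screening** — proportion correct, corrected item-total
   correlations, Cronbach's alpha.
2. **Rasch calibration** — the one-parameter logistic model
   `P(X_ni = 1) = exp(θ_n − δ_i) / (1 + exp(θ_n − δ_i))`, estimated by
   conditional maximum likelihood (CML) with elementary symmetric functions,
   under the sum-zero constraint Σδ = 0; with the standard diagnostic
   battery: infit/outfit mean squares and standardized z, the Andersen
   likelihood-ratio test, principal components of standardized residuals,
   inter-item residual correlations, and a variance-explained summary.
3. **DIF** — per-item standardized difficulty differences between two groups,
   `z = (δ_ref − δ_focal) / √(SE_ref² + SE_focal²)`.
4. **LLTM** — the linear logistic test model, which constrains each item
   difficulty to a weighted sum of feature effects, `δ′_i = Σ_j q_ij η_j`,
   over a binary items × features Q-matrix; compared with the Rasch model by
   a nested likelihood-ratio test and by the correlation of the two
   difficulty sets.
5. **DCF** — differential component functioning: group-wise LLTM
   calibrations compared feature-by-feature with Wald chi-square statistics
   `W = (η_ref − η_focal)² / (SE_ref² + SE_focal²) ~ χ²(1)` at a
   Bonferroni-adjusted level α* = α/J.

A synthetic-response generator (`SimulationDesign` / `simulate_responses`)
produces data with exactly this structure — normal abilities, LLTM
difficulties, optional group-specific feature effects (DCF) and per-item
shifts (DIF) — so every stage is testable without any external download.
The package also ships the published 15-item MRT instrument's Q-matrix and
calibrated feature-effect vector as a fixture (`mrt_fixture`).

## Worked example

```python
import mrt_irt as m

q, eta, items = m.mrt_fixture()
design = m.SimulationDesign(q=q, eta=eta, n_persons={"male": 300, "female": 200}, seed=7)
responses = m.simulate_responses(design)

report = m.run_full_analysis(responses, m.mrt_feature_table())

print(f"Cronbach's alpha: {report.cronbach_alpha:.2f}")
lr = report.global_fit["andersen_lr"]
print(f"Andersen LR: chi2({lr['df']}) = {lr['statistic']:.2f}, p = {lr['p_value']:.3f}")
mc = report.model_comparison
print(f"Rasch vs LLTM: LR = {mc['lr_statistic']:.2f} on df = {mc['df']}, "
      f"r(delta_Rasch, delta_LLTM) = {mc['pearson_r']:.3f}")
print(report.feature_table.round(2).to_string(index=False))
```

prints (this exact run):

```
Cronbach's alpha: 0.69
Andersen LR: chi2(14) = 13.10, p = 0.519
Rasch vs LLTM: LR = 7.51 on df = 8, r(delta_Rasch, delta_LLTM) = 0.999
        feature   eta   se  ci_lower  ci_upper
         Ncubes  3.49 0.16      3.17      3.81
          Color  2.35 0.17      2.01      2.69
Image structure -0.56 0.07     -0.69     -0.42
      Occlusion -0.65 0.07     -0.79     -0.50
       Rotation  1.41 0.08      1.26      1.56
  Configuration -1.15 0.06     -1.27     -1.02
```

Reading the output: internal consistency is acceptable (α = 0.69 for a
simulated 500-person sample); the Andersen test does not reject Rasch-model
invariance (p = 0.52); the LLTM restriction is not rejected against the
unstructured Rasch model (the data were generated from the LLTM, so LR ≈ df),
and the recovered feature effects bracket the generating values
(3.65, 2.45, −0.59, −0.62, 1.50, −1.07) within their confidence intervals.
Cube count and colored distractors are the strongest difficulty drivers;
occlusion, mirror-image structure and homogenous configuration make items
easier. Since both simulated groups share one η vector, the DCF table in
`report.dcf_table` finds no significant feature difference.

The same pipeline is available from the shell:

```sh
mrt-irt simulate --seed 7 --out sim/          # response CSV + truth JSON
mrt-irt fixture  --out fixture/               # packaged Q-matrix / features
mrt-irt run --responses sim/responses.csv --features fixture/features.csv \
            --group-col group --out report/
```

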