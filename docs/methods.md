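# Methods

## Models

**Rasch model.** Dichotomous responses follow
`P(X_ni = 1) = expit(θ_n − δ_i)` with person ability θ_n and item difficulty
δ_i, both in logits. Item difficulties are estimated by conditional maximum
likelihood (CML): conditioning on each person's raw score removes θ from the
likelihood, so the item estimates carry no assumption about the ability
distribution. The conditional probability of a response pattern with raw
score r is `Π_i ε_i^{x_i} / γ_r(ε)` with easiness `ε_i = exp(−δ_i)` and
γ_r the elementary symmetric function (ESF) of order r. The scale origin is
fixed by Σδ = 0 (enforced through a contrast basis, exact to machine
precision); this makes printed item tables comparable across runs.

**LLTM.** The linear logistic test model replaces the free difficulties with
`δ′_i = Σ_j q_ij η_j` over a binary Q-matrix. There is no intercept and no
extra normalization: the η vector is identified by the structure whenever
the all-ones vector is not in the Q-matrix column space (true of the
packaged instrument). A consequence worth knowing: LLTM implied difficulties
and sum-zero Rasch difficulties can differ by a location shift, which is why
model concordance is summarized by the (location-invariant) Pearson
correlation of the two difficulty sets, not by agreement. The nested
likelihood-ratio statistic is the difference of −2 conditional
log-likelihoods on `(k − 1) − J` degrees of freedom, and the R² of the
difficulty correlation is flagged against the conventional 0.76 concordance
threshold.

**DIF / DCF.** Group invariance is assessed twice. At the item level, each
group is calibrated separately (each with its own sum-zero normalization —
the established practice; the resulting scale alignment is approximate and
noted in the output rather than silently assumed) and differences are
standardized as `z = (δ_ref − δ_focal)/√(SE_ref² + SE_focal²)` against the
normal. At the feature level, group-wise LLTM calibrations are compared per
feature with the Wald statistic
`W = (η_ref − η_focal)²/(SE_ref² + SE_focal²) ~ χ²(1)` at the Bonferroni
level α* = α/J (0.05/6 ≈ 0.008 for the packaged instrument). Signs are
always reference-minus-focal, with an explicit "harder for" column so the
sign convention cannot be misread.

## Numerics

* **ESFs** are computed by the summation recursion in log space
  (`logaddexp`), stable for tests of 50+ items. Gradients need leave-one-out
  ESFs and the observed information needs leave-two-out ESFs; both are
  computed by the same recursion vectorized over items/pairs, O(k³) and
  O(k⁴) log-space operations per evaluation — negligible for realistic test
  lengths.
* **Optimization** is Newton–Raphson on the observed information with
  step-halving, from a zero start, converging when the gradient's maximum
  absolute entry falls below 1e−8 (cap 200 iterations; typical fits take
  5–8). The LLTM re-uses the same engine with the chain rule through Q.
  Standard errors come from the inverse observed information, mapped through
  the contrast basis (Rasch) or the Q-matrix (LLTM, delta method
  `SE(δ′_i) = √(q_i' Σ_η q_i)`).
* **Estimability.** Persons with extreme raw scores (0 or k) carry no
  conditional information and are excluded from estimation but kept in the
  data; items with no variance among the remaining persons are excluded with
  a logged warning (their difficulty lies at ±∞ — the silent behaviour of
  standard Rasch software made explicit). Beyond that, a finite CML maximum
  requires the item comparison digraph (edge i→j when someone solved i but
  not j) to be strongly connected; quasi-separated data are rejected with a
  clear error instead of returning divergent estimates.
* **Person abilities** are ML given the CML difficulties (Newton on the
  score equation). Extreme scores get finite proxies via the half-score
  adjustment (0 → 0.3, k → k − 0.3) and are flagged.
* **Fit statistics.** Outfit is the unweighted mean of squared standardized
  residuals, infit the information-weighted version; both are standardized
  through the Wilson–Hilferty cube-root transformation with their model
  variance (the conventional ZSTD). Item statistics aggregate over
  non-extreme persons. Items are flagged as misfitting when either |z|
  reaches the configured threshold (default 2.0).
* **Residual structure.** The residual PCA takes eigenvalues of the
  item-by-item correlation matrix of standardized residuals over complete,
  non-extreme rows; a largest eigenvalue below 2.0 (configurable) is read as
  sufficient unidimensionality. Note that off-diagonal residual correlations
  have a built-in negative bias of roughly −1/(k − 1) under the model, so
  "near zero" means near that value, not 0 exactly.
* **Variance explained** is the R² of the fitted probabilities against the
  observed 0/1 responses, `1 − Σ(x − P)²/Σ(x − x̄)²` over non-missing cells
  with x̄ the grand mean. This raw-residual definition is one of several in
  circulation; it is the package's convention.
* **Andersen LR test** splits at the median raw score by default; degrees of
  freedom are computed from the parameters actually estimated per subgroup
  (subgroup item exclusions are logged), which is what printed dfs from
  standard software reflect.

## Missing data

Missing responses are treated as "not administered": excluded from raw
scores and from all likelihood sums (persons are grouped by
administered-item pattern, so the ESF denominators are pattern-specific).
Cronbach's alpha uses complete cases with a logged count; item-total
correlations use each item's respondents against their rest-scores. Persons
with missing group labels stay in pooled analyses and are dropped, with a
logged count, from group-wise analyses.

## Pipeline conventions

Misfit handling is a single pass: flag at the configured threshold, remove
(if `remove_misfit_items`), re-fit once. Iterative purification is
deliberately not performed. The Q-matrix is rebuilt on the retained items
(the cube-count mean split therefore uses the retained items' mean; ties at
the threshold code 0 because the rule is strict ">"). All result tables
carry full-precision values, with 2-decimal display columns added only at
write time.

## Synthetic data generator

`simulate_responses` draws θ per group from a normal distribution, builds
δ = Qη (+ optional per-item shifts) and draws independent Bernoulli
responses, all from one seeded generator stream (same seed ⇒ bit-identical
data). Defaults: SD 1; when no ability mean is given, abilities are centred
on the mean generated difficulty — an instrument targeted at its population.
This matters for the packaged fixture, whose Qη difficulties are not
centred: because CML conditions the ability location out entirely, centring
θ on mean(Qη) reproduces the same response distributions as a standard-normal
population facing centred difficulties, without breaking the exact LLTM
structure (centring δ itself would, since the all-ones vector is outside the
Q-matrix column space).

What the generator emulates: the logistic response process, LLTM difficulty
structure, group-specific feature effects and additive DIF shifts. What it
does not: guessing (multiple-choice items have a nonzero floor the Rasch
model ignores), response dependence, speededness, response times, or any
missingness mechanism. Passing recovery and calibration tests on generated
data therefore validates the estimators and test procedures under their own
assumptions; they do not certify robustness to violations real MRT data may
contain.

## Test-suite problem sizes

Stochastic checks run at sizes chosen to keep the suite quick while leaving
comfortable statistical margins: one n = 2000 fixture draw for feature-effect
recovery (every η within 2 SE), 200 replications at n = 500 for difficulty
RMSE (< 0.15 logits, per-item bias within ±0.05), 500 null replications at
n = 250/group and 14 items for DIF/DCF error-rate calibration (mean per-item
flag rate within the 99% binomial envelope of 0.05; Bonferroni familywise
DCF error within its nominal bound), 50 random micro-datasets (≤ 4 items,
≤ 20 persons) against a brute-force enumeration oracle (agreement to 1e−4),
and 40–60 replications for the nominal-rate checks of the Andersen and
nested LR tests.

## Known limitations

Only dichotomous responses (no partial credit/rating scale), only CML (no
MML or Bayesian estimation, hence no population distribution estimates),
exactly two groups for DIF/DCF, no purification iterations, no interaction
features in the Q-matrix, and no random-item extension of the LLTM (the
feature decomposition is treated as exact up to the LR-test verdict).
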