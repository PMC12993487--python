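# Methods

## The problem

Microbiome count tables from designed experiments (factorial treatments,
time courses) are zero-inflated, overdispersed, compositional and
high-dimensional. Univariate differential-abundance tools fit one model per
taxon and ignore the multivariate structure; classical ASCA (ANOVA
simultaneous component analysis) captures the multivariate design structure
but assumes Gaussian responses. `glmasca` combines the two: per-taxon
Tweedie GLMs supply a linearized *working response* matrix, which is then
decomposed into orthogonal design-effect matrices and analysed by PCA and
permutation tests.

## Model

For taxon *j* with counts **y**ⱼ over *n* samples and a shared sum-coded
design **X** = (X₀ | X₁ | … | X_F) (intercept, mains, interactions), we fit
a GLM with log link and Tweedie variance Var(Y) = φⱼ·μ^ρⱼ. For 1 < ρ < 2
the Tweedie is the compound Poisson–gamma: positive probability at exactly
zero and a continuous skewed density on (0, ∞) — a single-family treatment
of zero inflation and overdispersion that needs no pseudocounts and no
separate zero model.

IRLS maximum likelihood yields, per taxon, the coefficient vector β̂ⱼ, the
linear predictor η̂ⱼ = Xβ̂ⱼ, weights ŵᵢⱼ = μ̂ᵢⱼ^(2−ρⱼ) (log link), working
residuals r̂ʷ = D̂⁻¹(y − μ̂) with D̂ = diag(∂μ/∂η), and working response
ẑ = η̂ + r̂ʷ. Stacking over taxa gives Ẑ = XB̂ + R̂ʷ, which splits into effect
matrices M_f = X_f B̂_f.

**Orthogonality.** For a *balanced* design (equal replication R in every
factor-level cell) and a *saturated* model (one parameter per cell), the
weighted hat matrix collapses to (1/R)-scaled identity blocks, commutes
with the weights, and makes η̂ ⊥ r̂ʷ in the unweighted inner product. Hence

    ‖Ẑ‖² = Σ_f ‖M_f‖² + ‖R̂ʷ‖²,

exactly, and each effect's importance is
%Var_f = 100·‖M_f‖² / (‖Ẑ‖² − ‖M₀‖²), with the residual share defined with
the same denominator so the table sums to 100. A second route to
orthogonality — links constructed so the IRLS weights are constant
(`constant_weight_link`), e.g. gamma with log link — needs only balance,
not saturation; both routes are implemented and verified numerically
(`verify_orthogonality`, `hat_matrix`).

**Offsets are rejected** by the model API: an offset shifts η̂ outside the
column space arithmetic that the decomposition relies on; normalize the
counts instead.

## Normalization

* `poscounts`: per-taxon reference = geometric mean over *positive* counts
  (zeros excluded from the log sum, n kept in the denominator); sample size
  factor = median ratio over co-positive taxa, rescaled to geometric mean 1
  (identifiability; verified against DESeq2's `type="poscounts"` on a toy
  matrix). Zeros stay zeros.
* `mclr`: per sample, log counts centred by the mean log of that sample's
  nonzero entries; zeros preserved; one global shift (|min| + 1) keeps all
  transformed nonzero values positive so the Tweedie support still applies.

Normalized values are never rounded — the compound Poisson–gamma supports
continuous positive data with exact zeros.

## Estimation choices

* **ρ grid**: profile likelihood over ρ ∈ {1.05, 1.10, …, 1.95} per taxon.
  At each grid point all taxa are refitted by IRLS (β̂ does not depend on φ)
  and φ is profiled out by golden-section search on log φ, bracketed three
  log-units around the Pearson moment estimate Σ(y−μ̂)²/μ̂^ρ/(n−m). The
  bracket keeps the series normalizer away from pathologically small
  dispersions; the grid winner and its φ̂ are returned.
* **Density**: the compound Poisson–gamma normalizer a(y; φ, ρ) is an
  infinite series over the latent Poisson count; we sum a window centred on
  the analytically located mode, widening until edge terms fall below 1e−12
  of the maximum (verified against an independent wide-window evaluation,
  against statsmodels' Tweedie log likelihood, and by numerical integration
  of the total mass to 1 within 1e−4).
* **IRLS**: initialization μ⁽⁰⁾ = (y + mean of positive y)/2; convergence on
  relative deviance change < 1e−8; max 100 iterations; step-halving if a
  step increases the deviance. Non-convergent taxa are kept and flagged
  (droppable via `drop_nonconverged`).
* **Boundary cells.** A design cell whose responses are all zero has its
  saturated-model MLE on the boundary (cell mean 0, log-link coefficient
  −∞). Left alone, the linear predictor drifts without limit and a handful
  of sparse taxa dominate every norm in the decomposition. Fitted means are
  therefore floored at a detection limit: the taxon's smallest positive
  value divided by R — the smallest mean any cell with at least one
  detection can have — so no interior estimate is ever clipped while
  boundary cells stay on the data's own log scale. For taxa with boundary
  cells the sum-of-squares partition is then only approximate (relative gap
  around 1e−2 on sparse tables); with a per-cell presence filter (the
  recommended real-data workflow) no boundary cells survive and the
  partition is exact.

## Inference

Row permutations of the normalized response table (design fixed) destroy
all sample–design association; each permutation triggers a full refit with
the per-taxon ρ̂ held at its observed-data estimate (nuisance; full
re-estimation available via `reestimate_power=True`). Permutation RNG
streams are spawned per permutation from the master seed, so results are
independent of execution order and bit-reproducible.

* **Global test** per effect: SS_f = ‖T_f^q‖², the squared Frobenius norm of
  the first-q PC scores of M_f; p = (#{SS⁽ᵏ⁾ ≥ SS} + 1)/(N_p + 1).
* **Feature test** per effect: scaled leverage h_fj = Σ_{k≤q} λ_k P_jk²,
  the squared loadings weighted by the variances the components explain.
  With absolute variances (default) the leverages sum to the global
  statistic and respond to effect scale; the variance-*share* weighting
  (`leverage_scale="share"`) is scale-free and, because permutation
  destroys effect scale but barely moves relative shares, has very little
  per-feature power — it is kept as an option for comparability. Raw
  p-values are BH-adjusted across the taxa of the tested effect;
  significance means p_adj < α (default 0.05).
* **q rule**: per effect, the smallest q whose cumulative explained variance
  reaches 80% (`"var80"`), resolved on the observed data and held fixed
  across permutations; integers and `"full"` are accepted. q need not agree
  across effects or between the global and feature tests.
* Combined effects (e.g. a treatment main effect plus its interaction with
  time, when the interaction is significant) are tested by summing the
  orthogonal effect matrices before the PCA.

The smallest attainable p is exactly 1/(N_p + 1); with 9,999 permutations
that is 0.0001.

## Synthetic data

The generator emulates a factorial microbiome experiment: per taxon a
zero-inflated truncated log-normal with parameters (μ̃ⱼ, σⱼ², πⱼ) — zero
with probability πⱼ, otherwise round(exp(N(μ̃ᵢⱼ, σⱼ²))) truncated below at 1
so nonzero draws look like detected counts. Differential taxa shift μ̃ᵢⱼ
additively through the sum-coded covariates: β₁ on the condition code, (β₂,
β₃, β₄) on the time codes, (β₅, β₆, β₇) on the interaction codes.

Defaults (the study configuration): 2 conditions × 4 time points × 5
replicates (n = 40), p = 206 taxa, 45 spiked (20 condition / 15 time / 10
interaction, drawn among taxa with prevalence ≥ 20%), effect sizes
(2, 3, 1.5, 1.5, 2.8, 2.4, 1.4) with half of each class negated. Null
parameters default to values typical of a filtered 16S survey —
μ̃ⱼ ~ N(3.5, 1), σⱼ ~ U(0.5, 1.5), πⱼ ~ U(0.05, 0.60) — or can be estimated
from a template table by method of moments (`estimate_null_params`; the
moment estimator stands in for hierarchical-Bayes template fitting, which
is out of scope).

What the generator does **not** emulate: taxon–taxon correlation, read-depth
(library-size) variation and the induced compositional coupling, batch
effects. Passing tests therefore demonstrate correctness of the machinery
and calibration under independent zero-inflated log-normal taxa, not
robustness to compositional artefacts.

## Evaluation study

`run_simulation_study` generates replicate datasets, applies the abundance
filter (≥10 counts in ≥5 samples), poscounts normalization, the Tweedie
GLM-ASCA fit and per-effect feature tests, and scores calls against ground
truth: FDR (0 for an empty call set), sensitivity, specificity, F1,
Matthews correlation, and a rank-based AUC using 1 − p_raw as the score.
Taxa removed by the filter count as non-calls (false negatives if spiked).
Metrics are reported per effect and pooled; Monte-Carlo standard errors
accompany the means. Dataset and permutation seeds derive deterministically
from the master seed.

Observed behaviour at the default study size (20 datasets, n = 40, 999
permutations): the pooled mean FDR sits well below the nominal 5% level
(the test is conservative — permutation ties and leverage competition both
push p up), the feature ranking is strong (mean AUC above 0.9), and
per-feature sensitivity is high for the 1-df condition effect but low for
sparse taxa spiked on the 3-df time and interaction effects: with ~50%
zeros, truncation of nonzero draws at 1 and the detection-limit floor
compress the observable dynamic range, so a permutation that happens to
clump zeros can mimic the aligned pattern. Power recovers with replication
(n = 80, 160) and for well-detected taxa.

## Problem sizes used

Simulation-heavy checks are run at sizes chosen to make their Monte-Carlo
error small relative to the asserted tolerance while keeping the suite
practical on a single CPU: 20 replicate datasets at n = 40 with 999
permutations for the FDR study; 500 null simulations with 99 permutations
for the type-I calibration; n = 2000 for power-parameter recovery; 20
random designs for the orthogonality sweep.

## Known limitations

* Unbalanced or unsaturated designs break the exact decomposition; the
  model warns, the pipeline aborts unless forced, and the orthogonality
  report quantifies the gap. Projection-based corrections are out of scope.
* Continuous covariates, nested/random effects and longitudinal mixed
  models are not supported.
* The per-feature permutation test is conservative for sparse taxa (see
  above); interpret absence of significance for low-prevalence taxa with
  care, or filter per cell as in the recommended workflow.
* ρ is selected on a grid; between-grid values are not interpolated.
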