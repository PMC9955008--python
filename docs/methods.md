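# Methods

This note documents the statistical machinery implemented in `codmi`, the
conventions chosen where several readings were defensible, and what the
test suite does and does not establish.

## Model and scope

The data are right-censored survival records zᵢ = (tᵢ, dᵢ) from a
homogeneous cohort, with dᵢ = 1 for a death of the disease under study and
dᵢ = 0 for non-informative censoring, plus m COVID-death times θⱼ whose
status indicator is missing: a COVID death is informative (correlated with
disease progression), so neither naive classification is acceptable. The
survival model is strictly the non-parametric Kaplan–Meier product-limit
distribution — no covariates, no Cox-type regression, no
cumulative-incidence competing-risks machinery. The "true" distribution is
*defined* as the best-fitting KM distribution of the extended data (standard
records plus virtual lifetimes); this self-referential definition is what
the EM iteration and the simulation's truth construction both lean on.

## Kaplan–Meier conventions

- **Per-record at-risk accounting.** The at-risk count decrements by one
  per record, so g tied records contribute g hazard factors. Survival
  values agree with the usual distinct-time product; the per-record form is
  required by the extended variance formula, whose at-risk recursion runs
  over records. `summary()` provides the distinct-time table for reporting.
- **Tie ordering.** Deaths precede censorings at tied times (a censored
  subject at t is still at risk for a death at t); same-status ties keep
  input order (stable sort), making every computation deterministic.
- **Left continuity.** S(t) = P(T ≥ t); evaluation at an event time returns
  the pre-jump value, `side="right"` gives P(T > t). Greenwood sums use the
  inclusive (≤ t) convention and the post-jump S.
- **Completion.** Life expectancies need a full distribution. When the
  largest observation is censored, the fit (not the data) treats that single
  record as a death, relocating the residual mass Q_fin to t_max. This
  matches the classical observation that self-consistency of the KM
  estimator holds only when S(t_max) = 0, and amounts to reading T as the
  lifetime *within the study*, min(T, t_max).
- **Strict truncation.** e_θ averages over masses at times strictly greater
  than θ; mass exactly at θ is excluded. A θ with no mass strictly beyond it
  raises — never a silent zero.

## The EM iteration

Initialization sets τ̂⁽⁰⁾ⱼ = θⱼ (`at_theta`) or θⱼ + ê_θⱼ(z) (`expectancy`,
the default, and the mode used throughout the simulation study). Each sweep
fits the completed KM distribution of w = z ∪ {(τ̂ⱼ, 1)} and replaces each
τ̂ⱼ with θⱼ + ê_θⱼ. Convergence is declared when
max_j |ê⁽ᵏ⁺¹⁾ⱼ − ê⁽ᵏ⁾ⱼ| < ε (absolute value — a signed difference cannot
define a stopping rule); the first comparison is made against the
expectancies implied by the initializer (zero under `at_theta`), and one
iteration means one estimation+expectation sweep, initialization not
counted. On the embedded Arm A example this convention yields exactly 10
sweeps at ε = 0.1 and 33 at ε = 1e-8, with the imputed vector stable to two
decimals between the two — the trailing drift between tolerance levels is
itself of order ε, so "the fixed point" is only defined up to the chosen
tolerance.

**Cyclicity.** The iteration is not guaranteed to converge; it can enter a
genuine cycle (the test suite carries an 11-record data set with a
period-4 cycle). Iterates are hashed after rounding; the rounding quantum
adapts to be at least two decades finer than ε, since a coarse quantum
makes slow asymptotic convergence look like a period-1 cycle. On
recurrence, the iterate with the smallest successive change in the cycle is
returned; it is accepted if that change is below ε (in practice the main
stopping rule fires first in that case, so a detected cycle normally means
failure). Failure is a status, never an exception. No automatic restart or
data perturbation is attempted; the CLI exposes `--jitter` for a manual,
prominently logged rescue.

COVID times beyond the last death of z are accepted (completion guarantees
mass at t_max); θ at or beyond t_max itself has no mass strictly beyond and
raises with the offending index.

## Adjustment for censoring

To relax the assumption that every COVID-dead patient would have died of
the disease, the converged imputed set is status-reversed (times fixed, all
indicators flipped) and refitted: the reverse-KM distribution estimates
censoring times, and τ̂ⱼ⁽ᴿ⁾ = θⱼ + ê⁽ᴿ⁾_θⱼ is the censoring-consistent
alternative. The choice between τ̂ⱼ and τ̂ⱼ⁽ᴿ⁾ is driven by α(θⱼ), the
probability that an event at θⱼ is a death rather than a censoring, with
α = 0.5 classified as death and user overrides taking precedence.

α̂(t) is fitted on the standard observations only. Empirical cell hazards
(events / person-time at risk in the cell) are computed on an equal-width
grid over [0, t_max] and smoothed by a parametric hazard family fitted by
exposure-weighted least squares **on the log-hazard scale** (Weibull:
log h linear in log t; Gompertz: linear in t; exponential: constant); cells
with no events are excluded from the fit but covered by the curve. α̂ is
piecewise constant per cell, 0.5 where both hazards vanish. Defaults:
Weibull, G = 9 cells. The defaults were chosen so that the direct/reverse
classification on the two embedded NCOG examples lands on the documented
pattern (Arm A: first three COVID times death-like, last two
censoring-like; Arm B: only the first death-like); the α *values* depend
strongly on family and grid — two-parameter hazard pairs can only produce
monotone α curves — so only the classification, not the curve itself,
should be treated as reproducible. G must balance resolution against
per-cell counts; at n ≈ 50, nine cells keeps a handful of events per cell.

**Fully censored endpoints.** When every imputation is classified as a
censoring (α ≡ 0, the simulation's censored regime), a single reverse pass
over the converged direct output is not self-consistent: the imputed
records then sit at death-based positions inside the reverse fit, which
biases the estimates upward of 2% in the Monte-Carlo study.
`reverse_codmi_lifetimes` therefore iterates the expectation step on the
reverse side (standard statuses flipped, imputed records non-events) to the
same tolerance, mirroring the truth construction; the one-shot
`reverse_km_lifetimes` remains the right operation for the mixed worked
example, where it is only applied to the individually reclassified times.

## Extended Greenwood variance

Treating imputed values as observations understates variance. The merged
sample y = (t′ᵢ, d′ᵢ, δ′ᵢ) spreads each imputation j as fractional deaths:
its (direct if δⱼ = 1, reverse if δⱼ = 0) death-mass distribution —
both fitted on the completed merged sample — is truncated strictly beyond
θⱼ and renormalized into q*ᵢⱼ, with totals Qᵢ = Σⱼ q*ᵢⱼ (Σᵢ Qᵢ = m) and
Qᵢ⁽²⁾ = Σⱼ (q*ᵢⱼ)². The corrected hazard is h̄ᵢ = d′ᵢ νᵢ / R̄ᵢ with
νᵢ = (1 − δ′ᵢ) + Qᵢ, and the standard deviation adds
(((R̄ᵢ−1)/R̄ᵢ)Qᵢ − Qᵢ⁽²⁾)/((1−h̄ᵢ)²R̄ᵢ²) per record to the classical
summand h̄ᵢ/((1−h̄ᵢ)R̄ᵢ).

Numerical conventions:

- **At-risk recursion.** The correction enters through the record that has
  just left: R̄ᵢ = R̄ᵢ₋₁ − 1 + (νᵢ₋₁ − 1)d′ᵢ₋₁ (a `literal_recursion` flag
  switches to the same-index reading for sensitivity work; both coincide
  when m = 0).
- With m = 0 the formula reduces *exactly* (≤ 1e-12) to classical
  Greenwood — the key correctness anchor, enforced as a property test.
- Summands with h̄ᵢ = 1 are zero, as in the classical formula; negative
  added-variance terms (not excluded by the formula's derivation for
  extreme configurations) are clamped to zero with a logged warning rather
  than producing a complex root.
- Note the corrected hazards can locally *undercut* the classical ones
  (imputed records carry weight νᵢ = Qᵢ < 1), so the extended s.d. is not
  pointwise ≥ the classical s.d.; the guaranteed properties are
  non-negativity and a CI that strictly contains the estimate.
- Confidence intervals come from bounds on log Ŝ: exp(log Ŝ ± z·sd/Ŝ),
  clamped to [0, 1], z parameterized by level (1.96 at the default 95%).

## Simulation design

Each scenario is built from a real seed arm:

1. **Bootstrap z̃** — n_sim records drawn with replacement, stratified to
   preserve the seed's death/censoring proportion (death count rounded to
   nearest; Arm A's 42/51 gives 82 deaths at n_sim = 100).
2. **COVID times** — preliminary lifetimes τ̃⁽⁰⁾ⱼ resampled from the seed's
   death times not exceeding the bootstrap's last death, thinned by
   θ̃ⱼ = ũⱼ·τ̃⁽⁰⁾ⱼ, ũⱼ ~ U(0,1). Only the uniform law is implemented.
3. **Truth** — n_iter conditional-expectation sweeps of the completed KM
   fit of z̃ ∪ {(τ̃, 1)} (its status-reversal in the censored regime, the
   imputed records remaining non-events there), then one draw per j from
   the truncated final distribution. Limiting to n_iter = 10 sweeps rather
   than full convergence deliberately accepts a small bias in exchange for
   robustness. Should truncation support be empty for some j, its ũⱼ is
   redrawn up to 100 times before the scenario is dropped — under
   completion this is provably unreachable (positive mass always sits at
   t̃_max > θ̃ⱼ), but the guard documents the degenerate-input policy.
4. **Estimates** — CoDMI (ε = 1 day, expectancy init, ≤ 100 sweeps) plus
   the two naive estimators (θ̃ classified as death / as censoring, life
   expectancy read from the corresponding completed fit). In the censored
   regime CoDMI is followed by the iterated reverse adjustment with all
   α forced to 0, and the unadjusted estimate is kept for comparison.

Non-convergent scenarios (about 1.5% on Arm A, 7% on Arm B, dominated by
extreme bootstrap configurations that cycle) carry no estimate; means and
standard errors are computed over the N_c convergent scenarios only, with
naive estimates summarized over the same set for comparability. The
overall s.e.m. is the standard deviation of the per-scenario mean error
divided by √N_c. A single `SeedSequence` spawns per-scenario substreams, so
batches are bit-for-bit reproducible and trivially parallelizable.

Default problem sizes — n_sim = 100, m_sim = 10, n_iter = 10, ε = 1,
itermax = 100 — are the reference study conditions; the package runs
N = 5000 scenarios per regime in its acceptance script (≈ 15 s per regime
on one core), which puts the Monte-Carlo standard error of the overall
relative prediction error near 0.2–0.45 percentage points; the test suite
uses N = 2000 for the same checks.

**What the simulation does and does not show.** Scenarios inherit the
discrete support of the seed arm: heavy ties, a hard upper bound at the
seed's largest death time, and a truth process that is *by construction*
the model CoDMI assumes (the self-consistent KM distribution of the
extended data). Passing therefore demonstrates internal consistency and
near-unbiasedness under the model's own data-generating mechanism — it
says nothing about misspecification (covariate-driven dependence between
disease and COVID mortality, interval censoring, continuous-time
smoothness), which real data will exhibit.

## Known limitations

- Identifiability of the fixed point is an open question; results are
  sensitive to initialization in non-convergent cases, and the package
  deliberately offers no automatic multi-start search.
- The α curve is a coarse, grid- and family-dependent heuristic; it is a
  decision aid for setting δⱼ, not a calibrated probability model.
- The extended variance formula treats the fractional-death masses as
  fixed weights; uncertainty in the imputation *positions* τ̂ⱼ themselves
  is not propagated beyond the binomial-mixing argument behind the added
  term.
- Iteration counts are convention-dependent (what the first comparison is
  made against, whether initialization counts); the package's convention is
  fixed and documented above, but counts from other implementations may
  differ by a small offset even when the fixed points agree.
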