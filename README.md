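# codmi — Covid-Death Mean-Imputation for Kaplan–Meier survival analysis

COVID-19 deaths of oncological patients in a survival study are neither
deaths of the disease under study nor non-informative censorings: the strong
correlation between cancer progression and COVID-19 mortality makes them
*informative* censorings, which the classical Kaplan–Meier (KM) estimator
cannot absorb. `codmi` implements an EM-style answer for biostatisticians
and trial analysts: each COVID-death time θ is replaced by the counterfactual
**virtual lifetime** τ̂ = θ + ê_θ, where ê_θ is the mean residual lifetime
under the KM distribution fitted to the standard data *plus the imputed
records themselves*, iterated to a fixed point.

Given records z = {(tᵢ, dᵢ)} (time, status: 1 = death of disease, 0 =
censoring) and COVID-death times θ₁…θ_m, each sweep

1. **estimation** — fits the product-limit estimator
   Ŝ(t) = ∏_{i: t₍ᵢ₎ ≤ t} (1 − d₍ᵢ₎/R(t₍ᵢ₎)) to w = z ∪ {(τ̂ⱼ, 1)}, forcing
   Ŝ(t_max) = 0 (distribution completion) when the largest time is censored;
2. **expectation** — recomputes each life expectancy on the truncated
   death-mass distribution, ê_θ = Σ_{t₍ᵢ₎>θ} (t₍ᵢ₎−θ) q₍ᵢ₎ / Σ_{t₍ᵢ₎>θ} q₍ᵢ₎,

stopping when max_j |ê⁽ᵏ⁺¹⁾ − ê⁽ᵏ⁾| < ε. Around this core the package
provides

- **adjustment for censoring**: reverse-KM virtual lifetimes (all statuses
  flipped), a grid-fitted non-censoring probability curve
  α̂(t) = ĥ(t)/(ĥ(t) + ĥ⁽ᴿ⁾(t)), and the selection rule τ̂*ⱼ = τ̂ⱼ if
  α(θⱼ) ≥ 0.5, else τ̂ⱼ⁽ᴿ⁾ — with expert overrides;
- an **extended Greenwood formula**: each imputation is spread as fractional
  deaths Qᵢ over the uncensored time points, widening the variance
  s.d.(Ŝ(t)) = Ŝ(t)·[Σ h̄ᵢ/((1−h̄ᵢ)R̄ᵢ) + (((R̄ᵢ−1)/R̄ᵢ)Qᵢ − Qᵢ⁽²⁾)/((1−h̄ᵢ)²R̄ᵢ²)]^½
  and the log-scale confidence intervals built from it;
- a **Monte-Carlo study** measuring the bias of CoDMI against the two naive
  estimators (count COVID deaths as deaths, or as censorings) on
  bootstrap-generated scenarios with a self-consistent ground truth.

The estimators follow scikit-learn conventions (`fit`, `transform`,
`get_params`, fitted attributes with trailing underscores) and compose with
sklearn tooling; thin module-level functions mirror them.

## Worked example

The package embeds the two arms of the NCOG head/neck cancer study
(survival in days; Arm A: 51 records, 42 deaths; Arm B: 45 records, 14
censorings) together with five artificial COVID-death times per arm.

```python
import numpy as np
from codmi import CoDMIImputer, CensoringAdjuster, load_fixture, reverse_km_lifetimes

arm_a = load_fixture("arm_a")                       # theta = 250, 500, ..., 1250
imp = CoDMIImputer(tolerance=0.1, init="at_theta").fit(arm_a.standard, arm_a.covid_times)
print(imp.status_, imp.n_iter_)
print(np.round(imp.tau_hat_, 2))

tau_r = reverse_km_lifetimes(imp.result_.imputed_sample, arm_a.covid_times)
print(np.round(tau_r, 2))

adj = CensoringAdjuster().fit(arm_a.standard)
print(np.round(adj.alpha(np.array(arm_a.covid_times)), 3))
```

prints

```
converged 10
[ 894.32 1118.85 1253.58 1286.24 1354.  ]
[1207.49 1296.23 1347.78 1347.78 1398.12]
[0.847 0.657 0.584 0.47  0.425]
```

The EM iteration converges in 10 sweeps at ε = 0.1 days: the patient who
died of COVID-19 at day 250 is imputed the virtual disease-death time
894.32, and so on. The reverse-KM alternatives (line 3) are the estimates
to use if an imputation is judged to be a censoring rather than a death;
the α curve classifies the last two COVID times (θ = 1000 and 1250, where
α < 0.5) as censoring-like, so the adjusted data set keeps 894.32, 1118.85
and 1253.58 as deaths and takes 1347.78 and 1398.12 as censored records (the last value is
exactly 1398.125, on the rounding boundary).

The same workflow is available from the shell:

```sh
codmi impute --data arm_a --covid-times 250,500,750,1000,1250 \
             --tolerance 0.1 --init at_theta --out w.csv --diagnostics diag.json
codmi pipeline --data arm_a --covid-times 250,500,750,1000,1250 \
               --init at_theta --out-prefix run     # impute -> adjust -> ci
codmi simulate --seed-data arm_a --n-scenarios 2000 --rng-seed 42 --out-prefix sim
```

## Layout

| module | contents |
|---|---|
| `codmi.sample` | validated (time, status) containers, ordering and status reversal |
| `codmi.km` | `KaplanMeierEstimator`: product-limit fit, completion, life expectancy, Greenwood |
| `codmi.imputation` | `CoDMIImputer` / `run_codmi`: the EM iteration with cycle detection |
| `codmi.adjustment` | reverse-KM lifetimes, hazard grid, α curve, `CensoringAdjuster` |
| `codmi.variance` | merged samples, fractional deaths, extended Greenwood, CIs |
| `codmi.simulation` | scenario generation, truth construction, error summaries |
| `codmi.datasets` | NCOG fixtures and CSV I/O |
| `codmi.cli` | `codmi fit / impute / adjust / ci / simulate / pipeline` |

See `docs/methods.md` for the statistical details and design choices.
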