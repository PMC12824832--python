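# mjm — multilevel joint models for cluster randomized trials

`mjm` fits Bayesian **multilevel joint models (MJM)** of longitudinal and
time-to-event outcomes for **cluster randomized trials**: subjects are
nested in groups (classrooms, clinics), the intervention is assigned at
the group level, and two linked outcomes are observed per subject — a
repeatedly measured continuous marker and a possibly censored event time.
It is written for biostatisticians evaluating group-based interventions
who need both outcomes analyzed jointly *and* the clustering respected in
both submodels.

## The model

Longitudinal submodel (three-level linear mixed model), for subject *j*
in group *l*:

```
y_jl(t) = m_jl(t) + ε,                     ε  ~ N(0, σ_ε²)
m_jl(t) = x(t)'β + z(t)'u_jl + v_l,        u_jl ~ N(0, Σ_u),  v_l ~ N(0, σ_v²)
```

Survival submodel (piecewise-constant proportional hazards with a group
frailty, linked by the **current value** of the trajectory):

```
λ_jl(t) = λ_q · exp( ω'γ + α·m_jl(t) + g_l ),   t ∈ [τ_{q-1}, τ_q),
g_l ~ N(0, σ_g²)
```

The survival likelihood is carried by an **auxiliary mixed-effect Poisson
model** on interval-level pseudo-observations δ_jlq with exposure offset
log t_jlq ("Poisson trick"): the two likelihoods are proportional, so
posteriors over shared parameters coincide — an identity the test suite
asserts exactly.  α is the association between the marker level and the
log-hazard; setting `multilevel=False` drops v and g, giving the standard
two-level joint model (JM) used to quantify the cost of ignoring the
group level.  Estimation is MCMC (blocked Gibbs/Metropolis; see
`docs/methods.md`), with split-chain R-hat < 1.1 as the convergence gate
and conditional-deviance DIC for comparing trajectory specifications.

The package also contains the full simulation framework: a generator that
draws nested trial data from this model (Weibull baseline hazard, event
times by inverting the cumulative hazard under the time-varying
trajectory, administrative censoring at 9 years, measurements every 6
months for 5 years), censoring-rate calibration, the 72-cell scenario
grid, and a replicate runner reporting bias, relative bias, MESE and ESE.

## Worked example

```python
from mjm import (McmcConfig, ModelSpec, MultilevelJointModel,
                 ScenarioConfig, generate_dataset, equal_length_grid)

# one synthetic trial: 30 classrooms of 15 children, 20% censoring
scenario = ScenarioConfig(censoring_target=0.2, L=30, group_size=15,
                          var_v=5.0, var_g=0.4, Q=3, seed=11)
data, truth = generate_dataset(scenario)

model = MultilevelJointModel(data, ModelSpec.simulation_mjm(Q=3),
                             grid=equal_length_grid(9.0, 3))
result = model.fit(McmcConfig(chains=3, adapt=100, burn_in=800, thin=8,
                              draws_per_chain=250, seed=5))
print(result.summary().table.loc[
    ["beta:treatment:time", "alpha", "var_v", "var_g"],
    ["mean", "sd", "q2.5", "q97.5", "rhat"]].round(3))
print("converged:", result.converged, " DIC: %.1f" % result.dic()["dic"])
```

Output:

```
                      mean     sd   q2.5  q97.5   rhat
beta:treatment:time -2.326  0.369 -3.052 -1.596  1.006
alpha               -0.194  0.015 -0.226 -0.167  1.003
var_v                3.805  1.375  1.835  6.868  1.030
var_g                0.214  0.081  0.102  0.412  1.001
converged: True  DIC: 20440.1
```

The generating values were β₁₀₁ = −2 (the treatment-by-time effect: the
intervention lowers the marker by 2 units/year) and α = −0.2 (each unit
of the marker multiplies the hazard by e^−0.2 ≈ 0.82); both posterior
means sit well within one posterior SD of the truth.  The group-level
variance components (truths 5 and 0.4) show the shrinkage typical of
Bayesian multilevel fits with 30 groups.

A CLI mirrors the library: `mjm generate`, `mjm fit`, `mjm study`,
`mjm compare`, `mjm report` (all take `--seed`; see `mjm --help`).

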