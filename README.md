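# adaptivecrm

Consumer-resource models of competitive microbial communities with **dynamic
metabolic adaptation**: simulation of coexistence experiments, simplex/convex-hull
analysis, and MCMC fitting of a diauxic-growth variant to density curves.

## The model

In MacArthur's consumer-resource framework, *m* species compete for *p*
substitutable resources:

    dn_σ/dt = n_σ ( Σ_i v_i α_σi r_i(c_i) − δ_σ )
    dc_i/dt = s_i − Σ_σ n_σ α_σi r_i(c_i) − μ_i c_i

with Monod responses r_i(c) = c/(K_i + c), resource values v_i (cell/g), death
rates δ_σ (1/h), supply rates s_i (g/(mL·h)) and degradation rates μ_i (1/h).
Classically the metabolic strategies α_σi — the maximum uptake rates of each
resource — are fixed parameters, and at most *p* species can stably coexist
(the Competitive Exclusion Principle, CEP).

Here the strategies are dynamical variables: each species performs gradient
ascent of its own growth rate g_σ = Σ_i v_i α_σi r_i − δ_σ under a total
uptake budget Σ_i α_σi ≤ E*_σ,

    dα_σi/dt = α_σi λ_σ [ v_i r_i − Θ(φ_σ) (Σ_j v_j r_j α_σj) / (Σ_k α_σk) ],

where φ_σ = Σ_i α_σi/E*_σ − 1 ≤ 0 is the budget constraint, Θ the Heaviside
step (Θ(0) = 1) and λ_σ the learning rate. Writing E*_σ = Q_σ δ_σ defines the
characteristic timescale ratio (CTR) Q_σ; with a common CTR the community
**self-organizes** — the value-weighted, sum-normalized strategies pull the
rescaled supply vector inside their convex hull on the (p−1)-simplex — and an
arbitrary number of species coexists on few resources. With species-specific
CTRs (Q_σ ~ Normal(⟨Q⟩, Σ)), coexistence is transient, and the time to the
first extinctions grows as (Σ/⟨Q⟩)⁻¹.

A single-species, two-resource batch variant describes diauxic growth on
galactose: ethanol is excreted in proportion Y to galactose consumption and
respired after a lag, producing the familiar biphasic density curve. This
variant (10 parameters) is fitted to growth curves with an ensemble MCMC
sampler and compared against the frozen-strategy null model by AIC
(relative likelihood exp(Δ_AIC/2)).

## Worked example

```python
import numpy as np
from adaptivecrm import (EnsembleConfig, run_self_organization,
                         run_extinction_scaling, fit_power_law)

# Fig-style hull capture: common CTR, supply initially outside the hull
rep = run_self_organization(m=10, p=3, seed=1, hull_placement="outside")
print(rep.initially_inside, rep.finally_inside, rep.n_survivors)

# extinction-time scaling with the CTR coefficient of variation
config = EnsembleConfig(m=10, p=3, replicates=10, seed=42, t_max=1e5)
table = run_extinction_scaling(config, [0.04, 0.07, 0.125, 0.22, 0.4])
fit = fit_power_law(table["cv"], table["mean_time"])
print(f"{fit.exponent:.2f} +/- {fit.exponent_stderr:.2f}")
```

prints

```
False True 10
-0.87 +/- 0.12
```

i.e. the rescaled supply started **outside** the strategies' convex hull, the
strategies adapted until it was **inside**, and all 10 species coexist on 3
resources (stationary densities 1.5·10³–6.3·10³ cell/mL, all far above the
1 cell/mL extinction threshold); and the mean time to first extinction falls
from ≈415 h at Σ/⟨Q⟩ = 0.04 to ≈54 h at 0.4, a log–log slope of −0.87 ± 0.12,
consistent with the (Σ/⟨Q⟩)⁻¹ law.

Fitting a growth curve:

```python
from adaptivecrm import DiauxicCurveModel, GrowthCurve, ChainConfig

model = DiauxicCurveModel(GrowthCurve.from_csv("curve.csv"), variant="adaptive")
result = model.fit(ChainConfig(seed=0, nwalkers=32, nsteps=1000))
print(result.summary())         # posterior medians, 90% CIs, AIC, diagnostics
```

## Command line

Every experiment is a subcommand writing CSV tables plus a JSON manifest that
fully reproduces the run (resolved config + seed + versions):

```bash
adaptivecrm exp-self-organization --seed 1 --out runs/selforg
adaptivecrm exp-extinction-scaling --config my.yaml --out runs/scaling
adaptivecrm synth-curve --seed 2 --out runs/curve
adaptivecrm diauxic-fit --data runs/curve/growth_curve.csv --out runs/fit
```

Configs are plain YAML; unknown keys are rejected, and every value not given
falls back to a declared default (`adaptivecrm simulate --help` lists the
subcommands; see `src/adaptivecrm/config.py` for the schema).

`diauxic-fit` expects a CSV with columns `time_h,density_cell_per_ml`.
Plate-reader exports in spreadsheet form convert in one line:
`pandas.read_excel("curves.xls").rename(columns=...).to_csv("curve.csv", index=False)`
(openpyxl/xlrd handle the spreadsheet formats).

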