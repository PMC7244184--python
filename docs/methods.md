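# Methods

## Model

The community state is (n, c, A): densities n_σ (cell/mL), concentrations
c_i (g/mL) and the m×p strategy matrix A with entries α_σi (g/(cell·h)).
Densities grow from Monod-saturated uptake weighted by resource values and
decline at per-capita death rates; concentrations follow supply minus
consumption minus first-order degradation. When adaptation is enabled each
strategy row performs multiplicative gradient ascent of its species' growth
rate; once the row sum reaches the budget E*_σ = Q_σ δ_σ, the component of
the gradient along the constraint normal is projected out (the Θ term), so
on the budget surface the row sum is conserved exactly and the dynamics
redistributes uptake capacity between resources. Strategies are
non-negative by construction (every derivative carries its own α as a
prefactor), and zero rows are absorbing: the projection's weighted average
is defined as 0 when a row vanishes.

All quantities live in one fixed unit system — hours, mL, grams of
resource, cells. The fixed-strategy (classical MacArthur) model is the same
code path with the strategy derivatives zeroed (`adaptive=False`), which is
also the λ → 0 limit.

The batch diauxic variant is the m=1, p=2 model without supply or dilution;
ethanol is produced at Y (g/g) times the galactose consumption rate and
consumed through its own Monod term, with the strategy pair adapting under
the budget (α_gal + α_eth)/(Qδ) ≤ 1 and learning rate λ = dδ.

## Numerical integration

`scipy.integrate.solve_ivp` with LSODA, relative tolerance 1e−8 and
per-block absolute tolerances (1e−6 cell/mL for densities, 1e−12 g/mL for
concentrations, 1e−12 for strategies): densities and concentrations differ
by many orders of magnitude, and the consumption terms make the system
stiff whenever n·α/K is large.

Two regularizations keep the constraint surface numerically benign:

* **Θ ramp.** The exact Heaviside factor turns the budget surface into a
  sliding mode — adapting rows are pushed onto it from below and the
  discontinuous right-hand side then makes any step-size controller
  chatter (we observed step sizes collapsing to ~1e−5 h). Θ is therefore
  ramped from 0 to 1 by a C¹ smoothstep over the thin layer
  −1e−6 ≤ φ < 0. Θ(0) = 1 and the φ ≤ −1e−6 branch are exact, so the
  on-surface conservation identity and the pure-gradient branch are
  unaffected; adapting rows simply come to rest at the top of the layer.
* **Row projection.** Numerical integration can overshoot the budget by
  O(rtol); after each integration segment (and in all stored states), rows
  whose sum exceeds E*(1 + 1e−9) are rescaled back onto the surface. The
  exact flow preserves the surface, so this correction stays at rounding
  level.

Piecewise-constant (periodic) supply protocols are integrated segment by
segment, restarting the solver at every switching instant so no step
crosses a discontinuity; the protocol starts in its "in" phase at t = 0
(configurable — the phase convention is a declared choice).

Extinction events are located by the solver's root-finding on
n_σ − threshold with downward direction only; the threshold defaults to
1 cell/mL. A species is recorded at most once (first crossing) and is never
removed from the ODE system, so populations can recover under variable
supply. When an experiment only needs the k-th extinction time, integration
stops at the k-th distinct crossing.

Stationarity is declared when max_i |f_i| / (|y_i| + floor_i) < tol (units
1/h), with floors equal to the per-block absolute tolerances; the search
integrates in doubling chunks up to t_max. Residuals of dying species fall
below any tolerance once their densities underflow the floor. With an
abandoned, non-degrading resource the concentration grows linearly forever
(residual ~ 1/t), so the decoupling experiment judges stationarity on the
biotic block (densities and strategies) only. Default tol is 1e−9; the
ensemble experiments use 1e−7, which changes survivor counts by nothing
(densities are separated from the threshold by ~3 decades) while keeping
runs fast.

Hull membership on the simplex is decided by a small linear program
(minimize the L1 residual of expressing the point as a convex combination;
member iff residual ≤ 1e−9), which is robust for collinear or duplicated
vertex sets where facet enumeration fails. The rescaling onto the simplex is
value-weighted sum-normalization, α̂_σi = v_i α_σi / Σ_j v_j α_σj (same for
supply); with degradation the effective supply point uses the net supply
s_i − μ_i c_i* at stationarity. Any per-species constant (e.g. an E*
normalization) cancels in the sum-normalization, so this representation is
insensitive to that choice.

## Ensemble experiment conditions

The ensemble generator draws communities at these defaults (chosen once;
magnitudes are a scaled unit system, since no canonical parameter set for
the community experiments is published):

| quantity | default | note |
|---|---|---|
| m, p | 10 (20 for the periodic-supply run), 3 | experiment-specific |
| δ_σ | log-uniform 0.05–0.5 /h | spans an order of magnitude |
| ⟨Q⟩ | 2 g/cell | common CTR in coexistence runs |
| Q_σ | Normal(⟨Q⟩, Σ), redrawn if ≤ 0 | scaling experiment |
| λ_σ | d·δ_σ, d = 2 g/cell | adaptation ~10× slower than growth |
| v_i | uniform 1–2 cell/g | all favorable: 1/v_i < ⟨Q⟩ |
| K_i | uniform 0.5–1.5 g/mL | concentrations of order K |
| Σ_i s_i | 6000 g/(mL·h) | sets stationary densities ~10³–10⁴ cell/mL |
| n_σ(0) | 10⁴ cell/mL | ~3 decades above the 1 cell/mL threshold |
| c_i(0) | K_i | Monod responses start at 1/2 |
| A(0) | Dirichlet(1,…,1) direction × u·E*, u ~ U(0.5, 1) | budget starts inactive |

The unfavorable-resource regimes set v_j = 0.3 cell/g (so 1/v_j = 3.3 > Q)
or μ_j = 1e5 /h; the degradation rate must exceed s_j/K_j (~2e3 /h here) for
the degraded resource to pool far below its half-saturation and become
unprofitable. A strategy column counts as abandoned when every species
allocates < 1e−6 of its budget to it.

Hull placement is achieved by sampling rescaled strategy directions from
Dirichlet(3,3,3) (mildly concentrated, so hulls do not fill the simplex) and
placing the supply point at the hull centroid ("inside") or 85% of the way
toward a simplex vertex, with rejection until the requested placement holds
("outside"). The periodic protocol alternates the inside-hull supply for
12 h with the outside-hull supply for 48 h.

Every experiment derives all its randomness from one master seed through
`numpy.random.default_rng` child seeds, so summary tables are bit-identical
across runs. Replicate counts default to 10 (the figure-scale ensembles use
more; the scaling behavior is already clear at 10 with the quoted standard
errors). Replicates in the scaling experiment that never reach the k-th
extinction within t_max are reported as censored and excluded from the mean
(the scaling claim concerns realized extinction times).

## Growth-curve fitting

The observable is log10 density; the likelihood is i.i.d. Gaussian on log10
residuals with a fitted scale σ (OD-derived densities span decades and
their errors are multiplicative). Priors are log-uniform boxes, by default
±3 decades around user-supplied centers — the intended centers are
literature or pilot estimates, mirrored by the synthetic exemplar's values.
Sampling uses emcee's affine-invariant ensemble in log10 parameter space
(walkers initialized in a small ball around the box center); the adaptive
variant has 10 model parameters + σ, the frozen-strategy variant 8 + σ
(the budget parameters Q and d are inert when strategies cannot move).
AIC = 2k − 2 log L_max with k counting all sampled parameters including σ;
Δ_AIC = AIC_adaptive − AIC_fixed and exp(Δ_AIC/2) is the relative
likelihood of the fixed-strategy model. Convergence is reported via a
split-chain Gelman–Rubin statistic per parameter plus a boundary diagnostic
(posterior tail quantiles within 2% of a prior bound); short chains are
flagged as unconverged rather than hidden.

Local identifiability is computed, not assumed: the Jacobian of the log10
model curve with respect to log10 parameters (central differences, 0.01
decades) gives the Fisher information at a parameter point; a parameter is
identifiable when its marginal standard error is below 0.25 decades and it
has negligible weight in the numerically null sensitivity subspace. From
the full 70 h / 421-point curve, 8 of the 10 diauxic parameters are locally
identifiable (K_eth and α_eth0 are not — the ethanol phase constrains
mostly their combinations).

### The synthetic growth-curve generator

`synthesize_growth_curve` simulates the diauxic model and applies
multiplicative lognormal noise (Gaussian on log10 with scale σ; σ =
log10(1.05) ≈ 0.021 corresponds to 5% noise). The default schedule is one
sample every 10 minutes for 70 h (421 points) and the default generating
parameters describe a yeast-like batch culture seeded at 1.6·10⁵ cell/mL in
0.5% w/v galactose: a fast galactose phase (≈0.3 /h) ending near 9 h, an
adaptation lag of ≈10 h during which density is nearly flat, and an
ethanol-fueled second phase rising above the first plateau, with yields
v_gal = 2·10¹⁰ cell/g, v_eth = 1.7·10¹⁰ cell/g and Y = 0.5 g/g. What the
generator does **not** emulate: replicate-to-replicate biological
variability, autocorrelated instrument drift, OD saturation/calibration
error, and the near-constant plateau of real stationary-phase OD (the model
has an explicit death term, so synthetic densities decline slowly after the
resources are spent). Passing recovery tests therefore demonstrates that
the inference machinery is calibrated for curves the model can represent,
not that real data satisfy the model's noise assumptions.

## Design choices where the design was open

* Θ(0) = 1 (surface included in the projected regime) makes the budget
  surface invariant; the alternative convention would make it repelling
  from above only and non-conserving at φ = 0.
* Extinct species stay in the system: only first crossing times are
  recorded, which preserves re-invasion dynamics under switching supply.
* The fixed-strategy null model is the adaptive code path with zeroed
  strategy derivatives, so model comparisons never mix integrators.
* The gradient form of the strategy dynamics is implemented exactly as the
  closed-form projected equation; no re-derivation through an explicit
  metric is attempted.
* Experiment scales (replicates 10, cv grid of 5 points over one decade,
  6 supply cycles, short MCMC chains) are declared problem sizes chosen so
  the claimed signatures are measured with quoted uncertainty.

## Known limitations

* Substitutable resources only; no cross-feeding, no resource classes with
  interactive (e.g. essential) co-limitation.
* Adaptation is phenomenological gradient ascent; there is no mechanistic
  gene-regulation model of catabolite repression, so lag durations are
  controlled by (d, E*, v, K) rather than regulatory kinetics.
* Deterministic ODEs throughout: extinction is a threshold crossing, not a
  demographic-stochastic absorption.
* The extinction-time power law is measured over one decade of Σ/⟨Q⟩ at
  10 replicates; the exponent carries a standard error of ≈0.1 and drifts
  toward flatter slopes at large cv, where the normal CTR draw is
  truncated at 0.
* MCMC chains sized for minutes of runtime are honest about it: the split
  R̂ diagnostic typically flags them as unconverged even when posterior
  intervals are already stable enough for coverage checks; production fits
  should run an order of magnitude more steps.
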