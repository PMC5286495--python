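# algalipid

Kinetic modelling of nitrogen-limited microalgal batch growth and neutral
lipid accumulation.

Microalgae accumulate neutral lipids (TAGs) when nitrogen runs out: protein
synthesis stalls, while carbon fixation keeps going and is redirected into
storage lipid. `algalipid` implements a deliberately simple batch-culture
model of this trade-off, aimed at strain screening and cultivation planning
(how much NaNO₃ to charge a batch with to trade biomass against final lipid
fraction), together with the estimation, correlation and sensitivity tooling
needed to calibrate it to time-course data.

## The model

For a closed batch with biomass `X(t)` (g dw L⁻¹), external nitrogen `N(t)`
(g L⁻¹, as NaNO₃) and lipid mass fraction `L(t)`:

```text
dX/dt = μmax · α(t) · (1 − X/Xmax) · X          adjusted logistic growth
α(t)  = 1 / (1 + (e^{h0} − 1) e^{−μmax t})      Baranyi–Roberts adjustment
dN/dt = −vm · N/(N + K_N) · X                   Michaelis–Menten uptake
Q(t)  = (N0 − N(t) + Φ) / X(t)                  quota by mass balance, Φ = X0·Q0
L(t)  = 1 − k·Q(t) − c                          lipid fraction, linear in quota
```

Eight parameters: `μmax, h0, vm, K_N, Xmax` (growth/uptake) and `k, c, Φ`
(composition). Two empirical correlations link the initial nitrogen charge
`N0` to outcomes across conditions: a quadratic `Xmax(N0)` and a linear
`h0(N0)`, from which the final lipid fraction at full depletion follows in
closed form as `Lf = (1 − c) − k(N0 + Φ)/Xmax(N0)`.

Estimation is staged, as the model was originally calibrated: bounded
multistart least squares fits the five growth/uptake parameters to the X and
N series (residuals scaled by each series' spread), then the three
composition parameters are fit to the lipid series with the stage-1
trajectory held fixed. A one-at-a-time ±20% perturbation analysis scores
each parameter's leverage on `L(t)` with a t-ratio, separating parameters
that must be measured carefully from those that can be transferred loosely
between strains.

## Worked example

Generate a synthetic triplicate batch experiment at 0.6 g L⁻¹ NaNO₃ (the
generator emulates the 24-day, 13-sample design the model was built on,
with 5 % multiplicative measurement noise), fit it, and rank parameter
sensitivity:

```python
from algalipid import BatchLipidModel, FitConfig, datasets

obs = datasets.generate(datasets.ha1_design(seed=1))
one = obs[obs.condition == "HA1_N0_0.6"].drop(columns="condition")
res = BatchLipidModel(one, FitConfig(seed=1)).fit()
print(res.summary())
```

```text
Batch lipid-accumulation kinetics: staged least squares
========================================================
parameter     estimate  unit
--------------------------------------------------------
mu_max          0.3006  1/day
h0              -1.338  dimensionless
vm              0.4921  g N/(g dw day)
KN              0.4329  g/L
Xmax             5.843  g dw/L
k                2.096  g protein/g N
c               0.4235  g carb/g dw
phi             0.0506  g N/L
--------------------------------------------------------
R^2: L(t) 0.7341  N(t) 0.9976  X(t) 0.9922
initial condition: X0 = 0.2872 g dw/L, N0 = 0.6312 g/L
objective 0.1953; converged: True; 228 model evaluations
```

The generating values were `μmax = 0.300`, `Xmax = 5.946`, `k = 2.122`,
`c = 0.440`, `Φ = 0.049`: growth and composition parameters come back
within a few percent from one noisy experiment. (The lower `L(t)` R²
reflects lipid readings censored at the assay floor, which the fit treats
as left-censored rather than chasing; see `docs/methods.md`.) Sensitivity
off the same results object:

```python
report = res.sensitivity()         # ±20%, 24-day horizon, daily grid
print(res.rank_sensitivity()[:2])  # ['c', 'k']
```

The carbohydrate offset `c` is degenerate (it shifts `L(t)` uniformly, so
it is detected with certainty — an effectively infinite t-ratio) and the
nitrogen-to-protein factor `k` is the strongest dynamical driver.

The same machinery is scriptable from the shell:

```bash
algalipid simulate --fixture HA1:0.9 --out traj.csv
algalipid --seed 1 synth --out obs.csv
algalipid --seed 1 fit --input obs.csv --out fit.json
algalipid sensitivity --fixture Csoro:100 --out sens.json --csv sens.csv
```

## Bundled parameter sets

`algalipid.datasets.fixture` ships the per-condition mean parameter sets
for *Coelastrum* sp. HA-1 (five NaNO₃ levels, 0.075–0.9 g L⁻¹) and
*Chlorella sorokiniana* (three light intensities at 1 g L⁻¹ NaNO₃, with
`vm`, `K_N` transferred from HA-1 at 0.9 g L⁻¹). These drive the synthetic
generator, the example workflows and the reproduction tests.

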