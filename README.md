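# atnfit

Calibrating bioenergetic food-web models to biomass time series.

`atnfit` is for ecologists who want to align an allometric trophic
network (ATN) model — a system of ODEs in which producers grow
logistically, consumers feed through saturating functional responses,
and a detrital loop recycles egestion and exudation — with annual
biomass records from a real ecosystem, treating the rate parameters as
unknowns of an inverse problem rather than fixing them from allometry.
The package grew out of modelling a shallow eutrophic lake food web
(one phytoplankton pool, zooplankton, benthos, ten fish guilds and
detritus), but every piece is generic over the web structure.

## The model in brief

Biomasses `B_i(t)` (tonnes/km², annual steps) follow

- producer: `dB/dt = r B (1 - B/K)(1 - s) - grazing`
- consumer: `dB/dt = -u_m B + u_a B Σ_j e_ij J_ij F_ij - predation - catch`
- detritus: `dB/dt = Σ (1-e) · intake + exudation - detritivory`

with the interference-free functional response
`F_ij = (B_j/B0_ij)^(1+q) / (1 + Σ_k (B_k/B0_ik)^(1+q))`.

Stochasticity enters either as **environmental noise** (independent
Wiener processes driving each node's SDE, absolute or relative scale,
Gaussian or lognormal one-step transition densities via
Euler–Maruyama) or as **observation noise** (deterministic dynamics
observed with Gaussian error). The likelihood always conditions on
recorded biomasses. Calibration maximizes the (optionally penalized)
likelihood with CMA-ES in softplus-transformed space, with allometric
lower bounds `a W^(-1/4)` on fish metabolic rates holding by
construction. Models are compared by AIC, Bray–Curtis dissimilarity
between predictions and data, counts of non-positive predicted
medians, and 90% central-probability-interval coverage.

See `docs/methods.md` for the full model description, conventions and
design decisions.

## Worked example

Generate a 4-node synthetic web (producer, grazer, predator,
detritus) with known truth, then recover the parameters at the
desk-scale optimizer budget:

```python
import numpy as np
from atnfit import (four_node_scenario, generate_dataset,
                    FitConfig, LossSpec, NoiseSpec, fit)

sc = four_node_scenario(seed=0)          # 50 years, absolute normal env. noise
data, truth = generate_dataset(sc)
cfg = FitConfig(offspring=20, max_iterations=200, restarts=10, seed=1,
                estimate_q=False, fixed_q=0.0)
res = fit(data, sc.web, NoiseSpec("environmental", "normal", "absolute", np.ones(4)),
          cfg, LossSpec(penalty="soft"), um_lower=sc.true_params.um_lower)
print("sigma true", truth["sigma"], "-> est", np.round(res.sigma, 3))
print("J     true", truth["params"].J, "-> est", np.round(res.params.J, 3))
print("loglik", round(res.loglik, 2), " AIC", round(res.aic, 1))
```

prints (about a minute on one core):

```
sigma true [0.3  0.15 0.08 0.25] -> est [0.274 0.124 0.082 0.263]
J     true [2.       0.886146 0.6     ] -> est [3.084 0.765 0.864]
loglik 75.67  AIC -123.3
```

Every noise scale is recovered within 30% and every maximum ingestion
rate within a factor of 2 — the accuracy one can expect from 50 annual
records; the log-likelihood at the optimum slightly exceeds the value
at the truth (75.7 vs 72.4), the usual mild overfit of maximum
likelihood.

The same workflow from the shell:

```sh
atnfit generate --scenario four-node --seed 3 --out data/
atnfit fit --data data/biomass.csv --web data/web.yaml \
           --layer env --family normal --scaling absolute \
           --q 0.0 --penalty soft --budget desk --seed 1 --out fit.json
atnfit evaluate --data data/biomass.csv --web data/web.yaml \
                --result fit.json --out report.json
```

## The analysis, end to end

The `analysis/` scripts run the full study-shaped pipeline on the
15-node, 72-link lake web (outputs under `results/`):

1. `01_generate_data.py` — synthetic 18-year dataset with the study's
   missingness pattern (268 observed cells, 6 interpolated for
   detritus, two zero records replaced by 1e-8, catches for five fish
   guilds);
2. `02_fit_models.py` — penalized ML calibration (174 free parameters,
   functional-response exponents fixed at 0.3) under absolute and
   relative normal environmental noise;
3. `03_evaluate_fits.py` — AIC, Bray–Curtis, CPI coverage per model;
4. `04_compare_models.py` — the cross-model comparison table.

At the reduced demonstration budget the absolute-noise model fits the
synthetic series well (BC ≈ 0.14, coverage ≈ 93%, one non-positive
predicted median) while the relative-noise model fails catastrophically
(AIC larger by ~7·10⁸) — the same qualitative ranking the full-scale
study reports.

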