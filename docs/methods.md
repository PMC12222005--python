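# Methods

## The model

`atnfit` implements a bioenergetic (allometric trophic network, ATN)
model for the annual biomass dynamics of a lake food web with a
detrital loop. The state is a vector of biomasses `B_i(t)` (tonnes per
km², one pool per guild plus one detritus pool); time runs in years.

**Producer** (one combined phytoplankton guild in the default web):

    dB_i/dt = r_i B_i G_i (1 - s_i)  -  Σ_j B_j J_ji F_ji

with logistic growth `G_i = 1 - B_i / K` against a system-wide
carrying capacity `K`, exudation fraction `s_i` routed to detritus,
and grazing losses summed over the producer's consumers `j`.

**Consumers**:

    dB_i/dt = -u_m,i B_i + u_a,i B_i Σ_j e_ij J_ij F_ij
              - Σ_j B_j J_ji F_ji - C_i(t)

Maintenance metabolism at rate `u_m,i`; assimilated intake with
assimilation efficiency `e_ij` and activity-respiration coefficient
`u_a,i` (`u_a = 1` disables activity respiration — the default, which
matches the better-performing variant); predation losses; and annual
catch rates `C_i(t)` for exploited fish guilds, applied as constant
rates over each unit step.

**Detritus** collects the unassimilated share `(1 - e_ij)` of all
non-detrital intake and producer exudation `r B G s`, and is depleted
only by detritivory. No burial or export term is included.

**Functional response** (no predator interference):

    F_ij = (B_j / B0_ij)^(1+q_ij) / (1 + Σ_k (B_k / B0_ik)^(1+q_ik))

`B0_ij` is the half-saturation biomass, and the exponent `q`
interpolates between Holling type II (`q = 0`) and type III (`q = 1`).
Each `F_ij` lies in [0, 1) and a consumer's fractions sum to < 1.
Negative biomasses (possible transiently during inference) are treated
as 0 inside the ratios, because fractional powers of negative bases are
undefined.

The continuous dynamics are advanced with the explicit Euler method at
`Δt = 1` year, matching the annual resolution of the data. During a
deterministic simulation, a pool whose Euler update falls to ≤ 0 is
*removed*: its biomass is held at exactly 0 from that year on and it is
fully decoupled (no feeding in either direction, no maintenance, no
catch). Full decoupling is the minimal self-consistent reading of
"removing" a guild; the removal record (node, first year) is part of
the simulation output.

## Noise models and likelihoods

Two opposite noise assumptions bracket reality:

**Environmental (process) noise.** Each node's SDE is driven by an
independent Wiener process, either with *absolute* scale
(`dB_i = f_i dt + σ_i dW_i`) or *relative* scale
(`dB_i = f_i dt + σ_i B_i dW_i`). The Euler–Maruyama discretization
gives a Gaussian one-year transition density per node: mean
`B_i + f_i(B̄) Δt`, standard deviation `σ_i √Δt` (absolute) or
`σ_i B_i √Δt` (relative). The likelihood is the product of these
factors over consecutive observed years, always conditioning on
*recorded* biomasses — predictive mass below zero therefore never
propagates into the simulation and is deliberately not clipped.
Lognormal variants replace each Gaussian factor by a lognormal
density. The parameterization is moment matching by default (lognormal
mean = Euler location, lognormal SD = the Gaussian scale); when the
Euler location is ≤ 0 the moment match is undefined and the factor
contributes a large negative constant (−10⁶) instead of raising, so
optimization can continue. An alternative parameterization that
reuses the Gaussian location/scale directly as log-space parameters is
available behind `lognormal_param="logspace"` but is not the default.

A likelihood factor for node `i` at step `t → t+1` is included only
when the node is observed at both endpoints and the step is exactly
one year; longer gaps contribute nothing (chaining the one-step
density across a gap would need an approximation the model does not
define). When the drift must be evaluated at a year where some *other*
node's record is absent, that entry of the conditioning state is
filled by the node's most recent recorded value (carry-forward,
backward fill at a leading gap). A cell that is masked out of the
likelihood but whose value is present still conditions the drift, so
masking removes exactly its own two factors.

**Observation noise.** The dynamics are deterministic from estimated
initial biomasses; each observed cell carries independent Gaussian
error around the simulated trajectory, with absolute (`σ_i`) or
relative (`σ_i B_i(t)`) scale. Cells of removed node-years contribute
no factor; their count feeds the non-positivity penalty. With fixed
absolute σ this likelihood is an affine function of the ordinary
least-squares objective, which the tests exploit as an independent
cross-check.

σ is indexed over all nodes *including detritus* — that convention is
what makes the free-parameter counts come out at 246/174
(environmental, with/without estimated functional-response exponents)
and 261/189 (observation) for the 72-link base web. Note a structural
caveat: the counts grow by 3 per extra link when exponents are
estimated and by 2 otherwise, so only the 72-link variant reproduces
all four published totals simultaneously; the published totals for the
73–75-link variants increase by 1 per link, which the per-link
counting convention used here cannot produce.

## Data preparation

Input is a wide CSV (rows = years, columns = nodes, blank = missing).
The preparation rules, applied by the synthetic generator's `degrade`
stage and expected of any real dataset before fitting:

- zero biomass records are read as recorded (the reader never edits
  data) and replaced by 1e-8 during preparation — a zero is taken to
  mean "very low", and strictly positive values keep relative noise
  and lognormal factors defined;
- interior gaps of nodes flagged for interpolation (detritus, whose
  pool varies slowly) are filled with the mean of the nearest observed
  years before and after, and flagged; interpolated cells count as
  data in likelihood, dissimilarity and coverage (switchable);
- a gap at a series end has no neighbor on one side and stays missing
  (its likelihood factors are simply dropped).

## Calibration

All free parameters are estimated jointly in unconstrained space. Each
positive parameter is mapped through the softplus `log(1 + exp(x))`
(computed as `logaddexp(0, x)`; the inverse uses `y + log(-expm1(-y))`
to avoid cancellation, giving round trips accurate to ~1e-7 over the
range met in practice). Consumer metabolic rates use
`u_m = u_m^L + softplus(x)`, so allometric lower bounds hold by
construction: for fish guilds `u_m^L = a W^(-1/4)` from the maximum
published body mass `W` in grams (quarter-power metabolic scaling; the
prefactor `a = 1` and the exponent are config-exposed placeholders,
since the exact constants behind the published bounds are not
available), and for guilds of uncertain composition (zooplankton,
benthos) the bound is a configured constant, default 1 per year.

Initial values are data-driven: `K` starts at the mean total observed
producer biomass, each `B0_ij` at the mean observed biomass of the
resource, `σ_i` at the sample SD of the node's series (SD of
log-ratios for relative scaling; a configurable fallback covers
series with under two observations), initial biomasses at the first
observed year, `q` at 0.2 (a stability-range value) when estimated,
and every other parameter at 1.

The loss is the negative log-likelihood plus an optional penalty
against biologically absurd fits that predict non-positive biomasses:

- *soft*: +100 per node-year whose predicted **median** biomass is
  ≤ 0 (environmental: median of the one-step predictive over
  likelihood-aligned cells; observation: simulated biomass ≤ 0, i.e.
  a removed node-year, over observed cells). The coefficient 100 puts
  one violation on the scale of the whole log-likelihood. The
  median-only criterion is the default because stricter criteria
  (e.g. any predictive mass below zero) empirically destroy the fit.
  Both the all-node and the detritus-excluded counts are always
  reported; the penalty uses the all-node count by default
  (switchable).
- *hard*: the loss is +∞ as soon as any prediction is non-positive.
  Supported and tested, but with annual Gaussian predictives a
  feasible point is rarely found — the soft penalty is the practical
  default.

Minimization uses CMA-ES — implemented in `atnfit.cmaes` as the
standard (μ/μ_w, λ) strategy with cumulative step-size adaptation and
rank-one/rank-μ covariance updates — because the loss surface is
high-dimensional and multimodal and derivatives are unavailable.
Infinite losses are legal (they rank last in a generation). The fit
runs `restarts` successive CMA-ES runs, each *warm-started at the
incumbent best* parameter vector with a re-initialized covariance and
step size; only the best candidate ever seen is kept, so the best loss
is non-increasing across restarts and the whole search is a pure
function of the seed. Two budget profiles ship with the package:
`desk` (20 offspring × 200 iterations × 10 restarts — laptop-scale,
used throughout the tests) and `paper` (200 × 3000 × 3000 —
cluster-scale); a `smoke` profile (8 × 20 × 2) exists for quick
trials. Other CMA-ES constants follow the standard defaults.

AIC is the standard `2k − 2 loglik` with `k` from the parameter count
above and the *unpenalized* log-likelihood at the optimum; no
small-sample correction is applied.

## Evaluation

- **AIC differences** against a chosen reference model (lower wins).
- **Bray–Curtis dissimilarity** `Σ|pred − obs| / Σ(pred⁺ + obs)` over
  all guilds and years; `similarity = 1 − BC`. Under environmental
  noise "pred" is the median of the one-step-ahead predictive (equal
  to the mean for Gaussian factors); under observation noise it is the
  deterministic trajectory. Negative medians keep their sign in the
  numerator and are clamped to zero in the denominator, so BC can
  honestly exceed 1 for models predicting far below zero; the clamp is
  switchable.
- **90% CPI coverage**: the fraction of cells whose observation falls
  inside the equal-tail central probability interval of the predictive
  distribution; for Gaussian predictives the lower bound may be
  negative. Under a correctly specified model coverage is calibrated
  (the tests verify 0.9 within 3 binomial SE at 500 cells).

## Synthetic data

The generator produces datasets with the *structure* of the study
series while the values follow a known ground truth, so every pipeline
stage can be tested end to end.

The default scenario: 15 nodes (1 producer; protozooplankton,
metazooplankton, benthos; ten fish guilds — ruffe, roach, bleak, white
bream, bream, smelt, perch, eel, pikeperch, pike; detritus), 18 annual
records labelled 1995–2012, eel and detritus missing in the final
year, six interior detritus years filled by two-point interpolation,
two zero records (smelt 2006, eel 1997) replaced by 1e-8 — 268
observed cells of which 6 interpolated — and constant catches for five
fish guilds (bream, perch, eel, pikeperch, pike) at 2% of initial
biomass per year. The 72-link feeding matrix is a documented
reconstruction from trophic roles (plankton → zooplankton →
planktivorous fish → piscivores; benthos → benthivores; detritivory by
zooplankton, benthos and omnivorous cyprinids); the study's own matrix
is not public, so everything that depends on structure uses only the
node/link counts. Three optional links (perch and pike cannibalism,
white bream as an eel resource) extend the matrix to 75 links.
Assimilation efficiencies use the classic bioenergetic values 0.66
(herbivory), 0.85 (carnivory), 0.45 (detritivory); producer exudation
is 0.4; activity respiration is off (`u_a = 1`), with 0.6 as the
tested alternative. Fish body masses are maximum published weights in
grams.

The true rate parameters are *constructed, not tuned*: biomasses are
set at plausible magnitudes for a shallow eutrophic lake (producer
tens of t/km², fish tenths to a few t/km²), each consumer's
half-saturation constant sits at its mean resource biomass (diet
shares then track availability, keeping predation pressure off scarce
pools), metabolic rates sit 2% above their lower bounds, and the
per-consumer ingestion scalings solve the linear flow balance that
makes every consumer's assimilated intake offset maintenance +
predation + catch at the initial state; the producer growth rate then
balances grazing. This puts the system at an interior equilibrium
whose annual Euler map is near-marginally stable, so 18-year
trajectories stay positive and the noisy path fluctuates around
realistic levels. Noise is absolute-normal with σ at 5% of each
node's typical biomass.

SDE paths are drawn by Euler–Maruyama (optionally with m sub-steps per
year); a non-positive intermediate state is reflected to 1e-8. This
reflection is a *generator-only* guard — the fitted model never needs
it because it predicts from recorded positives — and a path that
triggered it is redrawn with a fresh sub-seed (up to 20 attempts) so
emitted datasets are genuinely positive. Observation-noise scenarios
run the deterministic model and add per-cell Gaussian error, flooring
at 1e-8.

The 4-node recovery scenario (producer, grazer, predator, detritus;
50 years; absolute normal environmental noise) uses constants that
solve the exact flow balance at B* = (5, 2, 1, 4) *and* give the Euler
map spectral radius ≈ 0.93, so the path is a stationary fluctuation in
the partially saturated regime where ingestion rates and
half-saturation constants are separately identifiable. At the desk
budget the fit recovers every σ within 30% and every ingestion rate
within a factor of 2 of truth (verified in the acceptance suite).

**What the generator does not emulate:** the actual recorded biomass
values and their trends, guild-specific catch histories, any
correlation between node noises, non-stationary noise, and
demographic stochasticity. Passing tests therefore demonstrate the
machinery is correct under the model's own assumptions, not that the
model describes any real lake.

## Numerical choices

- Drift evaluation is vectorized over states, so a whole series'
  likelihood is one array pass; CMA-ES eigendecompositions are lazy
  (every `O(n/(λ(c1+cμ)))` generations) to keep 174-parameter fits
  minutes-scale.
- Likelihood factors are computed from the closed-form Gaussian /
  lognormal log-densities; an evaluation error or non-finite
  log-likelihood maps to a +∞ loss (optimizer-safe) and is logged.
- Ties in removal: a pool updating to exactly 0 counts as removed.
- Degenerate inputs: relative scaling at zero biomass raises; a
  dataset with no usable transition yields log-likelihood 0 (empty
  product) with a warning rather than raising, so partial datasets
  can still be scored.
- The transform round trip is accurate to ~1e-7 in free space; fitted
  metabolic rates can sit exactly on their bounds only in the limit
  x → −∞, so bound violations are impossible by construction.

## Limitations

- Parameter uncertainty (confidence sets, posteriors) is out of scope.
- No state-space model combining process and observation noise; the
  two layers are alternatives, not a joint model.
- No seasonal or abiotic forcing; the annual-scale model absorbs those
  into the noise term.
- The desk-scale optimizer budget demonstrates the machinery; results
  at that budget are illustrative, and the 77–81% similarity reported
  for the real lake series at cluster-scale budgets is not a target
  the synthetic pipeline reproduces.
- AIC with 174+ parameters on a few hundred observations is a ranking
  device, not a guard against overfitting.
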