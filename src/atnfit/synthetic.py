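"""Synthetic biomass datasets with known ground truth.

The generator emulates the *structure* of the Lake Võrtsjärv study
data — 15 state variables (one combined phytoplankton producer,
protozooplankton, metazooplankton, benthos, ten fish guilds and
detritus), 18 annual records, missing final-year cells for eel and
detritus, interior detritus gaps filled by two-point interpolation,
two zero records replaced by 1e-8, and catches for five fish guilds —
without reproducing the recorded values themselves.  Every pipeline
stage (likelihoods, calibration, evaluation) can therefore be tested
against a known truth.

The base feeding matrix is a documented reconstruction from the
guilds' trophic roles (plankton -> zooplankton -> planktivorous fish ->
piscivores; benthos -> benthivores; detritivory by zooplankton, benthos
and omnivorous cyprinids); the study's own supplementary matrix is not
public.  It has exactly 72 links; three optional links (perch and pike
cannibalism, white bream as an eel resource) extend it to 75.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .foodweb import FoodWeb, Guild, RateParameters, Trajectory, drift, simulate_deterministic
from .noise import BiomassDataset, NoiseSpec

__all__ = [
    "Scenario",
    "default_vortsjarv_web",
    "default_scenario",
    "four_node_web",
    "four_node_scenario",
    "simulate_sde",
    "apply_observation_model",
    "degrade",
    "generate_dataset",
]

logger = logging.getLogger(__name__)

#: floor used both for zero-record replacement and as the generator-side
#: reflection guard for non-positive simulated states
BIOMASS_FLOOR = 1e-8

# assimilation efficiency by resource type (classic bioenergetic values:
# carnivory 0.85, herbivory 0.66, detritivory 0.45)
E_CARNIVORY = 0.85
E_HERBIVORY = 0.66
E_DETRITIVORY = 0.45
#: producer exudation fraction
S_EXUDATION = 0.4
#: activity-respiration coefficient of the tested alternative (1 = off)
UA_ALTERNATIVE = 0.6

# maximum published body masses (g), used for allometric metabolic
# lower bounds of the fish guilds
FISH_MAX_MASS = {
    "ruffe": 400.0,
    "roach": 1840.0,
    "bleak": 60.0,
    "white_bream": 1000.0,
    "bream": 6010.0,
    "smelt": 180.0,
    "perch": 4750.0,
    "eel": 6600.0,
    "pikeperch": 20000.0,
    "pike": 28400.0,
}

#: fish guilds with annual catch records
CATCH_GUILDS = ("bream", "perch", "eel", "pikeperch", "pike")

# base 72-link feeding matrix: consumer -> resources
_BASE_DIETS: dict[str, tuple[str, ...]] = {
    "protozooplankton": ("phytoplankton", "detritus"),
    "metazooplankton": ("phytoplankton", "protozooplankton", "detritus"),
    "benthos": ("phytoplankton", "protozooplankton", "metazooplankton", "detritus"),
    "ruffe": ("protozooplankton", "metazooplankton", "benthos", "detritus"),
    "roach": ("phytoplankton", "protozooplankton", "metazooplankton", "benthos", "detritus"),
    "bleak": ("phytoplankton", "protozooplankton", "metazooplankton", "benthos", "detritus"),
    "white_bream": ("phytoplankton", "protozooplankton", "metazooplankton", "benthos", "detritus"),
    "bream": ("phytoplankton", "protozooplankton", "metazooplankton", "benthos", "detritus"),
    "smelt": ("protozooplankton", "metazooplankton", "benthos"),
    "perch": ("metazooplankton", "benthos", "ruffe", "roach", "bleak", "white_bream", "bream", "smelt"),
    "eel": ("metazooplankton", "benthos", "detritus", "ruffe", "roach", "bleak", "smelt", "perch"),
    "pikeperch": ("metazooplankton", "benthos", "ruffe", "roach", "bleak", "white_bream", "bream", "smelt", "perch"),
    "pike": ("metazooplankton", "benthos", "ruffe", "roach", "bleak", "white_bream", "bream", "smelt", "perch", "pikeperch", "eel"),
}

#: optional extra links reproducing the 72-75 link feeding-matrix variants
OPTIONAL_LINKS = (("perch", "perch"), ("pike", "pike"), ("eel", "white_bream"))


def default_vortsjarv_web(
    extra_links: tuple[tuple[str, str], ...] = (),
    ua: float = 1.0,
) -> FoodWeb:
    """The 15-node Võrtsjärv-like base web with 72 feeding links.

    ``extra_links`` may include any of :data:`OPTIONAL_LINKS`;
    ``ua < 1`` switches activity respiration on for all consumers.
    """
    guilds = [Guild("phytoplankton", "producer")]
    for name in ("protozooplankton", "metazooplankton", "benthos"):
        guilds.append(Guild(name, "consumer"))
    for name in FISH_MAX_MASS:
        guilds.append(
            Guild(name, "consumer", max_body_mass=FISH_MAX_MASS[name], has_catch=name in CATCH_GUILDS)
        )
    guilds.append(Guild("detritus", "detritus"))

    links = [(c, r) for c, diet in _BASE_DIETS.items() for r in diet]
    for l in extra_links:
        if l not in OPTIONAL_LINKS:
            raise ValueError(f"unknown optional link {l!r}")
        links.append(l)

    producer = {"phytoplankton"}
    e = {}
    for c, r in links:
        if r in producer:
            e[(c, r)] = E_HERBIVORY
        elif r == "detritus":
            e[(c, r)] = E_DETRITIVORY
        else:
            e[(c, r)] = E_CARNIVORY
    s = {"phytoplankton": S_EXUDATION}
    ua_map = {g.name: ua for g in guilds if g.role == "consumer"}
    return FoodWeb(guilds, links, e=e, s=s, ua=ua_map)


@dataclass
class Scenario:
    """Generating conditions for one synthetic dataset."""

    web: FoodWeb
    true_params: RateParameters
    true_noise: NoiseSpec
    B_init: np.ndarray
    n_years: int
    seed: int
    years0: int = 1995  # label of the first year
    missing_pattern: frozenset = frozenset()  # (node, year) unobserved
    zero_pattern: frozenset = frozenset()  # (node, year) recorded as zero
    interpolate_nodes: frozenset = frozenset()  # nodes whose gaps get interpolated
    catches: np.ndarray | None = None  # (n_years, n_nodes) annual catch rates
    substeps: int = 1  # Euler-Maruyama increments per year

    def __post_init__(self) -> None:
        self.B_init = np.asarray(self.B_init, dtype=float)
        names = set(self.web.node_names)
        years = set(range(self.years0, self.years0 + self.n_years))
        for node, year in set(self.missing_pattern) | set(self.zero_pattern):
            if node not in names or year not in years:
                raise ValueError(f"pattern entry ({node!r}, {year}) out of range")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.years0, self.years0 + self.n_years)


def simulate_sde(scenario: Scenario, rng: np.random.Generator | None = None) -> Trajectory:
    """Euler–Maruyama path of the environmental-noise SDE.

    With ``substeps = m`` each year is divided into m increments of
    ``dt = 1/m``.  Non-positive intermediate states are reflected to
    the 1e-8 floor (a generator-only guard, recorded in the removal
    slot as nothing — the guard keeps all emitted biomasses positive).
    With ``sigma = 0`` this reproduces :func:`simulate_deterministic`
    exactly (no removal is triggered on a positive path).
    """
    rng = np.random.default_rng(scenario.seed if rng is None else rng)
    noise = scenario.true_noise
    params = scenario.true_params
    web = scenario.web
    m = int(scenario.substeps)
    dt = 1.0 / m
    n = web.n_nodes
    out = np.empty((scenario.n_years, n))
    B = scenario.B_init.copy()
    out[0] = B
    n_reflected = 0
    for t in range(1, scenario.n_years):
        c = scenario.catches[t - 1] if scenario.catches is not None else None
        for _ in range(m):
            f = drift(B, params, web, c)
            eps = rng.standard_normal(n)
            if noise.scaling == "absolute":
                dW = noise.sigma * np.sqrt(dt) * eps
            else:
                dW = noise.sigma * B * np.sqrt(dt) * eps
            B = B + f * dt + dW
            bad = B <= 0
            if np.any(bad):
                n_reflected += int(bad.sum())
                B = np.where(bad, BIOMASS_FLOOR, B)
        out[t] = B
    traj = Trajectory(B=out)
    traj.n_reflected = n_reflected  # generator diagnostic
    return traj


def apply_observation_model(
    trajectory: np.ndarray, noise: NoiseSpec, rng: np.random.Generator | int
) -> np.ndarray:
    """Add per-cell Gaussian observation error to a simulated trajectory.

    Values <= 0 after the error draw are set to the 1e-8 floor,
    mirroring the zero-record replacement of the study data.
    """
    if noise.layer != "observation":
        raise ValueError("apply_observation_model needs an observation-layer noise spec")
    rng = np.random.default_rng(rng)
    B = np.asarray(trajectory, dtype=float)
    eps = rng.standard_normal(B.shape)
    if noise.scaling == "absolute":
        obs = B + noise.sigma * eps
    else:
        obs = B + noise.sigma * B * eps
    return np.where(obs <= 0, BIOMASS_FLOOR, obs)


def degrade(matrix: np.ndarray, scenario: Scenario) -> BiomassDataset:
    """Apply the study's data-preparation rules to a simulated matrix.

    Masks the missing pattern, replaces zero-pattern records with 1e-8,
    and for nodes flagged for interpolation fills interior gaps with
    the mean of the nearest observed years before and after (flagged
    interpolated; an end-of-series gap stays unfilled with a warning).
    """
    web = scenario.web
    years = scenario.years
    B = np.asarray(matrix, dtype=float).copy()
    T, n = B.shape
    observed = np.ones((T, n), dtype=bool)
    interpolated = np.zeros((T, n), dtype=bool)
    yindex = {int(y): k for k, y in enumerate(years)}
    for node, year in scenario.missing_pattern:
        observed[yindex[year], web.index(node)] = False
    for node, year in scenario.zero_pattern:
        B[yindex[year], web.index(node)] = BIOMASS_FLOOR
    for node in scenario.interpolate_nodes:
        j = web.index(node)
        col_obs = observed[:, j]
        for t in np.flatnonzero(~col_obs):
            before = np.flatnonzero(col_obs[:t])
            after = t + 1 + np.flatnonzero(col_obs[t + 1 :])
            if before.size == 0 or after.size == 0:
                logger.warning(
                    "cannot interpolate %r at year %d: no neighbor on one side",
                    node,
                    int(years[t]),
                )
                continue
            B[t, j] = 0.5 * (B[before[-1], j] + B[after[0], j])
            observed[t, j] = True
            interpolated[t, j] = True
    B = np.where(observed, B, np.nan)
    return BiomassDataset(
        nodes=web.node_names,
        years=years,
        B_obs=B,
        observed_mask=observed,
        catches=scenario.catches,
        interpolated_mask=interpolated,
    )


def generate_dataset(
    scenario: Scenario, max_attempts: int = 20
) -> tuple[BiomassDataset, dict]:
    """Simulate, (optionally) observe, and degrade one dataset.

    Environmental-noise scenarios draw an SDE path; the draw is
    repeated with fresh sub-seeds (up to ``max_attempts``) until no
    reflection guard fired, so emitted biomasses are genuinely
    positive.  Observation-noise scenarios run the deterministic model
    and add measurement error.  Returns the dataset and a ground-truth
    record (parameters, noise scales, latent trajectory).
    """
    noise = scenario.true_noise
    if noise.layer == "environmental":
        traj = None
        for attempt in range(max_attempts):
            rng = np.random.default_rng((scenario.seed, attempt))
            cand = simulate_sde(scenario, rng)
            if cand.n_reflected == 0:
                traj = cand
                break
        if traj is None:
            logger.warning(
                "all %d attempts hit the positivity guard; keeping the last path",
                max_attempts,
            )
            traj = cand
        matrix = traj.B
    else:
        traj = simulate_deterministic(
            scenario.B_init,
            scenario.true_params,
            scenario.web,
            scenario.catches,
            scenario.n_years,
        )
        matrix = apply_observation_model(
            traj.B, noise, np.random.default_rng((scenario.seed, 1))
        )
    data = degrade(matrix, scenario)
    truth = {
        "params": scenario.true_params,
        "sigma": noise.sigma.copy(),
        "noise": noise,
        "trajectory": traj.B.copy(),
        "B_init": scenario.B_init.copy(),
        "seed": scenario.seed,
    }
    return data, truth


# ---------------------------------------------------------------------------
# default scenarios


def _default_true_params(web: FoodWeb) -> tuple[RateParameters, np.ndarray]:
    """Hand-set stable parameters and initial state for the 15-node web.

    Chosen once so the deterministic 18-year trajectory stays strictly
    positive at biomasses on the scale of a shallow eutrophic lake
    (producer tens of t/km^2, fish tenths to a few t/km^2).
    """
    names = web.node_names
    B_init = np.array(
        [
            {
                "phytoplankton": 25.0,
                "protozooplankton": 3.0,
                "metazooplankton": 5.0,
                "benthos": 10.0,
                "ruffe": 0.8,
                "roach": 3.0,
                "bleak": 0.6,
                "white_bream": 1.5,
                "bream": 4.0,
                "smelt": 0.4,
                "perch": 1.5,
                "eel": 0.5,
                "pikeperch": 1.0,
                "pike": 0.8,
                "detritus": 40.0,
            }[n]
            for n in names
        ]
    )
    # metabolic rates slightly above their allometric/default lower bounds
    from .calibration import metabolic_lower_bounds
    from .foodweb import _fr_fractions

    um_lower = metabolic_lower_bounds(web)
    um = um_lower * 1.02
    L = web.n_links
    K = 100.0
    # half-saturation constant per consumer at its mean resource biomass:
    # diet shares then track availability, which keeps predation pressure
    # off the scarce pools and the annual Euler map well-behaved
    B0 = np.empty(L)
    for i in web.consumer_indices:
        sel = web.link_consumer == i
        B0[sel] = float(B_init[web.link_resource[sel]].mean())
    q = np.full(L, 0.3)
    params = RateParameters(
        r=np.array([1.0]), K=K, um=um, J=np.ones(L), B0=B0, q=q, um_lower=um_lower
    )
    catches = np.zeros(web.n_nodes)
    for name in CATCH_GUILDS:
        catches[web.index(name)] = 0.02 * B_init[web.index(name)]

    # near-equilibrium ingestion: per-consumer scalings c solve the linear
    # flow balance  ua_i e.J.F c_i B_i = um_i B_i + C_i + sum_pred c_p flux_pi
    # at the initial state (F is fixed there, so the system is linear in c)
    F = _fr_fractions(B_init[None, :], params, web)[0]
    cons = web.consumer_indices
    pos = {int(i): k for k, i in enumerate(cons)}
    nC = len(cons)
    A = np.zeros((nC, nC))
    b = np.zeros(nC)
    for k, i in enumerate(cons):
        own = web.link_consumer == i
        A[k, k] += web.ua[i] * float(np.sum(web.e[own] * F[own])) * B_init[i]
        b[k] = um[k] * B_init[i] + catches[i]
        preying = web.link_resource == i
        for l in np.flatnonzero(preying):
            p = int(web.link_consumer[l])
            A[k, pos[p]] -= B_init[p] * F[l]
    c = np.linalg.solve(A, b)
    if np.any(c <= 0):
        raise RuntimeError("flow-balance solve produced non-positive ingestion scaling")
    for k, i in enumerate(cons):
        params.J[web.link_consumer == i] *= c[k]
    # producer balance fixes r: growth (net of exudation) offsets grazing
    F = _fr_fractions(B_init[None, :], params, web)[0]
    p = int(web.producer_indices[0])
    grazing = float(
        np.sum(B_init[web.link_consumer] * params.J * F * (web.link_resource == p))
    )
    G = 1.0 - B_init[p] / K
    params.r = np.array([grazing / (B_init[p] * G * (1.0 - web.s[p]))])
    return params, B_init


def default_scenario(seed: int = 0, scaling: str = "absolute") -> Scenario:
    """The study-shaped default: 18 years, 15 nodes, 268 observed cells.

    Missing cells: eel and detritus in the final year.  Detritus
    additionally has six interior years filled by two-point
    interpolation.  Zero records (smelt 2006, eel 1997) are replaced by
    1e-8.  Catches run for five fish guilds at constant rates.
    """
    web = default_vortsjarv_web()
    params, B_init = _default_true_params(web)
    n_years = 18
    y0 = 1995
    sigma = 0.05 * B_init  # absolute scales ~5% of typical biomass
    if scaling == "relative":
        sigma = np.full(web.n_nodes, 0.05)
    noise = NoiseSpec("environmental", "normal", scaling, sigma)
    missing = {("eel", 2012), ("detritus", 2012)}
    detritus_gap_years = (1997, 1999, 2001, 2004, 2007, 2010)
    missing |= {("detritus", y) for y in detritus_gap_years}
    catches = np.zeros((n_years, web.n_nodes))
    for name in CATCH_GUILDS:
        j = web.index(name)
        catches[:, j] = 0.02 * B_init[j]  # modest constant exploitation
    return Scenario(
        web=web,
        true_params=params,
        true_noise=noise,
        B_init=B_init,
        n_years=n_years,
        seed=seed,
        years0=y0,
        missing_pattern=frozenset(missing),
        zero_pattern=frozenset({("smelt", 2006), ("eel", 1997)}),
        interpolate_nodes=frozenset({"detritus"}),
        catches=catches,
    )


def four_node_web() -> FoodWeb:
    """Producer, grazer, predator, detritus — the parameter-recovery toy."""
    guilds = [
        Guild("phytoplankton", "producer"),
        Guild("grazer", "consumer"),
        Guild("predator", "consumer"),
        Guild("detritus", "detritus"),
    ]
    links = [
        ("grazer", "phytoplankton"),
        ("grazer", "detritus"),
        ("predator", "grazer"),
    ]
    e = {
        ("grazer", "phytoplankton"): E_HERBIVORY,
        ("grazer", "detritus"): E_DETRITIVORY,
        ("predator", "grazer"): E_CARNIVORY,
    }
    return FoodWeb(guilds, links, e=e, s={"phytoplankton": 0.1})


def four_node_scenario(seed: int = 0, n_years: int = 50) -> Scenario:
    """Recovery scenario: 50 years of absolute normal environmental noise.

    True parameters put the system at an interior equilibrium of the
    annual Euler map with spectral radius < 1, so the noisy path is a
    stationary fluctuation around biomasses comparable to the
    half-saturation constants — the partially saturated regime in which
    ingestion rates and half-saturation constants are separately
    identifiable.  The constants solve the exact flow balance at
    B* = (5, 2, 1, 4).
    """
    web = four_node_web()
    params = RateParameters(
        r=np.array([0.826873]),
        K=8.0,
        um=np.array([0.508843, 0.17]),
        J=np.array([2.0, 0.886146, 0.6]),
        B0=np.array([4.0, 3.0, 4.0]),
        q=np.zeros(3),
        um_lower=np.array([1e-3, 1e-3]),
    )
    B_init = np.array([5.0, 2.0, 1.0, 4.0])
    sigma = np.array([0.3, 0.15, 0.08, 0.25])
    noise = NoiseSpec("environmental", "normal", "absolute", sigma)
    return Scenario(
        web=web,
        true_params=params,
        true_noise=noise,
        B_init=B_init,
        n_years=n_years,
        seed=seed,
        years0=2000,
    )
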