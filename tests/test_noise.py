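"""Transition densities, likelihoods and predictive intervals."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from atnfit.foodweb import RateParameters, drift, simulate_deterministic
from atnfit.noise import (
    BiomassDataset,
    NoiseSpec,
    PredictiveDistribution,
    cpi,
    env_loglik,
    median_prediction,
    obs_loglik,
    one_step_predictive,
)


def _dataset(three_node_web, B, years=None, mask=None, catches=None):
    T, n = B.shape
    years = np.arange(2000, 2000 + T) if years is None else years
    mask = np.ones((T, n), bool) if mask is None else mask
    # values stay present at masked cells (mask only governs the likelihood);
    # genuinely absent data are NaN in B itself
    return BiomassDataset(
        nodes=three_node_web.node_names,
        years=years,
        B_obs=B,
        observed_mask=mask,
        catches=catches,
    )


# ---------------------------------------------------------------------------
# one-step predictive

def test_predictive_absolute_scale(three_node_web, three_node_params, three_node_state):
    noise = NoiseSpec("environmental", "normal", "absolute", np.array([2.0, 1.0, 0.5]))
    pred = one_step_predictive(three_node_state, three_node_params, three_node_web, None, noise)
    f = drift(three_node_state, three_node_params, three_node_web)
    assert pred.loc == pytest.approx(three_node_state + f)
    assert pred.scale == pytest.approx([2.0, 1.0, 0.5])


def test_predictive_relative_scale(three_node_web, three_node_params):
    B = np.array([10.0, 4.0, 2.0])
    noise = NoiseSpec("environmental", "normal", "relative", np.array([0.1, 0.2, 0.3]))
    pred = one_step_predictive(B, three_node_params, three_node_web, None, noise)
    assert pred.scale == pytest.approx([1.0, 0.8, 0.6])


def test_predictive_relative_degenerate_at_zero(three_node_web, three_node_params):
    noise = NoiseSpec("environmental", "normal", "relative", np.ones(3))
    with pytest.raises(ValueError):
        one_step_predictive(
            np.array([0.0, 1.0, 1.0]), three_node_params, three_node_web, None, noise
        )


@pytest.mark.parametrize("family,scaling", [
    ("normal", "absolute"), ("normal", "relative"),
    ("lognormal", "absolute"), ("lognormal", "relative"),
])
def test_predictive_matches_monte_carlo(three_node_web, three_node_params, three_node_state, family, scaling):
    """Mean/SD of 1e5 simulated one-year transitions match the predictive
    within 3 Monte-Carlo standard errors, for all four noise variants."""
    sigma = np.array([0.5, 0.2, 0.08])
    noise = NoiseSpec("environmental", family, scaling, sigma)
    pred = one_step_predictive(three_node_state, three_node_params, three_node_web, None, noise)
    rng = np.random.default_rng(42)
    N = 100_000
    if family == "normal":
        # Euler-Maruyama draw: B + f dt + sigma (B) sqrt(dt) eps
        f = drift(three_node_state, three_node_params, three_node_web)
        scl = sigma if scaling == "absolute" else sigma * three_node_state
        draws = three_node_state + f + scl * rng.standard_normal((N, 3))
        exp_mean, exp_sd = pred.loc, pred.scale
    else:
        draws = stats.lognorm.rvs(
            s=pred.scale, scale=np.exp(pred.loc), size=(N, 3), random_state=rng
        )
        # moment matching: lognormal mean = Euler location, sd = normal scale
        f = drift(three_node_state, three_node_params, three_node_web)
        exp_mean = three_node_state + f
        exp_sd = sigma if scaling == "absolute" else sigma * three_node_state
    m = draws.mean(axis=0)
    s = draws.std(axis=0, ddof=1)
    se_mean = exp_sd / np.sqrt(N)
    assert np.all(np.abs(m - exp_mean) < 3 * se_mean)
    # SE of the SD estimate ~ sd / sqrt(2(N-1)), inflated for lognormal skew
    se_sd = 6 * exp_sd / np.sqrt(2 * (N - 1))
    assert np.all(np.abs(s - exp_sd) < 3 * se_sd)


def test_lognormal_logspace_parameterization(three_node_web, three_node_params, three_node_state):
    """The alternative switch reuses the normal location/scale in log space."""
    sigma = np.array([0.5, 0.2, 0.08])
    noise = NoiseSpec(
        "environmental", "lognormal", "absolute", sigma, lognormal_param="logspace"
    )
    pred = one_step_predictive(three_node_state, three_node_params, three_node_web, None, noise)
    f = drift(three_node_state, three_node_params, three_node_web)
    assert pred.loc == pytest.approx(three_node_state + f)
    assert pred.scale == pytest.approx(sigma)


# ---------------------------------------------------------------------------
# environmental likelihood

def test_env_loglik_single_year_is_empty_product(three_node_web, three_node_params):
    data = _dataset(three_node_web, np.array([[1.0, 2.0, 3.0]]))
    noise = NoiseSpec("environmental", "normal", "absolute", np.ones(3))
    assert env_loglik(data, three_node_params, three_node_web, noise) == 0.0


def test_env_loglik_two_year_scalar_oracle(three_node_web, three_node_params):
    """Two years, absolute normal: the likelihood is a sum of scalar Gaussian
    log-densities around the Euler prediction."""
    B = np.array([[6.0, 2.0, 5.0], [5.5, 2.2, 5.1]])
    data = _dataset(three_node_web, B)
    sigma = np.array([0.5, 0.2, 0.4])
    noise = NoiseSpec("environmental", "normal", "absolute", sigma)
    f = drift(B[0], three_node_params, three_node_web, data.catches[0])
    expected = sum(
        stats.norm.logpdf(B[1, i], loc=B[0, i] + f[i], scale=sigma[i]) for i in range(3)
    )
    got = env_loglik(data, three_node_params, three_node_web, noise)
    assert got == pytest.approx(expected, abs=1e-9)


def _factor_list_oracle(data, params, web, noise):
    """Brute-force enumeration of all transition factors (normal family)."""
    total = 0.0
    filled = data.conditioning_states()
    for k in range(data.n_years - 1):
        if data.years[k + 1] - data.years[k] != 1:
            continue
        f = drift(filled[k], params, web, data.catches[k])
        for i in range(data.n_nodes):
            if not (data.observed_mask[k, i] and data.observed_mask[k + 1, i]):
                continue
            scale = (
                noise.sigma[i]
                if noise.scaling == "absolute"
                else noise.sigma[i] * filled[k, i]
            )
            total += stats.norm.logpdf(
                data.B_obs[k + 1, i], loc=filled[k, i] + f[i], scale=scale
            )
    return total


def test_env_loglik_masking_drops_exactly_two_factors(three_node_web, three_node_params):
    """Masking node i at an interior year removes the factor predicting that
    cell and the factor conditioning on it — nothing else."""
    rng = np.random.default_rng(7)
    B = rng.uniform(1.0, 8.0, size=(6, 3))
    noise = NoiseSpec("environmental", "normal", "absolute", np.array([0.5, 0.3, 0.6]))
    full = _dataset(three_node_web, B)
    mask = np.ones((6, 3), bool)
    mask[3, 1] = False
    masked = _dataset(three_node_web, B, mask=mask)
    for ds in (full, masked):
        got = env_loglik(ds, three_node_params, three_node_web, noise)
        assert got == pytest.approx(
            _factor_list_oracle(ds, three_node_params, three_node_web, noise), abs=1e-9
        )
    # the two dropped factors, recomputed directly
    f2 = drift(B[2], three_node_params, three_node_web, full.catches[2])
    f3 = drift(B[3], three_node_params, three_node_web, full.catches[3])
    dropped = stats.norm.logpdf(B[3, 1], B[2, 1] + f2[1], 0.3) + stats.norm.logpdf(
        B[4, 1], B[3, 1] + f3[1], 0.3
    )
    got_full = env_loglik(full, three_node_params, three_node_web, noise)
    got_masked = env_loglik(masked, three_node_params, three_node_web, noise)
    assert got_full - got_masked == pytest.approx(dropped, abs=1e-9)


def test_env_loglik_relative_and_lognormal_match_enumeration(three_node_web, three_node_params):
    rng = np.random.default_rng(11)
    B = rng.uniform(1.0, 8.0, size=(5, 3))
    data = _dataset(three_node_web, B)
    sigma = np.array([0.1, 0.05, 0.08])
    rel = NoiseSpec("environmental", "normal", "relative", sigma)
    assert env_loglik(data, three_node_params, three_node_web, rel) == pytest.approx(
        _factor_list_oracle(data, three_node_params, three_node_web, rel), abs=1e-9
    )
    logn = NoiseSpec("environmental", "lognormal", "absolute", np.array([0.5, 0.3, 0.6]))
    # scalar lognormal oracle with moment matching
    total = 0.0
    for k in range(4):
        f = drift(B[k], three_node_params, three_node_web, data.catches[k])
        for i in range(3):
            mean = B[k, i] + f[i]
            sd = logn.sigma[i]
            s2 = np.log1p((sd / mean) ** 2)
            mu = np.log(mean) - s2 / 2
            total += stats.lognorm.logpdf(B[k + 1, i], s=np.sqrt(s2), scale=np.exp(mu))
    assert env_loglik(data, three_node_params, three_node_web, logn) == pytest.approx(
        total, abs=1e-9
    )


def test_env_loglik_invariant_to_padding_missing_years(three_node_web, three_node_params):
    rng = np.random.default_rng(3)
    B = rng.uniform(1.0, 8.0, size=(4, 3))
    noise = NoiseSpec("environmental", "normal", "absolute", np.ones(3) * 0.5)
    base = _dataset(three_node_web, B)
    padded_B = np.vstack([np.full((1, 3), np.nan), B, np.full((2, 3), np.nan)])
    mask = ~np.isnan(padded_B)
    padded = BiomassDataset(
        nodes=three_node_web.node_names,
        years=np.arange(1999, 1999 + 7),
        B_obs=padded_B,
        observed_mask=mask,
    )
    assert env_loglik(padded, three_node_params, three_node_web, noise) == pytest.approx(
        env_loglik(base, three_node_params, three_node_web, noise), abs=1e-12
    )


def test_transition_density_integrates_to_one(three_node_web, three_node_params, three_node_state):
    noise = NoiseSpec("environmental", "normal", "absolute", np.array([0.5, 0.2, 0.4]))
    pred = one_step_predictive(three_node_state, three_node_params, three_node_web, None, noise)
    for i in range(3):
        val, _ = quad(
            lambda x: stats.norm.pdf(x, pred.loc[i], pred.scale[i]),
            pred.loc[i] - 12 * pred.scale[i],
            pred.loc[i] + 12 * pred.scale[i],
        )
        assert val == pytest.approx(1.0, abs=1e-8)


def test_predictive_collapses_as_sigma_vanishes(three_node_web, three_node_params):
    """As sigma -> 0 the density at the Euler mean diverges and the density
    anywhere else collapses."""
    B = np.array([[6.0, 2.0, 5.0], [5.8, 2.1, 5.2]])
    at_mean = []
    off_mean = []
    for s in (1.0, 0.1, 0.01):
        noise = NoiseSpec("environmental", "normal", "absolute", np.full(3, s))
        data_off = _dataset(three_node_web, B)
        off_mean.append(env_loglik(data_off, three_node_params, three_node_web, noise))
        f = drift(B[0], three_node_params, three_node_web)
        B_on = np.vstack([B[0], B[0] + f])
        data_on = _dataset(three_node_web, B_on)
        at_mean.append(env_loglik(data_on, three_node_params, three_node_web, noise))
    assert at_mean[0] < at_mean[1] < at_mean[2]
    assert off_mean[0] > off_mean[1] > off_mean[2]


# ---------------------------------------------------------------------------
# observation likelihood

def test_obs_loglik_zero_residual_closed_form(three_node_web, three_node_params):
    """Data equal to the simulated trajectory: each factor is log(1/(s sqrt(2 pi)))."""
    B_init = np.array([6.0, 2.0, 5.0])
    traj = simulate_deterministic(B_init, three_node_params, three_node_web, None, 4)
    data = _dataset(three_node_web, traj.B)
    s = 0.7
    noise = NoiseSpec("observation", "normal", "absolute", np.full(3, s))
    got = obs_loglik(data, three_node_params, three_node_web, noise, B_init)
    expected = 12 * np.log(1.0 / (s * np.sqrt(2 * np.pi)))
    assert got == pytest.approx(expected, abs=1e-9)


def test_obs_loglik_term_by_term_oracle(three_node_web, three_node_params):
    rng = np.random.default_rng(5)
    B_init = np.array([6.0, 2.0, 5.0])
    traj = simulate_deterministic(B_init, three_node_params, three_node_web, None, 5)
    B = traj.B * rng.uniform(0.8, 1.2, traj.B.shape)
    data = _dataset(three_node_web, B)
    sigma = np.array([0.5, 0.3, 0.6])
    for scaling in ("absolute", "relative"):
        noise = NoiseSpec("observation", "normal", scaling, sigma)
        expected = 0.0
        for t in range(5):
            for i in range(3):
                sc = sigma[i] if scaling == "absolute" else sigma[i] * traj.B[t, i]
                expected += stats.norm.logpdf(B[t, i], traj.B[t, i], sc)
        got = obs_loglik(data, three_node_params, three_node_web, noise, B_init)
        assert got == pytest.approx(expected, abs=1e-9)


def test_obs_loglik_mask_additivity(three_node_web, three_node_params):
    """Removing one cell from the mask subtracts exactly that cell's term."""
    rng = np.random.default_rng(9)
    B_init = np.array([6.0, 2.0, 5.0])
    traj = simulate_deterministic(B_init, three_node_params, three_node_web, None, 4)
    B = traj.B * rng.uniform(0.9, 1.1, traj.B.shape)
    sigma = np.array([0.5, 0.3, 0.6])
    noise = NoiseSpec("observation", "normal", "absolute", sigma)
    full = _dataset(three_node_web, B)
    mask = np.ones((4, 3), bool)
    mask[2, 0] = False
    partial = _dataset(three_node_web, B, mask=mask)
    term = stats.norm.logpdf(B[2, 0], traj.B[2, 0], sigma[0])
    ll_full = obs_loglik(full, three_node_params, three_node_web, noise, B_init)
    ll_part = obs_loglik(partial, three_node_params, three_node_web, noise, B_init)
    assert ll_full - ll_part == pytest.approx(term, abs=1e-9)


def test_obs_loglik_requires_initial_biomass(three_node_web, three_node_params):
    data = _dataset(three_node_web, np.ones((3, 3)))
    noise = NoiseSpec("observation", "normal", "absolute", np.ones(3))
    with pytest.raises(ValueError):
        obs_loglik(data, three_node_params, three_node_web, noise, None)


def test_obs_loglik_equals_negative_least_squares_up_to_constants(
    three_node_web, three_node_params
):
    """With fixed absolute sigma, the observation log-likelihood is an affine
    function of the OLS objective around the simulated trajectory."""
    rng = np.random.default_rng(13)
    B_init = np.array([6.0, 2.0, 5.0])
    traj = simulate_deterministic(B_init, three_node_params, three_node_web, None, 6)
    s = 0.9
    noise = NoiseSpec("observation", "normal", "absolute", np.full(3, s))
    n_cells = 18
    const = n_cells * np.log(1.0 / (s * np.sqrt(2 * np.pi)))
    for trial in range(3):
        B = traj.B * rng.uniform(0.7, 1.3, traj.B.shape)
        data = _dataset(three_node_web, B)
        ll = obs_loglik(data, three_node_params, three_node_web, noise, B_init)
        sse = float(np.sum((B - traj.B) ** 2))
        assert ll == pytest.approx(const - sse / (2 * s**2), abs=1e-9)


# ---------------------------------------------------------------------------
# intervals and medians

def test_cpi_standard_normal():
    pred = PredictiveDistribution("normal", np.zeros(1), np.ones(1))
    lo, hi = cpi(pred, 0.9)
    assert lo[0] == pytest.approx(-1.6449, abs=1e-4)
    assert hi[0] == pytest.approx(1.6449, abs=1e-4)


def test_cpi_lognormal_standard():
    pred = PredictiveDistribution("lognormal", np.zeros(1), np.ones(1))
    lo, hi = cpi(pred, 0.9)
    assert lo[0] == pytest.approx(np.exp(-1.6449), abs=1e-3)
    assert hi[0] == pytest.approx(np.exp(1.6449), abs=1e-3)


def test_cpi_rejects_bad_level():
    pred = PredictiveDistribution("normal", np.zeros(1), np.ones(1))
    with pytest.raises(ValueError):
        cpi(pred, 1.0)


def test_cpi_empirical_coverage():
    """Coverage of simulated draws falls at the nominal level +- 3 binomial SE."""
    rng = np.random.default_rng(21)
    pred = PredictiveDistribution("normal", np.array([3.0]), np.array([2.0]))
    lo, hi = cpi(pred, 0.9)
    draws = rng.normal(3.0, 2.0, 10_000)
    freq = np.mean((draws >= lo[0]) & (draws <= hi[0]))
    se = np.sqrt(0.9 * 0.1 / 10_000)
    assert abs(freq - 0.9) < 3 * se


def test_median_normal_equals_location():
    pred = PredictiveDistribution("normal", np.array([3.0]), np.array([5.0]))
    assert median_prediction(pred)[0] == 3.0


def test_median_lognormal_and_monte_carlo():
    pred = PredictiveDistribution("lognormal", np.array([0.7]), np.array([0.5]))
    assert median_prediction(pred)[0] == pytest.approx(np.exp(0.7))
    rng = np.random.default_rng(8)
    draws = stats.lognorm.rvs(s=0.5, scale=np.exp(0.7), size=100_000, random_state=rng)
    # MC error of the median ~ 1/(2 f(m) sqrt(N))
    f_m = stats.lognorm.pdf(np.exp(0.7), s=0.5, scale=np.exp(0.7))
    se = 1.0 / (2 * f_m * np.sqrt(draws.size))
    assert abs(np.median(draws) - np.exp(0.7)) < 3 * se


def test_noise_spec_validation():
    with pytest.raises(ValueError):
        NoiseSpec("observation", "lognormal", "absolute", np.ones(2))
    with pytest.raises(ValueError):
        NoiseSpec("environmental", "normal", "absolute", np.array([1.0, 0.0]))
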