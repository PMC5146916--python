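import math

import numpy as np
import pytest
from scipy import stats

from poretrans.analysis import (crossing_intervals, diffusion_constant,
                                diffusion_scaling, fit_first_passage,
                                fit_power_law, flory_fit, gyration_radius,
                                mean_translocation_time, normalized_tau)
from poretrans.errors import (FitError, NoSuccessfulTranslocations)
from poretrans.protocol import (EnsembleResult, ProtocolConfig,
                                TranslocationRecord)


def _fake_ensemble(times, force=10.0, extra_failures=0):
    recs = [TranslocationRecord(status="translocated", seed=i,
                                steps=int(t / 5e-3), time=float(t))
            for i, t in enumerate(times)]
    recs += [TranslocationRecord(status="failed_slide", seed=900 + i)
             for i in range(extra_failures)]
    cfg = ProtocolConfig(force=force, ensemble_size=max(1, len(recs)),
                         thermalization_steps=0, max_steps=1)
    return EnsembleResult(config=cfg, records=recs)


# --- translocation-time statistics -------------------------------------------

def test_mean_time_hand_values():
    assert mean_translocation_time(_fake_ensemble([2.0, 4.0])) == (3.0, 1.0)
    m, se = mean_translocation_time(_fake_ensemble([7.5]))
    assert m == 7.5 and math.isnan(se)


def test_failures_are_excluded_from_statistics():
    ens = _fake_ensemble([2.0, 4.0], extra_failures=3)
    assert mean_translocation_time(ens) == (3.0, 1.0)
    assert ens.tally == {"translocated": 2, "failed_slide": 3, "timeout": 0}


def test_no_successes_raise():
    with pytest.raises(NoSuccessfulTranslocations):
        mean_translocation_time(_fake_ensemble([], extra_failures=2))


def test_mean_against_known_first_passage_law():
    # ensemble drawn from an inverse-Gaussian law recovers its analytic mean
    mu, lam = 120.0, 400.0
    t = stats.invgauss.rvs(mu / lam, scale=lam, size=400,
                           random_state=np.random.default_rng(5))
    m, se = mean_translocation_time(_fake_ensemble(t))
    assert m == pytest.approx(mu, abs=3 * se)


def test_normalized_tau():
    a = _fake_ensemble([80.0, 80.0], force=2.5)
    b = _fake_ensemble([100.0, 100.0], force=2.5)
    ratio, err = normalized_tau(a, b)
    assert ratio == pytest.approx(0.8)
    same, _ = normalized_tau(a, a)
    assert same == pytest.approx(1.0)
    with pytest.raises(ValueError, match="force mismatch"):
        normalized_tau(a, _fake_ensemble([100.0], force=5.0))


# --- first-passage fits -------------------------------------------------------

def test_first_passage_parameter_recovery():
    mu, lam = 80.0, 500.0
    t = stats.invgauss.rvs(mu / lam, scale=lam, size=2000,
                           random_state=np.random.default_rng(8))
    fit = fit_first_passage(t)
    assert fit.mu == pytest.approx(mu, abs=3 * fit.mu_stderr)
    assert fit.lam == pytest.approx(lam, abs=3 * fit.lam_stderr)
    # the MLE of the mean is exactly the sample mean (moment identity)
    assert fit.mu == pytest.approx(t.mean(), rel=1e-12)
    assert fit.ks_pvalue > 0.01
    # cross-check against the generic scipy fit with fixed location
    shape, _, scale = stats.invgauss.fit(t, floc=0.0)
    assert shape * scale == pytest.approx(fit.mu, rel=0.05)


def test_first_passage_transport_mapping():
    mu, lam, L = 50.0, 300.0, 30.0
    t = stats.invgauss.rvs(mu / lam, scale=lam, size=500,
                           random_state=np.random.default_rng(2))
    fit = fit_first_passage(t)
    assert fit.drift(L) == pytest.approx(L / fit.mu)
    assert fit.diffusivity(L) == pytest.approx(L**2 / (2 * fit.lam))


def test_first_passage_degenerate_and_small_samples():
    with pytest.raises(FitError, match="at least"):
        fit_first_passage(np.ones(10))
    with pytest.raises(FitError, match="degenerate"):
        fit_first_passage(np.full(100, 7.0))
    with pytest.raises(FitError):
        fit_first_passage(np.concatenate([np.ones(99), [-1.0]]))


# --- power-law fits -----------------------------------------------------------

def test_exact_power_laws_recovered():
    f = np.array([2.0, 5.0, 10.0, 20.0])
    fit1 = fit_power_law(f, 100.0 / f)
    assert fit1.exponent == pytest.approx(1.0, abs=1e-12)
    fit2 = fit_power_law(f, 42.0 / f**2)
    assert fit2.exponent == pytest.approx(2.0, abs=1e-12)
    assert fit2.amplitude == pytest.approx(42.0, rel=1e-9)


def test_noisy_power_law_recovery_and_error_coverage():
    # over many synthetic datasets the fitted exponent is unbiased and the
    # quoted standard error has roughly nominal 2-sigma coverage
    rng = np.random.default_rng(17)
    f = np.array([10.0, 14.0, 20.0, 28.0, 40.0])
    tau = 500.0 / f
    err = 0.04 * tau
    hits, exps = 0, []
    for _ in range(50):
        noisy = tau * np.exp(rng.normal(scale=0.04, size=f.size))
        fit = fit_power_law(f, noisy, err)
        exps.append(fit.exponent)
        if abs(fit.exponent - 1.0) <= 2 * fit.stderr:
            hits += 1
    assert hits >= 42                      # ~95 % nominal coverage
    assert np.mean(exps) == pytest.approx(1.0, abs=0.02)


def test_fit_window_restricts_points():
    f = np.array([1.0, 2.0, 4.0, 10.0, 20.0, 40.0])
    tau = np.where(f < 5, 100.0 / f**2, 100.0 / f)   # crossover shape
    fit = fit_power_law(f, tau, window=(10.0, 40.0))
    assert fit.n_points == 3
    assert fit.window == (10.0, 40.0) or fit.window == (10.0, 40.0)


def test_power_law_input_validation():
    with pytest.raises(FitError):
        fit_power_law([1.0, 2.0], [1.0, 0.5])
    with pytest.raises(ValueError):
        fit_power_law([1.0, 2.0, -3.0], [1.0, 0.5, 0.3])


# --- free-chain observables ---------------------------------------------------

def test_gyration_radius_closed_forms():
    assert gyration_radius(np.zeros((5, 3))) == 0.0
    two = np.array([[0.0, 0, 0], [3.0, 0, 0]])
    assert gyration_radius(two) == pytest.approx(1.5)
    # straight rod of N beads with spacing s: Rg^2 = s^2 (N^2 - 1) / 12
    N, s = 49, 0.96
    rod = np.zeros((N, 3))
    rod[:, 2] = s * np.arange(N)
    assert gyration_radius(rod) ** 2 == pytest.approx(s**2 * (N**2 - 1) / 12)


def test_gyration_mass_weighting():
    pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
    light_heavy = gyration_radius(pos, masses=[1.0, 3.0])
    com = 0.75
    expect = math.sqrt((1 * com**2 + 3 * (1 - com) ** 2) / 4)
    assert light_heavy == pytest.approx(expect)


def test_diffusion_constant_on_brownian_paths():
    # replicate-averaged estimate on exact Brownian paths recovers D
    rng = np.random.default_rng(23)
    D, dt = 0.7, 0.05
    ests = []
    for _ in range(24):
        steps = rng.normal(scale=math.sqrt(2 * D * dt), size=(8000, 3))
        com = np.cumsum(steps, axis=0)
        ests.append(diffusion_constant(com, dt, fit_window=(0.03, 0.12)))
    se = np.std(ests, ddof=1) / math.sqrt(len(ests))
    assert np.mean(ests) == pytest.approx(D, abs=3 * se)
    with pytest.raises(FitError, match="shorter"):
        diffusion_constant(com[:5], dt)


def test_scaling_fit_exact_and_validation():
    N = np.array([13.0, 25.0, 49.0])
    fit = diffusion_scaling(N, 1.5 / N)
    assert fit.exponent == pytest.approx(-1.0, abs=1e-12)
    nu_fit = flory_fit([4, 8, 16], [2.0 * 4**0.69, 2.0 * 8**0.69,
                                    2.0 * 16**0.69])
    assert nu_fit.exponent == pytest.approx(0.69, abs=1e-9)
    with pytest.raises(FitError):
        flory_fit([4, 8], [1.0, 2.0])


def test_crossing_intervals_attribution():
    cs = np.array([0, 100, 700, 800])          # bead 2 stalled
    who, iv = crossing_intervals(cs)
    assert list(who) == [1, 2, 3]
    assert list(iv) == [100, 600, 100]
    # out-of-order crossings are attributed to the late bead
    cs = np.array([0, 100, 900, 300])
    who, iv = crossing_intervals(cs)
    assert list(who) == [1, 3, 2]
    with pytest.raises(ValueError, match="incomplete"):
        crossing_intervals(np.array([0, -1, 10]))
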