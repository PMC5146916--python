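"""Translocation-time statistics, scaling fits and free-chain observables.

The headline quantities are the mean translocation time tau(f) with its
standard error, power-law exponents from weighted log-log fits
(tau ~ f^-gamma, R_g ~ n^nu, D ~ N^-1), normalized ratios
tau* = tau(condition)/tau(reference), and the first-passage fit of the
translocation-time histogram.  The histogram of driven translocation times
is modelled by the first-passage density of a 1-D drift-diffusion process,
i.e. the inverse-Gaussian (Wald) family

    p(t; mu, lam) = sqrt(lam / (2 pi t^3)) exp(-lam (t - mu)^2 / (2 mu^2 t)),

whose two identifiable shape parameters map onto an effective transport
picture via mu = L/v and lam = L^2/(2D) for a nominal distance L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import FitError, NoSuccessfulTranslocations
from .protocol import EnsembleResult


# --- translocation-time statistics ------------------------------------------

def mean_translocation_time(ensemble: EnsembleResult) -> tuple:
    """Arithmetic mean and standard error over translocated records only.

    A single success gives an undefined (nan) standard error; zero successes
    raise :class:`NoSuccessfulTranslocations` rather than returning zero.
    """
    t = ensemble.times
    if len(t) == 0:
        raise NoSuccessfulTranslocations(
            "no successful translocations at this state point")
    if len(t) == 1:
        return float(t[0]), math.nan
    return float(t.mean()), float(t.std(ddof=1) / math.sqrt(len(t)))


def normalized_tau(ensemble: EnsembleResult,
                   reference: EnsembleResult) -> tuple:
    """tau* = tau / tau_ref with errors propagated in quadrature.

    Both ensembles must sit at the same pulling force.
    """
    if ensemble.config.force != reference.config.force:
        raise ValueError(
            f"force mismatch: {ensemble.config.force} vs "
            f"{reference.config.force}; tau* compares matched forces")
    m, dm = mean_translocation_time(ensemble)
    r, dr = mean_translocation_time(reference)
    ratio = m / r
    err = ratio * math.hypot(dm / m if m else 0.0, dr / r if r else 0.0)
    return ratio, err


# --- first-passage (inverse-Gaussian) fit -----------------------------------

@dataclass(frozen=True)
class FirstPassageFit:
    """Maximum-likelihood inverse-Gaussian fit of translocation times."""

    mu: float          # mean first-passage time
    lam: float         # shape parameter L^2 / (2 D)
    n: int
    loglik: float
    ks_statistic: float
    ks_pvalue: float

    @property
    def mu_stderr(self) -> float:
        return math.sqrt(self.mu**3 / (self.n * self.lam))

    @property
    def lam_stderr(self) -> float:
        return self.lam * math.sqrt(2.0 / self.n)

    def drift(self, distance: float) -> float:
        """Effective drift velocity for a nominal passage distance."""
        return distance / self.mu

    def diffusivity(self, distance: float) -> float:
        """Effective diffusion constant for a nominal passage distance."""
        return distance**2 / (2.0 * self.lam)


def fit_first_passage(times, min_samples: int = 50) -> FirstPassageFit:
    """Closed-form MLE of the inverse-Gaussian first-passage density.

    mu_hat is the sample mean and 1/lam_hat = mean(1/t - 1/mu_hat).  A
    degenerate sample (all times equal, or any non-positive time) is
    rejected.
    """
    t = np.asarray(times, dtype=float)
    if len(t) < min_samples:
        raise FitError(f"need at least {min_samples} times, got {len(t)}")
    if (t <= 0).any():
        raise FitError("translocation times must be positive")
    mu = t.mean()
    spread = float(np.mean(1.0 / t) - 1.0 / mu)
    if spread <= 1e-14 / mu:
        raise FitError("degenerate sample: no spread in translocation times")
    lam = 1.0 / spread
    dist = stats.invgauss(mu / lam, scale=lam)
    loglik = float(dist.logpdf(t).sum())
    if not np.isfinite(loglik):
        raise FitError("inverse-Gaussian likelihood did not evaluate finitely")
    ks = stats.kstest(t, dist.cdf)
    return FirstPassageFit(mu=float(mu), lam=float(lam), n=len(t),
                           loglik=loglik, ks_statistic=float(ks.statistic),
                           ks_pvalue=float(ks.pvalue))


# --- log-log scaling fits ----------------------------------------------------

@dataclass(frozen=True)
class ScalingFit:
    """Power-law exponent from a weighted least-squares log-log fit."""

    exponent: float
    stderr: float
    amplitude: float
    window: tuple
    n_points: int


def _loglog_fit(x, y, errors=None) -> ScalingFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise FitError("a scaling fit needs at least 3 points")
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("log-log fit requires strictly positive data")
    lx, ly = np.log(x), np.log(y)
    if errors is not None:
        errors = np.asarray(errors, dtype=float)
        if (errors <= 0).any():
            raise ValueError("errors must be positive")
        w = (y / errors) ** 2          # weights on log y
    else:
        w = np.ones_like(ly)
    X = np.column_stack([np.ones_like(lx), lx])
    WX = X * w[:, None]
    cov = np.linalg.inv(X.T @ WX)
    beta = cov @ (WX.T @ ly)
    resid = ly - X @ beta
    dof = len(x) - 2
    scale = float(resid @ (w * resid)) / dof if dof > 0 else 0.0
    # do not shrink the quoted error below the purely statistical one when the
    # fit happens to be unusually straight
    se = math.sqrt(cov[1, 1] * max(scale, 1.0)) if errors is not None \
        else math.sqrt(cov[1, 1] * scale) if dof > 0 else math.nan
    return ScalingFit(exponent=float(beta[1]), stderr=float(se),
                      amplitude=float(math.exp(beta[0])),
                      window=(float(x.min()), float(x.max())),
                      n_points=len(x))


def fit_power_law(f_values, tau_values, errors=None,
                  window: tuple | None = None) -> ScalingFit:
    """Exponent gamma of tau(f) ~ f^-gamma by weighted least squares.

    ``window = (f_min, f_max)`` restricts the fit; gamma is returned as a
    positive number for decaying data.
    """
    f = np.asarray(f_values, dtype=float)
    tau = np.asarray(tau_values, dtype=float)
    err = None if errors is None else np.asarray(errors, dtype=float)
    if window is not None:
        keep = (f >= window[0]) & (f <= window[1])
        f, tau = f[keep], tau[keep]
        err = None if err is None else err[keep]
    fit = _loglog_fit(f, tau, err)
    return ScalingFit(exponent=-fit.exponent, stderr=fit.stderr,
                      amplitude=fit.amplitude, window=fit.window,
                      n_points=fit.n_points)


#: default force windows for the two regimes of tau(f); the crossover for the
#: small pore sits between them
HIGH_FORCE_WINDOW = (10.0, math.inf)
LOW_FORCE_WINDOW = (0.0, 4.0)


def fit_two_power_laws(f_values, tau_values, errors=None) -> tuple:
    """Optional guide-curve decomposition: exponents in the low- and high-f
    windows, fitted separately (not used for headline exponents)."""
    low = fit_power_law(f_values, tau_values, errors,
                        window=(LOW_FORCE_WINDOW[0], LOW_FORCE_WINDOW[1]))
    high = fit_power_law(f_values, tau_values, errors,
                         window=(HIGH_FORCE_WINDOW[0], HIGH_FORCE_WINDOW[1]))
    return low, high


def compare_exponential_low_f(f_values, tau_values) -> dict:
    """Likelihood-style comparison of tau ~ f^-gamma vs tau ~ exp(-alpha f)
    in the low-force window, via residual sums of squares in log space."""
    f = np.asarray(f_values, dtype=float)
    tau = np.asarray(tau_values, dtype=float)
    keep = f <= LOW_FORCE_WINDOW[1]
    f, tau = f[keep], tau[keep]
    if len(f) < 3:
        raise FitError("need at least 3 low-force points")
    ly = np.log(tau)
    pl = np.polyfit(np.log(f), ly, 1)
    ex = np.polyfit(f, ly, 1)
    return {
        "power_law": {"gamma": -pl[0],
                      "rss": float(np.sum((ly - np.polyval(pl, np.log(f)))**2))},
        "exponential": {"alpha": -ex[0],
                        "rss": float(np.sum((ly - np.polyval(ex, f))**2))},
    }


def crossing_intervals(crossing_steps) -> tuple:
    """Per-bead passage intervals from first-crossing times.

    Sorts the beads by the step at which each first reached the trans side
    and attributes each inter-event interval to the bead that crossed; a
    stall while one bead engages the pore shows up as a long interval
    attributed to that bead.  Returns ``(bead_indices, intervals)`` for the
    second crossing onward.
    """
    cs = np.asarray(crossing_steps)
    if (cs < 0).any():
        raise ValueError("crossing steps incomplete: trajectory did not finish")
    order = np.argsort(cs, kind="stable")
    return order[1:], np.diff(cs[order])


# --- free-chain validation observables ---------------------------------------

def gyration_radius(positions, masses=None) -> float:
    """Mass-weighted radius of gyration of one conformation."""
    pos = np.asarray(positions, dtype=float)
    if masses is None:
        m = np.ones(len(pos))
    else:
        m = np.asarray(masses, dtype=float)
    com = np.average(pos, axis=0, weights=m)
    return float(np.sqrt(np.average(np.sum((pos - com) ** 2, axis=1),
                                    weights=m)))


def flory_fit(n_list, rg_list, errors=None) -> ScalingFit:
    """Apparent Flory exponent nu from R_g ~ n^nu across chain lengths."""
    return _loglog_fit(n_list, rg_list, errors)


def diffusion_constant(com_trajectory, dt: float,
                       fit_window: tuple = (0.1, 0.5)) -> float:
    """D from the long-time slope of the center-of-mass MSD.

    ``com_trajectory`` is the (n_samples, 3) center-of-mass track sampled
    every ``dt`` time units; the MSD is averaged over all time origins at
    lags between the given fractions of the trajectory length and fitted
    linearly *with* an intercept (the inertial transient of the underdamped
    dynamics shifts the MSD by a constant without changing its long-time
    slope); D = slope / (2 * 3).
    """
    com = np.asarray(com_trajectory, dtype=float)
    nsamp = len(com)
    lags = np.arange(max(1, int(fit_window[0] * nsamp)),
                     max(2, int(fit_window[1] * nsamp)))
    if nsamp < 10 or len(lags) < 2:
        raise FitError("trajectory shorter than the MSD fit window")
    msd = np.empty(len(lags))
    for k, lag in enumerate(lags):
        d = com[lag:] - com[:-lag]
        msd[k] = np.mean(np.sum(d * d, axis=1))
    t = lags * dt
    slope = float(np.polyfit(t, msd, 1)[0])
    return slope / 6.0


def diffusion_scaling(n_list, d_list, errors=None) -> ScalingFit:
    """Signed exponent of D versus chain size (expected -1, Rouse-like)."""
    return _loglog_fit(n_list, d_list, errors)
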