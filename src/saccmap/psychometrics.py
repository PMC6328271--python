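"""Cumulative-Gaussian psychometric fits for the constant-stimuli threshold task.

Performance in the two-alternative orientation task is modeled as

    P(correct; theta) = 0.5 + 0.5 * Phi((theta - mu) / sigma)

over tilt magnitude theta, anchored at the 50% guessing floor.  The tilt
threshold is the smallest theta at which the fitted function reaches the
criterion level (85% correct by default):

    threshold = mu + sigma * Phi^-1(2 * criterion - 1).

Fitting maximizes the binomial log-likelihood with a deterministic
multi-start grid followed by Nelder-Mead refinement, so repeated fits of
the same data give identical results without any seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtri
from scipy.stats import norm

#: tilt-interval bounds (deg) per task and eccentricity group
_TILT_BOUNDS = {
    "peripheral": {1: (1.0, 9.0), 2: (1.0, 13.0), 3: (1.0, 17.0),
                   4: (1.0, 17.0), 5: (1.0, 17.0)},
    "foveal": {1: (1.0, 25.0), 2: (1.0, 25.0), 3: (1.0, 21.0),
               4: (1.0, 21.0), 5: (1.0, 21.0)},
}


def tilt_intervals(group: int, task: str = "peripheral") -> np.ndarray:
    """Five linearly spaced tilt magnitudes (deg) for a task/eccentricity group."""
    try:
        lo, hi = _TILT_BOUNDS[task][group]
    except KeyError:
        raise ValueError(f"unknown task/group: {task!r}/{group!r}") from None
    return np.linspace(lo, hi, 5)


@dataclass
class ConstantStimuliBlock:
    """Aggregated constant-stimuli data for one eccentricity group."""

    eccentricity_group: int
    tilts: np.ndarray        # tilt magnitudes, deg
    n: np.ndarray            # trials presented per level
    k: np.ndarray            # correct responses per level

    def __post_init__(self):
        self.tilts = np.asarray(self.tilts, float)
        self.n = np.asarray(self.n, int)
        self.k = np.asarray(self.k, int)
        if not (len(self.tilts) == len(self.n) == len(self.k)):
            raise ValueError("tilts, n and k must have equal length")
        if (self.k > self.n).any() or (self.n < 0).any():
            raise ValueError("need 0 <= k <= n per level")


@dataclass
class PsychometricFit:
    mu: float
    sigma: float
    loglik: float
    threshold: float
    stable: bool
    criterion: float = 0.85
    lapse: float = 0.0

    def predict(self, theta) -> np.ndarray:
        return psychometric_function(theta, self.mu, self.sigma)


def psychometric_function(theta, mu: float, sigma: float) -> np.ndarray:
    """P(correct) at tilt magnitude theta under the guessing-floor model."""
    return 0.5 + 0.5 * norm.cdf((np.asarray(theta, float) - mu) / sigma)


def _nll(params, tilts, n, k):
    mu, log_sigma = params
    sigma = np.exp(log_sigma)
    p = 0.5 + 0.5 * norm.cdf((tilts - mu) / sigma)
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return -np.sum(k * np.log(p) + (n - k) * np.log(1 - p))


def fit_cumulative_gaussian(block: ConstantStimuliBlock,
                            criterion: float = 0.85) -> PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit of one threshold block.

    Degenerate data are flagged unstable with the threshold clamped to the
    tested interval: all-correct blocks clamp to the lowest tested tilt,
    chance-level blocks to the highest.
    """
    used = block.n > 0
    tilts, n, k = block.tilts[used], block.n[used], block.k[used]
    if len(np.unique(tilts)) < 2:
        raise ValueError("need at least two distinct tilt levels with trials")
    t_lo, t_hi = float(tilts.min()), float(tilts.max())

    if (k == n).all():  # ceiling: slope unconstrained from above
        return PsychometricFit(mu=t_lo, sigma=np.finfo(float).eps, loglik=0.0,
                               threshold=t_lo, stable=False, criterion=criterion)
    pooled = k.sum() / n.sum()
    top = k[np.argmax(tilts)] / n[np.argmax(tilts)]
    if pooled <= 0.55 and top <= 0.65:  # indistinguishable from guessing
        ll = -_nll((t_hi * 10, np.log(t_hi * 10)), tilts, n, k)
        return PsychometricFit(mu=t_hi * 10, sigma=t_hi * 10, loglik=ll,
                               threshold=t_hi, stable=False, criterion=criterion)

    span = t_hi - t_lo
    mu_grid = np.linspace(t_lo - span, t_hi + span, 9)
    ls_grid = np.log(np.geomspace(span / 20, span * 4, 7))
    starts = sorted(((float(m), float(s)) for m in mu_grid for s in ls_grid),
                    key=lambda p: _nll(p, tilts, n, k))
    best, best_nll = None, np.inf
    for x0 in starts[:3]:
        res = minimize(_nll, x0, args=(tilts, n, k), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if res.fun < best_nll:
            best, best_nll = res.x, res.fun
    mu, sigma = float(best[0]), float(np.exp(best[1]))

    thr = threshold_at_criterion(mu, sigma, criterion)
    stable = True
    if thr < 0.0:
        thr, stable = 0.0, False
    elif thr > 2.0 * t_hi:
        thr, stable = t_hi, False
    return PsychometricFit(mu=mu, sigma=sigma, loglik=-best_nll,
                           threshold=thr, stable=stable, criterion=criterion)


def threshold_at_criterion(mu: float, sigma: float, criterion: float = 0.85) -> float:
    """Tilt at which the fitted function reaches the criterion correct rate."""
    if not 0.5 < criterion < 1.0:
        raise ValueError(f"criterion must lie in (0.5, 1), got {criterion}")
    return float(mu + sigma * ndtri(2.0 * criterion - 1.0))


def threshold_profile(thresholds: Sequence[float],
                      eccentricities: Sequence[float]) -> Callable:
    """Piecewise-linear tilt-threshold profile over eccentricity.

    Constant extrapolation beyond the outer groups; used to assign the
    tilt shown at every grid node of the main task from the node's
    distance to the fixation target.
    """
    thr = np.asarray(thresholds, float)
    ecc = np.asarray(eccentricities, float)
    if len(thr) != len(ecc):
        raise ValueError("thresholds and eccentricities must have equal length")
    if not (np.diff(ecc) > 0).all():
        raise ValueError("eccentricities must be strictly increasing")

    def profile(e):
        return np.interp(e, ecc, thr)

    return profile
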