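"""Resampling and ANOVA inference for the attention maps.

Comparisons at positions of interest use a paired bootstrap: participants
are the resampling unit (each participant's pair of values travels
together), the statistic is the mean difference, and the two-tailed p is
twice the smaller tail proportion of the resampled differences, floored at
1/B.  Saccade latency/accuracy effects of discrimination-target
eccentricity use a one-way repeated-measures ANOVA with partial eta
squared = SS_effect / (SS_effect + SS_error).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .geometry import TestGrid, surround_positions

logger = logging.getLogger(__name__)

DEFAULT_B = 10000


@dataclass
class BootstrapResult:
    observed_diff: float
    p_two_tailed: float
    n_resamples: int
    seed: int
    comparison: str = ""

    def __post_init__(self):
        assert 0.0 < self.p_two_tailed <= 1.0


@dataclass
class AnovaResult:
    F: float
    df_effect: int
    df_error: int
    p: float
    eta_p_sq: float          # proportion in [0, 1]
    degenerate: bool = False

    @property
    def eta_p_sq_percent(self) -> float:
        return 100.0 * self.eta_p_sq


def bootstrap_paired(a: Sequence[float], b: Sequence[float], B: int = DEFAULT_B,
                     seed: int = 0, comparison: str = "") -> BootstrapResult:
    """Paired bootstrap of mean(a) - mean(b) over participants.

    Each resample draws participants with replacement and recomputes the
    mean difference; p = 2 * min(P(diff* <= 0), P(diff* >= 0)), capped at 1
    and floored at 1/B.  Resamples draw n-1 of the n participants (the
    variance-unbiased m-out-of-n variant: the plug-in variance of a
    resampled mean of n draws is biased low by (n-1)/n, which makes the
    plain percentile test anticonservative for small panels) and the tail
    proportions are add-one smoothed.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("a and b must have equal length")
    if a.ndim != 1 or len(a) < 2:
        raise ValueError("need at least two paired values")
    d = a - b
    n = len(d)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, max(n - 1, 2)))
    diffs = d[idx].mean(axis=1)
    p_lo = (float((diffs <= 0).sum()) + 1.0) / (B + 1.0)
    p_hi = (float((diffs >= 0).sum()) + 1.0) / (B + 1.0)
    p = min(max(2.0 * min(p_lo, p_hi), 1.0 / B), 1.0)
    return BootstrapResult(observed_diff=float(d.mean()), p_two_tailed=p,
                           n_resamples=B, seed=seed, comparison=comparison)


def _paired_complete(a: pd.Series, b: pd.Series):
    """Align on participant and keep complete pairs only."""
    a, b = a.align(b, join="inner")
    ok = a.notna() & b.notna()
    if ok.sum() < len(a):
        logger.warning("dropping %d participants with incomplete values from "
                       "a paired comparison", int((~ok).sum()))
    return a[ok].to_numpy(), b[ok].to_numpy()


def _node_values(table: pd.DataFrame, poi, value: str) -> pd.Series:
    at = table[(table["x"] == poi[0]) & (table["y"] == poi[1])]
    if at.empty:
        raise ValueError(f"position {poi} missing from the table")
    return at.set_index("participant")[value]


def poi_vs_rest(table: pd.DataFrame, poi, B: int = DEFAULT_B, seed: int = 0,
                value: str = "dprime_norm", name: str = "") -> BootstrapResult:
    """Sensitivity at a position of interest vs the mean over all other
    tested nodes, per participant, paired bootstrap."""
    a = _node_values(table, poi, value)
    rest = table[(table["x"] != poi[0]) | (table["y"] != poi[1])]
    b = rest.groupby("participant")[value].mean()
    a, b = _paired_complete(a, b)
    return bootstrap_paired(a, b, B=B, seed=seed,
                            comparison=name or f"{poi} vs rest")


def poi_vs_surround(table: pd.DataFrame, poi, grid: TestGrid,
                    B: int = DEFAULT_B, seed: int = 0,
                    value: str = "dprime_norm", name: str = "") -> BootstrapResult:
    """Sensitivity at a position of interest vs the mean over its diagonal
    surround nodes, per participant, paired bootstrap."""
    surround = surround_positions(tuple(poi), grid)
    if not surround:
        raise ValueError(f"position {poi} has no surround nodes")
    a = _node_values(table, poi, value)
    sel = table[[tuple(p) in {tuple(s) for s in surround}
                 for p in zip(table["x"], table["y"])]]
    b = sel.groupby("participant")[value].mean()
    a, b = _paired_complete(a, b)
    return bootstrap_paired(a, b, B=B, seed=seed,
                            comparison=name or f"{poi} vs surround")


def rm_anova(y: np.ndarray) -> AnovaResult:
    """One-way repeated-measures ANOVA on a participants x levels matrix.

    SS_total splits into subject, effect (levels) and error (interaction)
    sums of squares; F = MS_effect / MS_error with df (k-1, (k-1)(n-1)).
    A zero error term (perfectly additive data) is flagged degenerate.
    """
    y = np.asarray(y, float)
    if y.ndim != 2:
        raise ValueError("y must be a 2-D participants x levels matrix")
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 participants and 2 levels")
    if not np.isfinite(y).all():
        raise ValueError("missing cells; repeated-measures ANOVA requires "
                         "a complete matrix")
    grand = y.mean()
    ss_effect = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_subject = k * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_error = ss_total - ss_effect - ss_subject
    df_effect = k - 1
    df_error = (k - 1) * (n - 1)
    ms_error = ss_error / df_error
    if ms_error <= 1e-12 * max(ss_total, 1.0):
        if ss_effect <= 1e-12 * max(ss_total, 1.0):
            # identical columns: no effect, possibly perfect additivity
            return AnovaResult(F=0.0, df_effect=df_effect, df_error=df_error,
                               p=1.0, eta_p_sq=0.0, degenerate=True)
        return AnovaResult(F=np.inf, df_effect=df_effect, df_error=df_error,
                           p=0.0, eta_p_sq=1.0, degenerate=True)
    F = (ss_effect / df_effect) / ms_error
    p = float(f_dist.sf(F, df_effect, df_error))
    eta = ss_effect / (ss_effect + ss_error) if (ss_effect + ss_error) > 0 else 0.0
    return AnovaResult(F=float(F), df_effect=df_effect, df_error=df_error,
                       p=p, eta_p_sq=float(eta))


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Optional multiple-testing correction across map-node tests (off by
    default in the pipeline, matching the per-node convention)."""
    p = np.asarray(p_values, float)
    return np.minimum(p * len(p), 1.0)
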