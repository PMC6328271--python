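"""Per-position signal-detection sensitivity tables.

A clockwise report to a clockwise discrimination target is (arbitrarily) a
hit, a clockwise report to a counterclockwise target a false alarm, so

    d' = z(hit rate) - z(false-alarm rate)

measures orientation sensitivity independent of response bias.  Rates of
exactly 0 or 1 are replaced by 0.01/0.99 before the z-transform;
below-chance performance maps to negative d' (no truncation).  Per
participant and condition, node sensitivities are min-max normalized to
[0, 1] before any averaging across participants.
"""

from __future__ import annotations

import logging
from typing import Tuple

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .records import Condition

logger = logging.getLogger(__name__)

#: extreme-rate correction bounds
RATE_CORRECTION = (0.01, 0.99)
#: cue-offset-to-saccade-onset boundary between the two cue conditions, ms
CONDITION_SPLIT_MS = 175.0
#: minimum trials of each tilt sign for a node cell to enter maps directly
MIN_PER_SIGN = 5


def split_conditions(trials: pd.DataFrame) -> pd.DataFrame:
    """Assign final condition labels and drop timing-inconsistent cue trials.

    Cue trials belong to the late-cue class when the cue disappeared at
    most 175 ms before saccade onset (SOA 50) and to the early-cue class
    when it disappeared more than 175 ms before (SOA 200).  Trials whose
    realized cue-offset-to-saccade interval contradicts their SOA class are
    dropped with a logged count.  Requires a ``latency`` column (ms from
    saccade-target onset to saccade onset).
    """
    df = trials.copy()
    cue = df["condition"] != Condition.NO_CUE.value
    soa = df["condition"].map({Condition.CUE_SOA50.value: 50.0,
                               Condition.CUE_SOA200.value: 200.0})
    # cue offset (after st onset) = dt_onset - SOA + 50 ms cue duration
    cue_off = df["dt_onset_ms"] - soa + 50.0
    interval = df["latency"] - cue_off
    late_ok = (df["condition"] == Condition.CUE_SOA50.value) & (interval <= CONDITION_SPLIT_MS)
    early_ok = (df["condition"] == Condition.CUE_SOA200.value) & (interval > CONDITION_SPLIT_MS)
    keep = ~cue | late_ok | early_ok
    dropped = int((~keep).sum())
    if dropped:
        logger.info("condition split dropped %d timing-inconsistent cue trials", dropped)
    return df[keep].reset_index(drop=True)


def tabulate(trials: pd.DataFrame) -> Tuple[float, float, int, int]:
    """(hit rate, false-alarm rate, n_cw, n_ccw) for the trials at one node.

    Rates of exactly 0 or 1 are replaced by the correction bounds.  A node
    with trials of only one tilt sign cannot be tabulated.
    """
    cw = trials[trials["dt_tilt"] > 0]
    ccw = trials[trials["dt_tilt"] < 0]
    n_cw, n_ccw = len(cw), len(ccw)
    if n_cw == 0 or n_ccw == 0:
        raise ValueError("node has trials of only one tilt sign")
    lo, hi = RATE_CORRECTION
    hit = float(np.clip((cw["response"] == "cw").mean(), lo, hi))
    fa = float(np.clip((ccw["response"] == "cw").mean(), lo, hi))
    return hit, fa, n_cw, n_ccw


def dprime(hit_rate: float, fa_rate: float) -> float:
    """z(hit) - z(false alarm); both rates must already be corrected."""
    if not (0.0 < hit_rate < 1.0 and 0.0 < fa_rate < 1.0):
        raise ValueError("rates must lie in (0, 1); apply the 0.99/0.01 "
                         "correction before computing d'")
    return float(ndtri(hit_rate) - ndtri(fa_rate))


def normalize(values: np.ndarray) -> np.ndarray:
    """Min-max map onto [0, 1].  NaNs pass through; raises on a flat field."""
    v = np.asarray(values, float)
    finite = v[np.isfinite(v)]
    if len(finite) < 2:
        raise ValueError("need at least two finite values to normalize")
    lo, hi = finite.min(), finite.max()
    if hi - lo <= 0:
        raise ValueError("all values equal; normalization undefined")
    return (v - lo) / (hi - lo)


def sensitivity_table(trials: pd.DataFrame, grid,
                      min_per_sign: int = MIN_PER_SIGN) -> pd.DataFrame:
    """Per (participant, condition, node) hit/FA counts, d' and normalized d'.

    Expects mirrored, included trials with columns dt_x, dt_y, dt_tilt,
    response, participant, condition.  Node cells with fewer than
    ``min_per_sign`` trials of either sign get NaN d' (they are later
    interpolated like untested intersections).  Normalization is per
    participant x condition over its tabulated nodes; a flat cell set is
    flagged excluded.
    """
    nodes = [tuple(p) for p in grid.as_array()]
    rows = []
    for (pp, cond), sub in trials.groupby(["participant", "condition"]):
        for node in nodes:
            at = sub[(sub["dt_x"] == node[0]) & (sub["dt_y"] == node[1])]
            cw = at[at["dt_tilt"] > 0]
            ccw = at[at["dt_tilt"] < 0]
            n_cw, n_ccw = len(cw), len(ccw)
            if min(n_cw, n_ccw) >= min_per_sign:
                hit, fa, _, _ = tabulate(at)
                d = dprime(hit, fa)
            else:
                hit = fa = d = np.nan
            rows.append({"participant": pp, "condition": cond,
                         "x": node[0], "y": node[1], "n_cw": n_cw,
                         "n_ccw": n_ccw, "hit_rate": hit, "fa_rate": fa,
                         "dprime": d})
    table = pd.DataFrame(rows)

    table["dprime_norm"] = np.nan
    table["excluded"] = False
    for (pp, cond), sub in table.groupby(["participant", "condition"]):
        vals = sub["dprime"].to_numpy()
        try:
            table.loc[sub.index, "dprime_norm"] = normalize(vals)
        except ValueError:
            table.loc[sub.index, "excluded"] = True
            logger.warning("participant %s condition %s: flat or empty d' "
                           "field, excluded from group maps", pp, cond)
    return table


def node_matrix(table: pd.DataFrame, value: str = "dprime_norm") -> pd.DataFrame:
    """Pivot a sensitivity table to participants x nodes for one condition."""
    return table.pivot_table(index="participant", columns=["x", "y"],
                             values=value, dropna=False)


def subtraction_table(cue_table: pd.DataFrame, no_cue_table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant re-normalized (cue - no cue) normalized-d' differences.

    Both inputs are single-condition slices of a sensitivity table over the
    same node set.  The per-node difference of normalized sensitivities is
    min-max re-normalized per participant; the group map averages these.
    """
    key = ["participant", "x", "y"]
    a = cue_table.set_index(key)["dprime_norm"]
    b = no_cue_table.set_index(key)["dprime_norm"]
    if not a.index.equals(b.index):
        raise ValueError("cue and no-cue tables must cover the same "
                         "participant x node set")
    diff = (a - b).reset_index(name="diff")
    diff["diff_norm"] = np.nan
    diff["excluded"] = False
    for pp, sub in diff.groupby("participant"):
        try:
            diff.loc[sub.index, "diff_norm"] = normalize(sub["diff"].to_numpy())
        except ValueError:
            diff.loc[sub.index, "excluded"] = True
            logger.warning("participant %s: degenerate subtraction field", pp)
    return diff
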