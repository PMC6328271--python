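"""Velocity-based saccade detection and trial-inclusion rules.

Eye position is sampled at 1 kHz.  Positions are smoothed with a centered
20-sample moving average, 2-D velocity is taken by central differences,
and a saccade is a run of samples whose speed exceeds

    median(speed) + lambda * SD_robust

for at least 20 ms, with the robust SD estimated per velocity component as
sqrt(median(v_c^2) - median(v_c)^2) and combined across components.  The
per-trial threshold makes detection robust to the saccade's own samples,
which would inflate a plain sample SD.

Trial inclusion mirrors the behavioral protocol: fixation held within a
2.0-dva radius of the fixation target, the primary saccade starting there
and landing within 2.0 dva of the saccade target, latency within
(25, 350) ms, no blink, and the discrimination target extinguished in the
150 ms before saccade onset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from .geometry import ScreenLayout, eccentricity_group, streams_overlap_targets
from .records import TrialRecord

logger = logging.getLogger(__name__)

#: sampling interval, ms
SAMPLE_DT_MS = 1.0
#: gaze gates around fixation and saccade targets, dva
GATE_RADIUS = 2.0
#: accepted saccade-latency window after saccade-target onset, ms
MIN_LATENCY_MS = 25.0
MAX_OFFSET_MS = 350.0
#: dt must extinguish within this window before saccade onset, ms
DT_WINDOW_MS = 150.0


@dataclass
class GazeTrace:
    """Uniform 1-kHz eye-position series for one trial."""

    t: np.ndarray       # ms from trial start, strictly increasing, 1-ms step
    x: np.ndarray       # dva
    y: np.ndarray       # dva
    valid: np.ndarray   # per-sample flag (False during blinks)

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.valid = np.asarray(self.valid, bool)
        if not (len(self.t) == len(self.x) == len(self.y) == len(self.valid)):
            raise ValueError("trace arrays must have equal length")
        dt = np.diff(self.t)
        if len(dt) and not np.allclose(dt, SAMPLE_DT_MS):
            raise ValueError("trace must be uniformly sampled at 1 kHz")

    def __len__(self):
        return len(self.t)


@dataclass
class SaccadeEvent:
    onset_t: float
    offset_t: float
    start_pos: tuple
    end_pos: tuple
    amplitude: float
    latency: Optional[float] = None  # vs saccade-target onset, set at validation


@dataclass
class InclusionResult:
    included: bool
    reasons: List[str] = field(default_factory=list)
    latency: Optional[float] = None
    landing_error: Optional[float] = None
    primary: Optional[SaccadeEvent] = None


def smooth_velocity(trace: GazeTrace, window: int = 20) -> np.ndarray:
    """Speed series (dva/s) from smoothed positions.

    Positions are averaged over a centered ``window``-sample boxcar, then
    differentiated by central differences.  Samples whose smoothing or
    difference stencil is incomplete (edges, blinks) are NaN.
    Returns an (n, 3) array of columns (vx, vy, speed) -- the components
    are needed by the robust threshold estimator.
    """
    n = len(trace)
    if n <= window + 2:
        raise ValueError(f"trace of {n} samples is too short for window {window}")
    x = np.where(trace.valid, trace.x, np.nan)
    y = np.where(trace.valid, trace.y, np.nan)
    half = window // 2
    kernel = np.ones(window) / window
    # centered moving average; any NaN in the stencil propagates
    xs = np.convolve(x, kernel, mode="full")[half:half + n]
    ys = np.convolve(y, kernel, mode="full")[half:half + n]
    xs[:half] = xs[n - window + half:] = np.nan
    ys[:half] = ys[n - window + half:] = np.nan

    dt_s = SAMPLE_DT_MS / 1000.0
    v = np.full((n, 3), np.nan)
    v[1:-1, 0] = (xs[2:] - xs[:-2]) / (2 * dt_s)
    v[1:-1, 1] = (ys[2:] - ys[:-2]) / (2 * dt_s)
    v[:, 2] = np.hypot(v[:, 0], v[:, 1])
    return v


def robust_speed_threshold(v: np.ndarray, lam: float = 3.0) -> float:
    """median(speed) + lam * robust SD, components estimated Engbert-style."""
    ok = np.isfinite(v[:, 2])
    if not ok.any():
        raise ValueError("velocity series has no defined samples")
    vx, vy, sp = v[ok, 0], v[ok, 1], v[ok, 2]
    var = 0.0
    for comp in (vx, vy):
        var += max(np.median(comp ** 2) - np.median(comp) ** 2, 0.0)
    return float(np.median(sp) + lam * math.sqrt(var))


#: onset-refinement level as a fraction of the run's peak speed
ONSET_PEAK_FRACTION = 0.1


def detect_saccades(v: np.ndarray, trace: GazeTrace, lam: float = 3.0,
                    min_duration: float = 20.0) -> List[SaccadeEvent]:
    """Saccade events: maximal supra-threshold speed runs of >= min_duration ms.

    The statistical threshold sits far below peak speed, so on the heavily
    smoothed velocity its first crossing anticipates the physical onset by
    up to half the smoothing window.  The reported onset is therefore
    refined to the first run sample at 10% of the run's peak speed (or the
    threshold, whichever is higher), a percentage-of-peak criterion that
    tracks the event's own rising flank instead of the noise floor.  The
    offset stays at the threshold re-crossing (the run's last sample), so
    the end position is read after the eye has essentially settled.  Start
    and end positions come from the raw (unsmoothed) trace.
    """
    thr = robust_speed_threshold(v, lam)
    above = np.isfinite(v[:, 2]) & (v[:, 2] > thr)
    events: List[SaccadeEvent] = []
    min_samples = int(round(min_duration / SAMPLE_DT_MS))
    i, n = 0, len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if j - i + 1 >= min_samples:
                level = max(thr, ONSET_PEAK_FRACTION * float(np.max(v[i:j + 1, 2])))
                k = i + int(np.argmax(v[i:j + 1, 2] >= level))
                start = (float(trace.x[k]), float(trace.y[k]))
                end = (float(trace.x[j]), float(trace.y[j]))
                events.append(SaccadeEvent(
                    onset_t=float(trace.t[k]), offset_t=float(trace.t[j]),
                    start_pos=start, end_pos=end,
                    amplitude=math.hypot(end[0] - start[0], end[1] - start[1]),
                ))
            i = j + 1
        else:
            i += 1
    return events


def _dist(p, q) -> float:
    return math.hypot(p[0] - q[0], p[1] - q[1])


def validate_trial(trial: TrialRecord, trace: GazeTrace,
                   events: List[SaccadeEvent], layout: ScreenLayout) -> InclusionResult:
    """Apply the inclusion rules to one trial.

    The primary saccade is the first detected event starting inside the
    fixation gate after saccade-target onset.
    """
    reasons: List[str] = []
    ft = layout.fixation_pos
    st = layout.saccade_target_pos
    st_onset = trial.st_onset_ms

    primary = None
    for ev in events:
        if ev.onset_t >= st_onset and _dist(ev.start_pos, ft) <= GATE_RADIUS:
            primary = ev
            break
    if primary is None:
        reasons.append("NO_SACCADE")
        return InclusionResult(False, reasons)

    primary.latency = primary.onset_t - st_onset
    landing_error = _dist(primary.end_pos, st)

    # fixation must hold from trial start until the saccade leaves the gate
    pre = (trace.t < primary.onset_t) & trace.valid
    if pre.any():
        d = np.hypot(trace.x[pre] - ft[0], trace.y[pre] - ft[1])
        if (d > GATE_RADIUS).any():
            reasons.append("FIX_BREAK")
    if landing_error > GATE_RADIUS:
        reasons.append("BAD_LANDING")
    if primary.latency < MIN_LATENCY_MS:
        reasons.append("EARLY_SACCADE")
    if primary.offset_t - st_onset > MAX_OFFSET_MS:
        reasons.append("LATE_SACCADE")
    # blink anywhere from trial start to 100 ms past the saccade offset
    blink_win = trace.t <= primary.offset_t + 100.0
    if (~trace.valid[blink_win]).any():
        reasons.append("BLINK")
    # dt must extinguish in the DT_WINDOW before saccade onset
    dt_off_abs = st_onset + trial.dt_offset_ms
    gap = primary.onset_t - dt_off_abs
    if not (0.0 <= gap <= DT_WINDOW_MS):
        reasons.append("DT_OUT_OF_WINDOW")
    # a second large movement within the trial
    later = [ev for ev in events if ev is not primary and ev.amplitude >= GATE_RADIUS]
    if later:
        reasons.append("MULTI_SACCADE")

    return InclusionResult(not reasons, reasons, latency=primary.latency,
                           landing_error=landing_error, primary=primary)


def process_trial(trial: TrialRecord, trace: GazeTrace,
                  layout: ScreenLayout) -> InclusionResult:
    """Convenience: smooth, detect and validate one trial."""
    v = smooth_velocity(trace)
    events = detect_saccades(v, trace)
    return validate_trial(trial, trace, events, layout)


def saccade_metrics(trials: List[TrialRecord], results: List[InclusionResult],
                    layout: ScreenLayout) -> pd.DataFrame:
    """Per-trial latency/landing-error table with overlap and eccentricity labels.

    Only trials with a detected primary saccade contribute; the ``included``
    column carries the full inclusion verdict.
    """
    rows = []
    for t, r in zip(trials, results):
        if r.primary is None:
            continue
        rows.append({
            "trial_id": t.trial_id,
            "participant": t.participant,
            "condition": t.condition.value,
            "latency": r.latency,
            "landing_error": r.landing_error,
            "overlap": streams_overlap_targets(t.matrix_offset, layout),
            "ecc_group": eccentricity_group(t.dt_pos, layout.fixation_pos, strict=False),
            "included": r.included,
        })
    return pd.DataFrame(rows)


def inclusion_report(trials: List[TrialRecord],
                     results: List[InclusionResult]) -> pd.DataFrame:
    rows = [{
        "trial_id": t.trial_id,
        "participant": t.participant,
        "included": r.included,
        "reasons": ";".join(r.reasons),
        "latency": r.latency,
        "landing_error": r.landing_error,
    } for t, r in zip(trials, results)]
    return pd.DataFrame(rows)
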