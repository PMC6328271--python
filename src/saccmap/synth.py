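"""Synthetic sessions: trial schedules, 1-kHz gaze traces and observer responses.

The generator produces everything the analysis consumes, with the
statistical structure the protocol assumes:

* **Schedules** counterbalance conditions, saccade sides, cue sides and the
  15 stream-matrix placements; discrimination-target positions are drawn
  over the test grid with the protocol's 30% down-weighting of the rows
  most distant from the cue (cue trials) or of the peripheral rows
  (no-cue trials).  Tilt signs are counterbalanced per node.
* **Gaze traces** hold Gaussian fixation jitter, one visually guided
  12-dva saccade with a raised-cosine velocity profile and main-sequence
  duration, Gaussian landing scatter, and optional blink gaps.
* **Responses** come from an equal-variance signal-detection observer whose
  sensitivity is a spatial gain field: a baseline plus Gaussian attention
  loci.  At gain 1 and tilt at threshold the observer is exactly at the
  85% criterion, which fixes the reference sensitivity
  d'_ref = 2 * Phi^-1(0.85).

All randomness flows from one session seed through named substreams
(schedule, gaze, responses), so sessions are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import ndtr, ndtri

from .gaze import GazeTrace, SAMPLE_DT_MS
from .geometry import (MATRIX_OFFSETS, Position, ScreenLayout, TestGrid,
                       build_test_grid, default_layout, positions_of_interest)
from .records import Condition, DT_DURATION_MS, TrialRecord

#: reference sensitivity: d' of an unattended observer at threshold tilt,
#: fixed by P(correct) = Phi(d'/2) = 0.85
D_PRIME_REF = 2.0 * ndtri(0.85)

#: post-landing tail recorded after the saccade, ms
TRACE_TAIL_MS = 100.0
#: blink gap length, ms
BLINK_GAP_MS = 50.0


@dataclass
class SaccadeModel:
    """Kinematic and timing parameters of the synthetic oculomotor system.

    Latency means follow the observed overlap/non-overlap split (186 ms
    baseline, +31.56 ms when the stream matrix covers the targets); the
    main sequence (duration = intercept + slope * amplitude) uses standard
    values of 21 ms and 2.2 ms/dva.
    """

    latency_mean: float = 186.0            # ms
    latency_sd: float = 20.0               # ms
    overlap_latency_penalty: float = 31.56  # ms
    landing_sd: float = 0.5                # dva, isotropic
    fixation_jitter_sd: float = 0.05       # dva, per axis per sample
    main_sequence_slope: float = 2.2       # ms per dva
    main_sequence_intercept: float = 21.0  # ms
    blink_prob: float = 0.01

    def __post_init__(self):
        for name in ("latency_sd", "landing_sd", "fixation_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.blink_prob <= 1.0:
            raise ValueError("blink_prob must be a probability")

    def duration_ms(self, amplitude: float) -> float:
        return self.main_sequence_intercept + self.main_sequence_slope * amplitude


@dataclass(frozen=True)
class AttentionLocus:
    center: Position
    amplitude: float
    spatial_sd: float  # dva


@dataclass
class ObserverModel:
    """Spatial-attention signal-detection observer.

    The sensitivity gain at position p is
    baseline_gain + sum_i amplitude_i * exp(-|p - center_i|^2 / (2 sd_i^2)),
    required positive everywhere.  ``criterion`` is the response bias of the
    equal-variance decision rule; ``lapse_rate`` the stimulus-independent
    guessing probability.
    """

    baseline_gain: float = 1.0
    loci: Tuple[AttentionLocus, ...] = ()
    criterion: float = 0.0
    lapse_rate: float = 0.0

    def __post_init__(self):
        self.loci = tuple(self.loci)
        if not 0.0 <= self.lapse_rate < 0.5:
            raise ValueError("lapse_rate must lie in [0, 0.5)")
        neg = self.baseline_gain + sum(min(l.amplitude, 0.0) for l in self.loci)
        if neg <= 0:
            raise ValueError("gain field is not positive everywhere")

    def gain(self, p: Position) -> float:
        g = self.baseline_gain
        for l in self.loci:
            d2 = (p[0] - l.center[0]) ** 2 + (p[1] - l.center[1]) ** 2
            g += l.amplitude * math.exp(-d2 / (2.0 * l.spatial_sd ** 2))
        return g


@dataclass
class TrialSchedule:
    """Pre-response plan for one trial (a TrialRecord without outcome)."""

    trial_id: int
    participant: int
    condition: Condition
    saccade_side: str
    cue_side: str
    matrix_offset: Position
    dt_pos: Position
    dt_tilt: float
    dt_onset_ms: float       # after saccade-target onset; +25 ms on overlap trials
    fixation_period_ms: float


def default_observers(layout: Optional[ScreenLayout] = None,
                      spatial_sd: float = 0.9) -> Dict[Condition, ObserverModel]:
    """Condition-specific attention fields emulating pre-saccadic remapping.

    Without a cue, attention sits on the saccade target only.  With a late
    cue (SOA 50 ms) a second locus appears at the cue; with an early cue
    (SOA 200 ms) a third, weaker locus appears at the cue's remapped
    location.  Amplitudes (st 1.0 > cue 0.9 > remap 0.8) preserve the
    observed ordering of sensitivity peaks and were sized at design time so
    that an 8-participant study resolves each locus against its surround.
    """
    poi = positions_of_interest(layout or default_layout("right", "up"))
    st = AttentionLocus(poi.st, 1.0, spatial_sd)
    cue = AttentionLocus(poi.cue, 0.9, spatial_sd)
    remap = AttentionLocus(poi.remap, 0.8, spatial_sd)
    return {
        Condition.NO_CUE: ObserverModel(loci=(st,)),
        Condition.CUE_SOA50: ObserverModel(loci=(st, cue)),
        Condition.CUE_SOA200: ObserverModel(loci=(st, cue, remap)),
    }


#: true tilt-threshold profile of the synthetic observer, deg vs dva.
#: Anchored at the reported foveal (4.42 deg) and outermost (14.10 deg at
#: ~15.75 dva) thresholds, linear in between.
TRUE_THRESHOLD_INTERCEPT = 4.42
TRUE_THRESHOLD_SLOPE = (14.10 - 4.42) / 15.75


def true_threshold_profile(eccentricity) -> np.ndarray:
    """Tilt (deg) an unattended observer needs for 85% correct at a given
    eccentricity (dva) from the fixation target."""
    return TRUE_THRESHOLD_INTERCEPT + TRUE_THRESHOLD_SLOPE * np.asarray(eccentricity, float)


def true_dprime(observer: ObserverModel, p: Position, tilt_magnitude: float,
                threshold_tilt_at_p: float) -> float:
    """Observer sensitivity at position p for a given shown tilt.

    d' scales linearly with tilt relative to the local threshold tilt and
    with the spatial gain; at gain 1 and tilt at threshold, the response
    rule yields exactly the 85% criterion.
    """
    if threshold_tilt_at_p <= 0:
        raise ValueError("threshold tilt must be positive")
    return observer.gain(p) * D_PRIME_REF * (tilt_magnitude / threshold_tilt_at_p)


def response_probability_cw(observer: ObserverModel, d_true: float,
                            tilt_sign: str) -> float:
    """P(report clockwise) under the equal-variance decision rule."""
    mean = d_true / 2.0 if tilt_sign == "cw" else -d_true / 2.0
    return ((1.0 - observer.lapse_rate) * ndtr(mean - observer.criterion)
            + observer.lapse_rate / 2.0)


def simulate_response(observer: ObserverModel, d_true: float, tilt_sign: str,
                      rng: np.random.Generator) -> str:
    p_cw = response_probability_cw(observer, d_true, tilt_sign)
    return "cw" if rng.random() < p_cw else "ccw"


def _node_weights(grid: TestGrid, cue_side: str, weighting: bool) -> np.ndarray:
    """Sampling weights over grid nodes with the 30% down-weighting rule."""
    arr = grid.as_array()
    w = np.ones(len(arr))
    if weighting:
        if cue_side == "up":
            w[arr[:, 1] <= -6.0] = 0.7     # two rows most distant from the cue
        elif cue_side == "down":
            w[arr[:, 1] >= 6.0] = 0.7
        else:
            w[np.abs(arr[:, 1]) >= 6.0] = 0.7  # two top and two bottom rows
    return w / w.sum()


def _mirror_to_actual(p: Position, saccade_side: str, cue_side: str) -> Position:
    """Map a canonical-frame position into the trial's actual frame."""
    x, y = p
    if saccade_side == "left":
        x = -x
    if cue_side == "down":
        y = -y
    return (x, y)


def generate_schedule(n_trials: int,
                      condition_mix: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
                      weighting: bool = True,
                      rng: Optional[np.random.Generator] = None,
                      participant: int = 0,
                      grid: Optional[TestGrid] = None,
                      tilt_for_node: Optional[Callable] = None) -> List[TrialSchedule]:
    """Draw a counterbalanced trial schedule.

    ``condition_mix`` orders (NO_CUE, CUE_SOA50, CUE_SOA200).
    ``tilt_for_node`` maps a canonical-frame node to the tilt magnitude to
    show there (defaults to the generator's true threshold profile, i.e.
    an eccentricity-matched design).
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    mix = np.asarray(condition_mix, float)
    if mix.shape != (3,) or not math.isclose(mix.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("condition_mix must be 3 proportions summing to 1")
    rng = rng if rng is not None else np.random.default_rng()
    grid = grid or build_test_grid()
    layout = default_layout("right", "up")
    ft = layout.fixation_pos
    if tilt_for_node is None:
        def tilt_for_node(p):
            return float(true_threshold_profile(math.hypot(p[0] - ft[0], p[1] - ft[1])))

    arr = grid.as_array()
    conditions = [Condition.NO_CUE, Condition.CUE_SOA50, Condition.CUE_SOA200]
    cond_draw = rng.choice(3, size=n_trials, p=mix)
    sides = rng.choice(["left", "right"], size=n_trials)
    cue_sides = rng.choice(["up", "down"], size=n_trials)
    # counterbalance the 15 placements: shuffled cycles
    offsets = []
    while len(offsets) < n_trials:
        block = list(MATRIX_OFFSETS)
        rng.shuffle(block)
        offsets.extend(block)
    fix_periods = rng.choice(np.arange(500.0, 901.0, 50.0), size=n_trials)
    dt_onsets = rng.uniform(50.0, 175.0, size=n_trials)

    sign_counter: Dict[Position, int] = {}
    schedules = []
    for i in range(n_trials):
        cond = conditions[cond_draw[i]]
        cue_side = "none" if cond is Condition.NO_CUE else str(cue_sides[i])
        w = _node_weights(grid, "up" if cue_side != "none" else "none", weighting)
        node = tuple(map(float, arr[rng.choice(len(arr), p=w)]))
        # tilt sign counterbalanced per node and condition
        key = (node, cond)
        c = sign_counter.get(key, rng.integers(0, 2))
        sign_counter[key] = c + 1
        sign = 1.0 if c % 2 == 0 else -1.0
        offset = offsets[i]
        dt_onset = float(dt_onsets[i])
        from .geometry import streams_overlap_targets
        if streams_overlap_targets(offset, layout):
            dt_onset += 25.0  # compensation for slower overlap-trial saccades
        schedules.append(TrialSchedule(
            trial_id=i, participant=participant, condition=cond,
            saccade_side=str(sides[i]), cue_side=cue_side,
            matrix_offset=offset,
            dt_pos=_mirror_to_actual(node, str(sides[i]), cue_side),
            dt_tilt=sign * tilt_for_node(node),
            dt_onset_ms=dt_onset, fixation_period_ms=float(fix_periods[i]),
        ))
    return schedules


def simulate_gaze_trace(s: TrialSchedule, m: SaccadeModel,
                        rng: np.random.Generator,
                        layout: Optional[ScreenLayout] = None,
                        ) -> Tuple[GazeTrace, dict]:
    """One 1-kHz gaze trace plus its ground truth (onset, latency, landing).

    Fixation jitter around the fixation target, a raised-cosine saccade at
    saccade-target onset + latency (with the overlap penalty when the
    stream matrix covers the targets), Gaussian landing error, then a
    recorded tail.  A blink, when drawn, invalidates a 50-ms gap at a
    uniformly random time.
    """
    from .geometry import streams_overlap_targets
    layout = layout or default_layout(s.saccade_side,
                                      s.cue_side if s.cue_side != "none" else "none")
    ft = np.asarray(layout.fixation_pos)
    st = np.asarray(layout.saccade_target_pos)
    amp = float(np.hypot(*(st - ft)))

    mean = m.latency_mean
    if streams_overlap_targets(s.matrix_offset, layout):
        mean += m.overlap_latency_penalty
    latency = max(mean + m.latency_sd * rng.standard_normal(), 1.0)
    onset = s.fixation_period_ms + latency
    duration = m.duration_ms(amp)
    n = int(math.ceil(onset + duration + TRACE_TAIL_MS))
    t = np.arange(n, dtype=float) * SAMPLE_DT_MS

    landing = st + m.landing_sd * rng.standard_normal(2)
    # raised-cosine velocity => displacement profile phi - sin(2 pi phi)/(2 pi)
    phase = np.clip((t - onset) / duration, 0.0, 1.0)
    prog = phase - np.sin(2.0 * np.pi * phase) / (2.0 * np.pi)
    pos = ft[None, :] + prog[:, None] * (landing - ft)[None, :]
    if m.fixation_jitter_sd > 0:
        pos = pos + m.fixation_jitter_sd * rng.standard_normal(pos.shape)

    valid = np.ones(n, dtype=bool)
    if m.blink_prob > 0 and rng.random() < m.blink_prob:
        gap = int(BLINK_GAP_MS / SAMPLE_DT_MS)
        start = int(rng.integers(0, max(n - gap, 1)))
        valid[start:start + gap] = False
        pos[start:start + gap] = np.nan

    trace = GazeTrace(t=t, x=pos[:, 0], y=pos[:, 1], valid=valid)
    truth = {"onset_ms": onset, "latency_ms": latency,
             "landing": (float(landing[0]), float(landing[1])),
             "duration_ms": duration}
    return trace, truth


def schedule_to_record(s: TrialSchedule, truth: Optional[dict] = None,
                       response: str = "") -> TrialRecord:
    return TrialRecord(
        trial_id=s.trial_id, participant=s.participant, condition=s.condition,
        saccade_side=s.saccade_side, cue_side=s.cue_side,
        matrix_offset=s.matrix_offset, dt_pos=s.dt_pos, dt_tilt=s.dt_tilt,
        dt_onset_ms=s.dt_onset_ms, fixation_period_ms=s.fixation_period_ms,
        response=response,
        true_saccade_onset_ms=None if truth is None else truth["onset_ms"],
        true_saccade_latency_ms=None if truth is None else truth["latency_ms"],
        true_landing_pos=None if truth is None else truth["landing"],
    )


def session_substreams(seed: int) -> Dict[str, np.random.Generator]:
    """Named substreams (schedule, gaze, responses) from one session seed."""
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(3)
    return {name: np.random.default_rng(k)
            for name, k in zip(("schedule", "gaze", "responses"), kids)}


def simulate_trial_response(s: TrialSchedule, observers: Dict[Condition, ObserverModel],
                            rng: np.random.Generator,
                            threshold_true: Optional[Callable] = None) -> str:
    """Draw the binary orientation report for one scheduled trial.

    The attention field is anchored to the trial's layout, so the shown
    position is mapped back to the canonical frame before the gain lookup.
    """
    node = _mirror_to_actual(s.dt_pos, s.saccade_side, s.cue_side)  # involution
    ft = default_layout("right", "up").fixation_pos
    ecc = math.hypot(node[0] - ft[0], node[1] - ft[1])
    thr = (true_threshold_profile(ecc) if threshold_true is None
           else threshold_true(ecc))
    obs = observers[s.condition]
    d = true_dprime(obs, node, abs(s.dt_tilt), float(thr))
    sign = "cw" if s.dt_tilt > 0 else "ccw"
    return simulate_response(obs, d, sign, rng)


def expected_inclusion_rate(schedules: Sequence[TrialSchedule], m: SaccadeModel,
                            rng: np.random.Generator, n_mc: int = 20000) -> float:
    """Design-level inclusion rate, independent of trace synthesis/detection.

    Monte-Carlo over the generative timing rules only: latency draw, the
    dt-offset window, the 25/350-ms latency bounds, landing scatter against
    the 2.0-dva gate and the blink gap.  Serves as an oracle for what
    fraction of generated trials the analysis should accept.
    """
    from .gaze import DT_WINDOW_MS, GATE_RADIUS, MAX_OFFSET_MS, MIN_LATENCY_MS
    layout = default_layout("right", "up")
    from .geometry import streams_overlap_targets
    idx = rng.integers(0, len(schedules), size=n_mc)
    ok = 0
    for i in idx:
        s = schedules[i]
        mean = m.latency_mean
        if streams_overlap_targets(s.matrix_offset, layout):
            mean += m.overlap_latency_penalty
        lat = mean + m.latency_sd * rng.standard_normal()
        dur = m.duration_ms(12.0)
        if lat < MIN_LATENCY_MS or lat + dur > MAX_OFFSET_MS:
            continue
        gap = lat - (s.dt_onset_ms + DT_DURATION_MS)
        if not (0.0 <= gap <= DT_WINDOW_MS):
            continue
        land = m.landing_sd * rng.standard_normal(2)
        if np.hypot(*land) > GATE_RADIUS:
            continue
        if rng.random() < m.blink_prob:
            n_tr = s.fixation_period_ms + lat + dur + TRACE_TAIL_MS
            start = rng.uniform(0.0, n_tr - BLINK_GAP_MS)
            if start <= s.fixation_period_ms + lat + dur + 100.0:
                continue
        ok += 1
    return ok / n_mc


@dataclass
class SyntheticSession:
    trials: List[TrialRecord]
    traces: List[GazeTrace]
    seed: int


def simulate_session(participant: int, n_trials: int, seed: int,
                     observers: Optional[Dict[Condition, ObserverModel]] = None,
                     saccade_model: Optional[SaccadeModel] = None,
                     condition_mix: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
                     tilt_for_node: Optional[Callable] = None,
                     keep_traces: bool = True) -> SyntheticSession:
    """Full synthetic session: schedule, traces and responses for one participant."""
    streams = session_substreams(seed)
    observers = observers or default_observers()
    m = saccade_model or SaccadeModel()
    schedules = generate_schedule(n_trials, condition_mix=condition_mix,
                                  rng=streams["schedule"], participant=participant,
                                  tilt_for_node=tilt_for_node)
    trials, traces = [], []
    for s in schedules:
        trace, truth = simulate_gaze_trace(s, m, streams["gaze"])
        resp = simulate_trial_response(s, observers, streams["responses"])
        trials.append(schedule_to_record(s, truth, resp))
        if keep_traces:
            traces.append(trace)
    return SyntheticSession(trials=trials, traces=traces, seed=seed)
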