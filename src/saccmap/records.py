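"""Shared trial-level record types.

Positions are screen-centered Cartesian coordinates in degrees of visual
angle (dva): +x rightward, +y upward.  Times are milliseconds from trial
onset unless a field name says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional

import pandas as pd

TRIAL_LOG_VERSION = "saccmap-trials-v1"

#: duration of the discrimination-target presentation (one 40-Hz halfcycle), ms
DT_DURATION_MS = 25.0
#: duration of the cue flash, ms
CUE_DURATION_MS = 50.0


class Condition(str, Enum):
    """Cue-timing condition of a trial.

    ``CUE_SOA50``/``CUE_SOA200``: a task-irrelevant cue precedes the
    discrimination target by 50 or 200 ms.  ``NO_CUE``: no cue is shown.
    """

    NO_CUE = "NO_CUE"
    CUE_SOA50 = "CUE_SOA50"
    CUE_SOA200 = "CUE_SOA200"

    @property
    def soa_ms(self) -> Optional[float]:
        return {"NO_CUE": None, "CUE_SOA50": 50.0, "CUE_SOA200": 200.0}[self.value]


@dataclass
class TrialRecord:
    """One trial: schedule, stimulus placement, events and response.

    ``dt_onset_ms`` is relative to saccade-target onset; the absolute
    saccade-target onset equals ``fixation_period_ms``.  Ground-truth gaze
    fields (``true_*``) are filled by the synthetic generator and are never
    consulted by the analysis; they exist so detector tests have an oracle.
    """

    trial_id: int
    participant: int
    condition: Condition
    saccade_side: str               # 'left' | 'right'
    cue_side: str                   # 'up' | 'down' | 'none'
    matrix_offset: tuple            # (dx, dy) of the 3x4 stream matrix, dva
    dt_pos: tuple                   # discrimination-target position, dva
    dt_tilt: float                  # signed tilt, deg (sign = cw/ccw)
    dt_onset_ms: float              # after saccade-target onset
    fixation_period_ms: float
    response: str = ""              # 'cw' | 'ccw'
    # ground truth from the generator (oracle only)
    true_saccade_onset_ms: Optional[float] = None   # absolute, from trial start
    true_saccade_latency_ms: Optional[float] = None
    true_landing_pos: Optional[tuple] = None

    @property
    def tilt_sign(self) -> str:
        return "cw" if self.dt_tilt > 0 else "ccw"

    @property
    def st_onset_ms(self) -> float:
        """Absolute saccade-target onset (= end of the fixation period)."""
        return self.fixation_period_ms

    @property
    def dt_offset_ms(self) -> float:
        """dt offset relative to saccade-target onset."""
        return self.dt_onset_ms + DT_DURATION_MS

    @property
    def cue_onset_ms(self) -> Optional[float]:
        """Cue onset relative to saccade-target onset (None on no-cue trials)."""
        soa = self.condition.soa_ms
        return None if soa is None else self.dt_onset_ms - soa

    @property
    def cue_offset_ms(self) -> Optional[float]:
        on = self.cue_onset_ms
        return None if on is None else on + CUE_DURATION_MS

    def replaced(self, **kw) -> "TrialRecord":
        return replace(self, **kw)


_DF_COLUMNS = [
    "trial_id", "participant", "condition", "saccade_side", "cue_side",
    "matrix_dx", "matrix_dy", "dt_x", "dt_y", "dt_tilt", "dt_onset_ms",
    "fixation_period_ms", "response",
    "true_saccade_onset_ms", "true_saccade_latency_ms",
    "true_landing_x", "true_landing_y",
]


def trials_to_frame(trials: list) -> pd.DataFrame:
    """Flatten TrialRecords into a DataFrame (tuple fields split into columns)."""
    rows = []
    for t in trials:
        lx, ly = t.true_landing_pos if t.true_landing_pos is not None else (None, None)
        rows.append((
            t.trial_id, t.participant, t.condition.value, t.saccade_side,
            t.cue_side, t.matrix_offset[0], t.matrix_offset[1],
            t.dt_pos[0], t.dt_pos[1], t.dt_tilt, t.dt_onset_ms,
            t.fixation_period_ms, t.response,
            t.true_saccade_onset_ms, t.true_saccade_latency_ms, lx, ly,
        ))
    return pd.DataFrame(rows, columns=_DF_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list:
    trials = []
    for r in df.itertuples(index=False):
        landing = None
        if r.true_landing_x is not None and not pd.isna(r.true_landing_x):
            landing = (float(r.true_landing_x), float(r.true_landing_y))
        trials.append(TrialRecord(
            trial_id=int(r.trial_id), participant=int(r.participant),
            condition=Condition(r.condition), saccade_side=r.saccade_side,
            cue_side=r.cue_side, matrix_offset=(float(r.matrix_dx), float(r.matrix_dy)),
            dt_pos=(float(r.dt_x), float(r.dt_y)), dt_tilt=float(r.dt_tilt),
            dt_onset_ms=float(r.dt_onset_ms),
            fixation_period_ms=float(r.fixation_period_ms),
            response=r.response if isinstance(r.response, str) else "",
            true_saccade_onset_ms=None if pd.isna(r.true_saccade_onset_ms) else float(r.true_saccade_onset_ms),
            true_saccade_latency_ms=None if pd.isna(r.true_saccade_latency_ms) else float(r.true_saccade_latency_ms),
            true_landing_pos=landing,
        ))
    return trials
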