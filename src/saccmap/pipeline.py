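"""End-to-end orchestration: threshold stage, main stage, reports.

The canned reproduce-on-synthetic experiment runs the whole protocol on
generated data: a constant-stimuli threshold stage fixes the tilt shown at
each eccentricity, the main stage simulates saccade trials, detects and
validates eye movements, tabulates d' per node and condition, builds the
normalized attention maps, and runs the bootstrap comparisons at the
positions of interest plus the latency/accuracy ANOVAs.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtri
from scipy.stats import norm

from . import gaze as gz
from . import io as sio
from . import mapping, sensitivity, stats
from .geometry import (TestGrid, build_test_grid, default_layout,
                       eccentricity_group, group_eccentricities,
                       positions_of_interest, streams_overlap_targets)
from .psychometrics import (ConstantStimuliBlock, fit_cumulative_gaussian,
                            psychometric_function, threshold_profile,
                            tilt_intervals)
from .records import Condition
from .synth import (AttentionLocus, D_PRIME_REF, ObserverModel, SaccadeModel,
                    default_observers, generate_schedule, schedule_to_record,
                    session_substreams, simulate_gaze_trace,
                    simulate_trial_response, true_threshold_profile)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a synthetic reproduce run."""

    task: str = "peripheral"              # 'peripheral' | 'foveal'
    participants: int = 8
    trials_per_participant: int = 1500
    threshold_trials: int = 400
    seed: int = 0
    condition_mix: Tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    bootstrap_B: int = 10000
    criterion: float = 0.85
    upsample_factor: int = 8
    min_inclusion: float = 0.5
    outdir: Optional[str] = None

    def __post_init__(self):
        if self.task not in ("peripheral", "foveal"):
            raise ValueError("task must be 'peripheral' or 'foveal'")
        if not math.isclose(sum(self.condition_mix), 1.0, abs_tol=1e-9):
            raise ValueError("condition_mix must sum to 1")
        if self.task == "foveal":
            # the foveal variant never shows the cue
            self.condition_mix = (1.0, 0.0, 0.0)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "condition_mix" in data:
            data["condition_mix"] = tuple(data["condition_mix"])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _derived_seed(root: int, *key: int) -> int:
    """Deterministic child seed below 2**31."""
    return int(np.random.SeedSequence([root, *key]).generate_state(1)[0] & 0x7FFFFFFF)


def threshold_task_observer(task: str) -> ObserverModel:
    """Observer driving the threshold stage.

    The peripheral variant measures thresholds during fixation with the
    target always cued, so the gain field is flat.  The foveal variant
    measures during saccade preparation, which draws attention away from
    the fixation target: a negative locus at ft lowers foveal gain,
    raising the measured foveal threshold.
    """
    if task == "peripheral":
        return ObserverModel()
    ft = default_layout("right", "up").fixation_pos
    return ObserverModel(loci=(AttentionLocus(ft, -0.7, 2.0),))


def run_threshold_stage(cfg: RunConfig,
                        grid: Optional[TestGrid] = None) -> pd.DataFrame:
    """Simulate and fit the constant-stimuli threshold blocks.

    Returns one row per participant x eccentricity group with the fitted
    cumulative-Gaussian parameters and the criterion threshold.  Aborts if
    more than two groups of any participant yield unstable fits.
    """
    grid = grid or build_test_grid()
    layout = default_layout("right", "up")
    ft = layout.fixation_pos
    observer = threshold_task_observer(cfg.task)
    eccs = group_eccentricities(grid, ft)
    nodes_by_group: Dict[int, list] = {g: [] for g in range(1, 6)}
    for p in grid.nodes:
        nodes_by_group[eccentricity_group(p, ft, strict=False)].append(p)

    per_group = cfg.threshold_trials // 5
    rows = []
    for pp in range(cfg.participants):
        rng = np.random.default_rng(_derived_seed(cfg.seed, 1, pp))
        unstable = 0
        for g in range(1, 6):
            tilts = tilt_intervals(g, cfg.task)
            n_level = np.full(5, per_group // 5, int)
            n_level[: per_group % 5] += 1
            k_level = np.zeros(5, int)
            for li, (tilt, n) in enumerate(zip(tilts, n_level)):
                nodes = nodes_by_group[g]
                for tr in range(n):
                    node = nodes[int(rng.integers(0, len(nodes)))]
                    ecc = math.hypot(node[0] - ft[0], node[1] - ft[1])
                    d = observer.gain(node) * D_PRIME_REF * tilt / float(
                        true_threshold_profile(ecc))
                    if rng.random() < norm.cdf(d / 2.0):
                        k_level[li] += 1
            fit = fit_cumulative_gaussian(
                ConstantStimuliBlock(g, tilts, n_level, k_level),
                criterion=cfg.criterion)
            unstable += not fit.stable
            rows.append({"participant": pp, "group": g,
                         "eccentricity": float(eccs[g - 1]), "mu": fit.mu,
                         "sigma": fit.sigma, "threshold": fit.threshold,
                         "stable": fit.stable})
        if unstable > 2:
            raise RuntimeError(
                f"participant {pp}: {unstable} of 5 threshold fits unstable; "
                "aborting (report: " + repr(rows[-5:]) + ")")
    return pd.DataFrame(rows)


def _tilt_function(thresholds: pd.DataFrame, participant: int) -> Callable:
    sub = thresholds[thresholds["participant"] == participant].sort_values("group")
    profile = threshold_profile(sub["threshold"].to_numpy(),
                                sub["eccentricity"].to_numpy())
    ft = default_layout("right", "up").fixation_pos

    def tilt_for_node(p):
        return float(profile(math.hypot(p[0] - ft[0], p[1] - ft[1])))

    return tilt_for_node


def simulate_and_process_participant(cfg: RunConfig, participant: int,
                                     tilt_for_node: Optional[Callable] = None,
                                     observers=None,
                                     saccade_model: Optional[SaccadeModel] = None,
                                     ) -> pd.DataFrame:
    """Generate one participant's session and run gaze validation trial by
    trial (traces are processed streaming and discarded)."""
    m = saccade_model or SaccadeModel()
    observers = observers or default_observers()
    streams = session_substreams(_derived_seed(cfg.seed, 2, participant))
    schedules = generate_schedule(
        cfg.trials_per_participant, condition_mix=cfg.condition_mix,
        rng=streams["schedule"], participant=participant,
        tilt_for_node=tilt_for_node)
    layout_cache: Dict[Tuple[str, str], object] = {}
    canonical = default_layout("right", "up")
    ft = canonical.fixation_pos
    rows = []
    for s in schedules:
        key = (s.saccade_side, s.cue_side if s.cue_side != "none" else "none")
        layout = layout_cache.get(key)
        if layout is None:
            layout = default_layout(s.saccade_side, key[1])
            layout_cache[key] = layout
        trace, truth = simulate_gaze_trace(s, m, streams["gaze"], layout)
        resp = simulate_trial_response(s, observers, streams["responses"])
        trial = schedule_to_record(s, truth, resp)
        res = gz.process_trial(trial, trace, layout)
        mirrored = _canonical_dt(s.dt_pos, s.saccade_side, s.cue_side)
        rows.append({
            "trial_id": s.trial_id, "participant": participant,
            "condition": s.condition.value, "saccade_side": s.saccade_side,
            "cue_side": s.cue_side, "dt_x": mirrored[0], "dt_y": mirrored[1],
            "dt_tilt": s.dt_tilt, "dt_onset_ms": s.dt_onset_ms,
            "response": resp, "included": res.included,
            "reasons": ";".join(res.reasons), "latency": res.latency,
            "landing_error": res.landing_error,
            "overlap": streams_overlap_targets(s.matrix_offset, layout),
            "ecc_group": eccentricity_group(mirrored, ft, strict=False),
        })
    return pd.DataFrame(rows)


def _canonical_dt(p, saccade_side: str, cue_side: str):
    x, y = p
    if saccade_side == "left":
        x = -x
    if cue_side == "down":
        y = -y
    return (x, y)


def _filled_table(table: pd.DataFrame, grid: TestGrid) -> pd.DataFrame:
    """Replace NaN normalized d' at under-sampled nodes by their
    natural-neighbor interpolation, per participant."""
    out = table.copy()
    arr = grid.as_array()
    for pp, sub in out.groupby("participant"):
        if sub["excluded"].any() or sub["dprime_norm"].notna().sum() < 3:
            continue
        vals = {(r.x, r.y): r.dprime_norm for r in sub.itertuples()}
        if not any(np.isnan(v) for v in vals.values()):
            continue
        coarse = mapping.natural_neighbor_fill(vals)
        for i in sub.index[sub["dprime_norm"].isna()]:
            x, y = out.at[i, "x"], out.at[i, "y"]
            iy = int(round((y + 9.0) / 3.0))
            ix = int(round((x + 12.0) / 3.0))
            out.at[i, "dprime_norm"] = coarse[iy, ix]
    return out


def run_main_stage(cfg: RunConfig, thresholds: Optional[pd.DataFrame] = None,
                   observers=None, saccade_model: Optional[SaccadeModel] = None,
                   ) -> dict:
    """Full main-task analysis on synthetic sessions.

    Returns a dict with the trial table, per-condition sensitivity tables,
    group attention maps, subtraction maps, the bootstrap report and the
    latency/accuracy ANOVAs, plus a manifest of every seed and parameter.
    """
    grid = build_test_grid()
    layout = default_layout("right", "up")
    poi = positions_of_interest(layout)

    frames = []
    for pp in range(cfg.participants):
        tilt_fn = (None if thresholds is None else _tilt_function(thresholds, pp))
        frames.append(simulate_and_process_participant(
            cfg, pp, tilt_for_node=tilt_fn, observers=observers,
            saccade_model=saccade_model))
    trials = pd.concat(frames, ignore_index=True)

    frac = trials["included"].mean()
    if frac < cfg.min_inclusion:
        hist = trials.loc[~trials["included"], "reasons"].str.split(";").explode()
        raise RuntimeError(
            f"only {frac:.1%} of trials survived inclusion (need "
            f">={cfg.min_inclusion:.0%}); exclusion histogram:\n"
            f"{hist.value_counts().to_string()}")
    logger.info("inclusion: %.2f%% of %d trials", 100 * frac, len(trials))

    included = trials[trials["included"]].reset_index(drop=True)
    included = sensitivity.split_conditions(included)

    conditions = [c.value for c in Condition if (included["condition"] == c.value).any()]
    tables, maps, filled = {}, {}, {}
    for cond in conditions:
        tbl = sensitivity.sensitivity_table(
            included[included["condition"] == cond], grid)
        tables[cond] = tbl
        filled[cond] = _filled_table(tbl, grid)
        per_maps = []
        for pp, sub in filled[cond].groupby("participant"):
            if sub["excluded"].any() or sub["dprime_norm"].notna().sum() < 3:
                continue
            vals = {(r.x, r.y): r.dprime_norm for r in sub.itertuples()}
            per_maps.append(mapping.build_attention_map(
                vals, factor=cfg.upsample_factor,
                provenance={"participant": pp, "condition": cond}))
        if per_maps:
            maps[cond] = mapping.group_average(per_maps)
        else:
            logger.warning("condition %s: no participant produced a usable "
                           "map (too few trials per node)", cond)

    # subtraction maps (cue condition minus no cue), re-normalized
    subtraction = {}
    if Condition.NO_CUE.value in tables:
        for cond in (Condition.CUE_SOA50.value, Condition.CUE_SOA200.value):
            if cond not in tables:
                continue
            diff = sensitivity.subtraction_table(tables[cond],
                                                 tables[Condition.NO_CUE.value])
            per_maps = []
            for pp, sub in diff.groupby("participant"):
                if sub["excluded"].any() or sub["diff_norm"].isna().any():
                    continue
                vals = {(r.x, r.y): r.diff_norm for r in sub.itertuples()}
                per_maps.append(mapping.build_attention_map(
                    vals, factor=cfg.upsample_factor))
            if per_maps:
                subtraction[cond] = mapping.group_average(per_maps)

    # bootstrap comparisons at the positions of interest
    poi_sets = {
        Condition.NO_CUE.value: {"ft": poi.ft, "st": poi.st},
        Condition.CUE_SOA50.value: poi.as_dict(),
        Condition.CUE_SOA200.value: poi.as_dict(),
    }
    report = []
    j = 0
    for cond in conditions:
        for name, pos in poi_sets[cond].items():
            for kind, fn in (("vs_rest", stats.poi_vs_rest),
                             ("vs_surround", None)):
                j += 1
                seed = _derived_seed(cfg.seed, 3, j)
                label = f"{cond}:{name}:{kind}"
                if kind == "vs_rest":
                    r = stats.poi_vs_rest(filled[cond], pos, B=cfg.bootstrap_B,
                                          seed=seed, name=label)
                else:
                    r = stats.poi_vs_surround(filled[cond], pos, grid,
                                              B=cfg.bootstrap_B, seed=seed,
                                              name=label)
                report.append({"comparison": label, "condition": cond,
                               "poi": name, "kind": kind,
                               "estimate": r.observed_diff,
                               "p": r.p_two_tailed, "B": r.n_resamples,
                               "seed": r.seed})

    anovas = _saccade_metric_anovas(trials)

    manifest = {"config": cfg.to_dict(),
                "inclusion_fraction": float(frac),
                "n_trials": int(len(trials)),
                "grid_nodes": len(grid.nodes),
                "seeds": {"sessions": [_derived_seed(cfg.seed, 2, pp)
                                       for pp in range(cfg.participants)]}}

    result = {"trials": trials, "tables": tables, "maps": maps,
              "subtraction_maps": subtraction, "report": pd.DataFrame(report),
              "anovas": anovas, "manifest": manifest}
    if cfg.outdir:
        _write_outputs(cfg, result, thresholds)
    return result


def _saccade_metric_anovas(trials: pd.DataFrame) -> dict:
    """Latency ANOVA over eccentricity groups 2-5 split by stream overlap;
    landing-accuracy ANOVA over all five groups."""
    ok = trials[trials["included"]]
    out = {}
    for overlap in (True, False):
        sub = ok[(ok["overlap"] == overlap) & (ok["ecc_group"] >= 2)]
        mat = sub.pivot_table(index="participant", columns="ecc_group",
                              values="latency", aggfunc="mean")
        if mat.isna().any().any() or mat.shape[1] < 2:
            logger.warning("latency ANOVA (overlap=%s): incomplete cells, skipped",
                           overlap)
            continue
        out[f"latency_overlap_{overlap}"] = stats.rm_anova(mat.to_numpy())
    mat = ok.pivot_table(index="participant", columns="ecc_group",
                         values="landing_error", aggfunc="mean")
    if not mat.isna().any().any() and mat.shape[1] >= 2:
        out["accuracy"] = stats.rm_anova(mat.to_numpy())
    return out


def _write_outputs(cfg: RunConfig, result: dict, thresholds) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    result["trials"].to_csv(out / "trials.csv", index=False)
    for cond, tbl in result["tables"].items():
        tbl.to_csv(out / f"sensitivity_{cond}.csv", index=False)
    for cond, amap in result["maps"].items():
        mapping.save_map_tsv(out / f"map_{cond}.tsv", amap)
        mapping.save_map_tsv(out / f"map_{cond}_fine.tsv", amap, which="fine")
    for cond, amap in result["subtraction_maps"].items():
        mapping.save_map_tsv(out / f"subtraction_{cond}.tsv", amap)
    result["report"].to_csv(out / "stats_report.csv", index=False)
    sio.write_manifest(out / "manifest.json", result["manifest"])
    if thresholds is not None:
        thresholds.to_csv(out / "thresholds.csv", index=False)
    anova_rows = [{"effect": k, **dataclasses.asdict(v),
                   "eta_p_sq_percent": v.eta_p_sq_percent}
                  for k, v in result["anovas"].items()]
    pd.DataFrame(anova_rows).to_csv(out / "anovas.csv", index=False)


def run_full(cfg: RunConfig) -> dict:
    thresholds = run_threshold_stage(cfg)
    result = run_main_stage(cfg, thresholds)
    result["thresholds"] = thresholds
    return result


# ---------------------------------------------------------------------------
# canned self-contained experiments

def threshold_criterion_recovery(n_sessions: int = 100, seed: int = 0,
                                 trials_per_session: int = 400,
                                 task: str = "peripheral",
                                 criterion: float = 0.85) -> float:
    """Mean percent correct of the generating psychometric function at the
    extracted threshold, over seeded constant-stimuli sessions.

    Each session presents 5 tilt magnitudes per eccentricity group
    (trials_per_session split evenly over the five groups); responses come
    from a known cumulative Gaussian whose criterion point sits at the
    task's true threshold for that eccentricity; the fitted threshold is
    then plugged back into the generating function.
    """
    grid = build_test_grid()
    ft = default_layout("right", "up").fixation_pos
    eccs = group_eccentricities(grid, ft)
    zc = ndtri(2.0 * criterion - 1.0)
    per_group = trials_per_session // 5
    values = []
    for s in range(n_sessions):
        rng = np.random.default_rng(_derived_seed(seed, 4, s))
        for g in range(1, 6):
            theta85 = float(true_threshold_profile(eccs[g - 1]))
            mu = 0.7 * theta85
            sig = 0.3 * theta85 / zc
            tilts = tilt_intervals(g, task)
            n_level = np.full(5, per_group // 5, int)
            n_level[: per_group % 5] += 1
            p_true = psychometric_function(tilts, mu, sig)
            k_level = rng.binomial(n_level, p_true)
            fit = fit_cumulative_gaussian(
                ConstantStimuliBlock(g, tilts, n_level, k_level),
                criterion=criterion)
            values.append(float(psychometric_function(fit.threshold, mu, sig)))
    return 100.0 * float(np.mean(values))


def locus_recovery_runs(n_runs: int = 20, participants: int = 8,
                        trials_per_participant: int = 1500, seed: int = 0,
                        B: int = 10000) -> pd.DataFrame:
    """Replicate end-to-end locus-recovery runs.

    Each run simulates a full study with the default condition-dependent
    observers and reports the POI-vs-surround p values at the saccade
    target, cue and remapped cue in the early-cue condition and at the
    remapped cue in the late-cue condition.
    """
    rows = []
    for r in range(n_runs):
        cfg = RunConfig(participants=participants,
                        trials_per_participant=trials_per_participant,
                        seed=_derived_seed(seed, 5, r), bootstrap_B=B)
        res = run_main_stage(cfg)
        rep = res["report"].set_index("comparison")
        rows.append({
            "run": r,
            "p_st_soa200": rep.loc["CUE_SOA200:st:vs_surround", "p"],
            "p_cue_soa200": rep.loc["CUE_SOA200:cue:vs_surround", "p"],
            "p_remap_soa200": rep.loc["CUE_SOA200:remap:vs_surround", "p"],
            "p_remap_soa50": rep.loc["CUE_SOA50:remap:vs_surround", "p"],
        })
    return pd.DataFrame(rows)
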