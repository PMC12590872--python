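"""End-to-end study pipeline over animals x 8 daily sessions.

Runs bout segmentation, event detection, activation typing, modulation,
bout-to-bout ensemble statistics, longitudinal similarity/fate/bias,
action separability, and peri-event decoding for every session of a study
(synthetic by default; any source of SessionRecording works), then
summarizes each headline metric as an early (days 1+2) vs late (days 7+8)
paired contrast across animals with a two-sided paired t statistic and an
exact sign-flip permutation p-value.

Every run is deterministic given (config, master seed); the materialized
config and its hash are embedded in the report.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io
from .behavior import MotionThresholds, detect_motion_events, session_summary
from .encoding import (DEFAULT_NS, build_perievent_design, efficiency_score,
                       fit_velocity_model, n_neuron_curve)
from .ensembles import (action_bias, activation_matrix, bout_activation_proportions,
                        fate_overlap, separability_matrix, separability_score,
                        similarity_by_day)
from .events import (EventParams, classify_activation_types, detect_calcium_events,
                     positively_modulated, standardize_matrix, window_active, TYPES)
from .synthgen import (N_DAYS, BehaviorParams, PopulationParams, SessionRecording,
                       generate_session)

logger = logging.getLogger("locopop")

__all__ = ["StudyConfig", "run_pipeline", "paired_early_late_summary",
            "analyze_session"]


@dataclass
class StudyConfig:
    """Materialized configuration for a full study run."""

    n_animals: int = 1
    master_seed: int = 0
    early_days: tuple[int, ...] = (1, 2)
    late_days: tuple[int, ...] = (7, 8)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    population: PopulationParams = field(default_factory=PopulationParams)
    thresholds: MotionThresholds = field(default_factory=MotionThresholds)
    events: EventParams = field(default_factory=EventParams)
    n_shuffles: int = 1000
    bout_window_s: float = 2.0          # centered window for ensemble vectors
    bias_days: tuple[int, ...] = (1, 2, 3)
    bias_bouts: int = 2
    encoding_window_s: float = 4.0
    ns: tuple[int, ...] = DEFAULT_NS
    separability_pcs: int = 8

    def __post_init__(self) -> None:
        if set(self.early_days) & set(self.late_days):
            raise ValueError("early and late day sets must be disjoint")
        for d in (*self.early_days, *self.late_days):
            if not 1 <= d <= N_DAYS:
                raise ValueError("day sets must be subsets of 1..8")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        for key, typ in (("behavior", BehaviorParams),
                         ("population", PopulationParams),
                         ("thresholds", MotionThresholds),
                         ("events", EventParams)):
            if key in d and isinstance(d[key], dict):
                sub = {k: tuple(v) if isinstance(v, list) else v
                       for k, v in d[key].items()}
                d[key] = typ(**sub)
        for key in ("early_days", "late_days", "bias_days", "ns"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def _window_stack(z: np.ndarray, events: np.ndarray, half: int):
    """Sum of peri-event windows and the retained-event count (for pooling)."""
    n = z.shape[1]
    ev = [e for e in np.asarray(events, int) if e - half >= 0 and e + half < n]
    if not ev:
        return np.zeros((z.shape[0], 2 * half + 1)), 0
    acc = np.zeros((z.shape[0], 2 * half + 1))
    for e in ev:
        acc += z[:, e - half:e + half + 1]
    return acc, len(ev)


def analyze_session(session: SessionRecording, config: StudyConfig,
                    seeds: dict | None = None) -> dict:
    """All single-session analyses; returns summaries plus the small
    intermediates the longitudinal statistics need (activation matrices,
    pooled peri-event window sums, per-day activity flags)."""
    rate = session.frame_rate_hz
    ep = config.events
    v = session.velocity
    bouts = detect_motion_events(v, rate, config.thresholds)
    mean_vel, motion_frac = session_summary(v, bouts.motion_mask)

    z, valid = standardize_matrix(session.dff)
    trains = detect_calcium_events(z, rate, ep)
    labels = classify_activation_types(z, bouts.onsets, bouts.offsets, rate, ep,
                                       valid)
    type_fractions = {t: float(np.mean(labels == t)) for t in TYPES}

    half_typ = int(round(ep.peri_window_s * rate))
    onset_active = window_active(z, bouts.onsets, rate, ep.peri_window_s,
                                 ep.active_thresh_sd) & valid
    offset_active = window_active(z, bouts.offsets, rate, ep.peri_window_s,
                                  ep.active_thresh_sd) & valid

    mask = bouts.motion_mask
    if mask.any() and not mask.all():
        _, modulated_fraction = positively_modulated(
            trains, mask, len(v), rate, ep)
    else:
        modulated_fraction = float("nan")

    out: dict = {
        "day": session.day,
        "animal": session.animal,
        "n_onsets": int(len(bouts.onsets)),
        "n_offsets": int(len(bouts.offsets)),
        "mean_velocity_cm_s": mean_vel,
        "motion_fraction": motion_frac,
        "modulated_fraction": modulated_fraction,
        "type_fractions": type_fractions,
        "n_events_total": int(sum(len(t) for t in trains)),
    }
    inter: dict = {
        "boutset": bouts,
        "labels": labels,
        "onset_active": onset_active,
        "offset_active": offset_active,
    }

    for action, events_f in (("onset", bouts.onsets), ("offset", bouts.offsets)):
        act_mat, kept = activation_matrix(z, events_f, rate, config.bout_window_s,
                                          ep.active_thresh_sd)
        inter[f"act_{action}"] = act_mat
        out[f"bout_proportions_{action}"] = (
            bout_activation_proportions(z, events_f, rate, 8,
                                        config.bout_window_s,
                                        ep.active_thresh_sd).tolist()
            if len(events_f) >= 8 else act_mat[:8].mean(axis=1).tolist())
        # pooled typing-criterion window sums: all bouts, and the first
        # `bias_bouts` bouts (for the action-bias early vector)
        inter[f"typsum_{action}"] = _window_stack(z, events_f, half_typ)
        inter[f"biassum_{action}"] = _window_stack(
            z, events_f[:config.bias_bouts], half_typ)
        out[f"n_active_{action}"] = int(
            (onset_active if action == "onset" else offset_active).sum())

        # decoding
        try:
            design = build_perievent_design(z, v, kept, rate,
                                            config.encoding_window_s)
            if design.n_bouts < 2:
                raise ValueError("fewer than two bouts")
            fit = fit_velocity_model(design)
            curve = n_neuron_curve(design, config.ns)
            out[f"adj_r2_{action}"] = fit.adj_r2
            out[f"n_curve_{action}"] = {int(k): f.adj_r2 for k, f in curve.items()}
            n_act = out[f"n_active_{action}"]
            out[f"efficiency_{action}"] = (
                efficiency_score(curve, n_act) if n_act >= 1 and curve
                else float("nan"))
        except ValueError as err:
            logger.info("day %d %s decoding skipped: %s", session.day, action, err)
            out[f"adj_r2_{action}"] = float("nan")
            out[f"n_curve_{action}"] = {}
            out[f"efficiency_{action}"] = float("nan")

    # action separability
    try:
        mat, labs = separability_matrix(z, bouts.onsets, bouts.offsets, rate,
                                        config.encoding_window_s)
        tsne_seed = (seeds or {}).get("tsne", 0)
        out["separability"] = separability_score(mat, labs,
                                                 config.separability_pcs,
                                                 tsne_seed)
    except ValueError as err:
        logger.info("day %d separability skipped: %s", session.day, err)
        out["separability"] = float("nan")
    return out, inter


def _pooled_active(inters: dict[int, dict], days, action: str,
                   which: str, thresh: float) -> np.ndarray:
    """Activity flags from peri-event windows pooled over several days."""
    acc, count = None, 0
    for d in days:
        s, c = inters[d][f"{which}_{action}"]
        acc = s if acc is None else acc + s
        count += c
    if count == 0:
        return np.zeros(acc.shape[0] if acc is not None else 0, bool)
    return (acc / count).max(axis=1) > thresh


def _analyze_animal(config: StudyConfig, animal: int,
                    sessions: dict[int, SessionRecording]) -> dict:
    rng = np.random.default_rng(
        np.random.SeedSequence((config.master_seed, animal, 10_001)))
    days = sorted(sessions)
    day_out, inters = {}, {}
    for d in days:
        tsne_seed = int((config.master_seed * 1000 + animal * 10 + d) % (2**31))
        day_out[d], inters[d] = analyze_session(
            sessions[d], config, seeds={"tsne": tsne_seed})

    out: dict = {"days": day_out}
    thresh = config.events.active_thresh_sd

    # similarity (within-day and across adjacent days) per action
    for action in ("onset", "offset"):
        by_day = {d: inters[d][f"act_{action}"] for d in days
                  if inters[d][f"act_{action}"].size}
        out[f"similarity_within_{action}"] = similarity_by_day(
            by_day, "within_day", config.n_shuffles, rng)
        out[f"similarity_across_{action}"] = {
            f"{a}-{b}": v for (a, b), v in similarity_by_day(
                by_day, "across_adjacent_days", config.n_shuffles, rng).items()}

    # fate overlap and action bias per action
    for action in ("onset", "offset"):
        flag = f"{action}_active"
        try:
            early = np.array([inters[d][flag] for d in config.early_days])
            late = np.array([inters[d][flag] for d in config.late_days])
            fr = fate_overlap(early, late, config.n_shuffles, rng)
            out[f"fate_{action}"] = {
                "observed_pct": fr.observed_pct,
                "shuffle_mean_pct": fr.shuffle_mean_pct,
                "p_value": fr.p_value,
                "n_late": fr.n_late,
            }
        except (KeyError, ValueError) as err:
            logger.info("animal %d fate (%s) skipped: %s", animal, action, err)
            out[f"fate_{action}"] = {"error": str(err)}
        try:
            members = np.flatnonzero(
                _pooled_active(inters, config.late_days, action, "typsum", thresh))
            early_on = _pooled_active(inters, config.bias_days, "onset",
                                      "biassum", thresh)
            early_off = _pooled_active(inters, config.bias_days, "offset",
                                       "biassum", thresh)
            out[f"action_bias_{action}"] = action_bias(members, early_on, early_off)
        except (KeyError, ValueError) as err:
            logger.info("animal %d bias (%s) skipped: %s", animal, action, err)
            out[f"action_bias_{action}"] = float("nan")
    return out


@dataclass
class PairedSummary:
    """Early-vs-late paired contrast across animals."""

    early_mean: float
    late_mean: float
    mean_diff: float
    t_stat: float
    t_p: float
    perm_p: float
    per_animal_diff: list[float]


def paired_early_late_summary(
    per_day: dict[int, dict[int, float]],
    early_days=(1, 2),
    late_days=(7, 8),
    max_exact: int = 12,
    seed: int = 0,
) -> PairedSummary:
    """Paired early/late contrast of a per-animal-per-day metric.

    ``per_day`` maps animal -> {day -> value}.  Early/late values are
    per-animal means over the named days; the permutation p comes from
    sign-flips of the paired differences (exhaustive for <= ``max_exact``
    animals, 10000 random flips beyond).  With fewer than two animals the
    summary is descriptive only (t and p are NaN).
    """
    early, late = [], []
    for animal, vals in sorted(per_day.items()):
        e = [vals[d] for d in early_days if d in vals and np.isfinite(vals[d])]
        l = [vals[d] for d in late_days if d in vals and np.isfinite(vals[d])]
        if e and l:
            early.append(np.mean(e))
            late.append(np.mean(l))
    early_a, late_a = np.asarray(early), np.asarray(late)
    diff = late_a - early_a
    n = len(diff)
    if n == 0:
        return PairedSummary(*([float("nan")] * 6), [])
    if n < 2:
        return PairedSummary(float(early_a.mean()), float(late_a.mean()),
                             float(diff.mean()), float("nan"), float("nan"),
                             float("nan"), diff.tolist())
    t_stat, t_p = stats.ttest_rel(late_a, early_a)
    obs = abs(diff.mean())
    if n <= max_exact:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
    else:
        signs = np.random.default_rng(seed).choice((1.0, -1.0), size=(10_000, n))
    null = np.abs((signs * diff).mean(axis=1))
    perm_p = float((null >= obs - 1e-12).mean())
    return PairedSummary(float(early_a.mean()), float(late_a.mean()),
                         float(diff.mean()), float(t_stat), float(t_p),
                         perm_p, diff.tolist())


def _metric_table(animals_out: dict) -> dict[str, dict[int, dict[int, float]]]:
    """Per-animal-per-day values for every early/late-contrast metric."""
    metrics: dict[str, dict[int, dict[int, float]]] = {}

    def put(name, animal, day, value):
        if value is None or (isinstance(value, float) and not np.isfinite(value)):
            return
        metrics.setdefault(name, {}).setdefault(animal, {})[day] = float(value)

    for a, aout in animals_out.items():
        for d, dout in aout["days"].items():
            for t in TYPES:
                put(f"{t}_fraction", a, d, dout["type_fractions"][t])
            put("mean_velocity_cm_s", a, d, dout["mean_velocity_cm_s"])
            put("motion_fraction", a, d, dout["motion_fraction"])
            put("modulated_fraction", a, d, dout["modulated_fraction"])
            put("separability", a, d, dout["separability"])
            for action in ("onset", "offset"):
                put(f"adj_r2_{action}", a, d, dout[f"adj_r2_{action}"])
                put(f"efficiency_{action}", a, d, dout[f"efficiency_{action}"])
        for action in ("onset", "offset"):
            for d, val in aout[f"similarity_within_{action}"].items():
                put(f"similarity_within_{action}", a, d, val)
    return metrics


def run_pipeline(config: StudyConfig, outdir: str | Path | None = None,
                 sessions: dict[tuple[int, int], SessionRecording] | None = None,
                 ) -> dict:
    """Run the full study analysis and return the report dictionary.

    Sessions are generated from the config's synthetic-study block unless
    an explicit ``sessions`` mapping (animal, day) -> SessionRecording is
    supplied.  When ``outdir`` is given, the report JSON, the materialized
    config, and tidy per-day/similarity CSVs are written there.
    """
    cfg_dict = config.to_dict()
    chash = io.config_hash(cfg_dict)
    logger.info("study run: %d animals, seed %d, config %s",
                config.n_animals, config.master_seed, chash)

    animals_out: dict[int, dict] = {}
    for a in range(config.n_animals):
        if sessions is None:
            day_sessions = {
                d: generate_session(config.behavior, config.population, a, d,
                                    config.master_seed)
                for d in range(1, N_DAYS + 1)
            }
        else:
            day_sessions = {d: s for (an, d), s in sessions.items() if an == a}
        animals_out[a] = _analyze_animal(config, a, day_sessions)

    metrics = _metric_table(animals_out)
    early_late = {}
    for name, table in metrics.items():
        s = paired_early_late_summary(table, config.early_days, config.late_days)
        early_late[name] = dataclasses.asdict(s)

    report = {
        "config": cfg_dict,
        "config_hash": chash,
        "master_seed": config.master_seed,
        "animals": animals_out,
        "early_late": early_late,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.save_config(outdir / "config.yaml", io._jsonable(cfg_dict))
        io.save_report_json(outdir / "report.json", report)
        _write_tidy_csvs(outdir, animals_out, metrics)
    return report


def _write_tidy_csvs(outdir: Path, animals_out: dict, metrics: dict) -> None:
    rows = []
    for a, aout in animals_out.items():
        for d, dout in aout["days"].items():
            row = {k: v for k, v in dout.items()
                   if isinstance(v, (int, float, str))}
            row.update({f"frac_{t}": dout["type_fractions"][t] for t in TYPES})
            rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "per_day.csv", index=False)
    sim_rows = [
        {"metric": name, "animal": a, "day": d, "value": v}
        for name, table in metrics.items()
        for a, days in table.items() for d, v in days.items()
    ]
    pd.DataFrame(sim_rows).to_csv(outdir / "metrics_tidy.csv", index=False)
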