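"""File formats, configuration, and the end-to-end analysis pipeline.

Tabular I/O is plain CSV (UTF-8, '.' decimal, times in seconds, frame
indices 0-based); floats are written with ``repr`` so write -> read
round-trips are bit-exact.  Trace CSVs carry a JSON sidecar with the
frame rate.  ``run_pipeline`` chains simulation, ΔF/F preprocessing,
peri-event analysis, decoding, and devaluation statistics, and is fully
reproducible from (config, seed).
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import behavior_stats, decoding, perievent, photometry
from .photometry import DffParams
from .synthetic import (AgentParams, BehavioralEvent, EventType,
                        NeuralGenParams, RawTrace, ScheduleKind, ScheduleSpec,
                        SessionRecord, default_event_amplitudes,
                        generate_trace, simulate_devaluation_pair,
                        simulate_session)

logger = logging.getLogger(__name__)

EVENT_LOG_COLUMNS = ["session_id", "time_s", "event_type", "rewarded",
                     "schedule_kind", "schedule_value"]
TRACE_COLUMNS = ["time_s", "fluorescence"]


# ---------------------------------------------------------------------------
# event logs
# ---------------------------------------------------------------------------

def write_event_log(session: SessionRecord, path: str | Path,
                    session_id: str = "s0") -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(EVENT_LOG_COLUMNS)
        for ev in session.events:
            w.writerow([session_id, repr(float(ev.time_s)),
                        ev.event_type.value, int(ev.rewarded),
                        session.schedule.kind.value,
                        repr(float(session.schedule.value))])
    return path


def read_event_log(path: str | Path) -> SessionRecord:
    """Load and validate a behavioral event log.

    Timestamps must be non-decreasing (no silent sorting) and event
    types must be known; violations raise with the offending line
    number.  A header-only file yields an empty extinction session.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file (missing header)")
        if header != EVENT_LOG_COLUMNS:
            raise ValueError(f"{path}: unexpected header {header!r}")
        events: list[BehavioralEvent] = []
        sched_kind: str | None = None
        sched_value: float | None = None
        prev_t = -math.inf
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(EVENT_LOG_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected "
                                 f"{len(EVENT_LOG_COLUMNS)} fields, got {len(row)}")
            _, t_s, etype_s, rew_s, kind_s, value_s = row
            try:
                t = float(t_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: bad time_s {t_s!r}")
            if t < 0:
                raise ValueError(f"{path}:{lineno}: negative time_s")
            if t < prev_t:
                raise ValueError(
                    f"{path}:{lineno}: non-monotone timestamp {t_s}")
            prev_t = t
            try:
                etype = EventType(etype_s)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: unknown event_type {etype_s!r}")
            if rew_s not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: rewarded must be 0/1")
            if sched_kind is None:
                sched_kind, sched_value = kind_s, float(value_s)
            events.append(BehavioralEvent(t, etype, rew_s == "1"))

    if sched_kind is None:  # header-only
        schedule = ScheduleSpec(kind=ScheduleKind.EXTINCTION)
    else:
        schedule = ScheduleSpec(kind=ScheduleKind(sched_kind),
                                value=sched_value)
    n_rewards = sum(1 for e in events
                    if e.event_type is EventType.REWARD_DELIVERY)
    duration = events[-1].time_s if events else 0.0
    cond = {ScheduleKind.RR: "RR", ScheduleKind.FR: "RR",
            ScheduleKind.RI: "RI"}.get(schedule.kind)
    return SessionRecord(schedule=schedule, events=events,
                         duration_s=duration, n_rewards=n_rewards,
                         termination=None, condition_label=cond)


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_trace(trace: RawTrace, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(TRACE_COLUMNS)
        for i, v in enumerate(trace.values):
            w.writerow([repr(trace.t0_s + i / trace.fps), repr(float(v))])
    with open(_sidecar_path(path), "w", encoding="utf-8") as fh:
        json.dump({"fps": trace.fps, "t0_s": trace.t0_s}, fh, sort_keys=True)
        fh.write("\n")
    return path


def read_trace(path: str | Path) -> RawTrace:
    path = Path(path)
    with open(_sidecar_path(path), encoding="utf-8") as fh:
        meta = json.load(fh)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != TRACE_COLUMNS:
            raise ValueError(f"{path}: unexpected header {header!r}")
        values = [float(row[1]) for row in reader if row]
    return RawTrace(fps=float(meta["fps"]), values=np.asarray(values),
                    t0_s=float(meta["t0_s"]))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _from_mapping(cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one end-to-end analysis run."""

    seed: int = 0
    n_sessions_per_condition: int = 3
    session_duration_s: float = 900.0
    reward_cap: int = 60
    rr_value: float = 20.0
    ri_value: float = 120.0
    rr_agent: AgentParams = field(default_factory=lambda: AgentParams(
        nose_poke_rate_hz=0.5, devaluation_factor=0.3))
    ri_agent: AgentParams = field(default_factory=lambda: AgentParams(
        nose_poke_rate_hz=0.3, devaluation_factor=1.0))
    neural: NeuralGenParams = field(default_factory=NeuralGenParams)
    amplitude_scale: float = 1.0   # scales all transient amplitudes
    dff: DffParams = field(default_factory=DffParams)
    pre_s: float = 2.0
    post_s: float = 2.0
    event_families: tuple[str, ...] = ("NP", "M_entry", "M_exit")
    k_folds: int = 4
    n_resamples: int = 400
    input_range: tuple[float, float] = (-2.0, 2.0)
    n_blocks: int = 10
    n_goal_subjects: int = 6
    n_habit_subjects: int = 5
    devaluation_duration_s: float = 600.0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        for key, sub in (("rr_agent", AgentParams), ("ri_agent", AgentParams),
                         ("neural", NeuralGenParams), ("dff", DffParams)):
            if key in data and isinstance(data[key], dict):
                data[key] = _from_mapping(sub, data[key])
        for key in ("event_families", "input_range"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return _from_mapping(cls, data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _scaled_neural(cfg: PipelineConfig) -> NeuralGenParams:
    if cfg.amplitude_scale == 1.0:
        return cfg.neural
    amps = {k: v * cfg.amplitude_scale
            for k, v in cfg.neural.event_amplitudes.items()}
    slopes = {k: v * cfg.amplitude_scale
              for k, v in cfg.neural.drift_slope_per_block.items()}
    return dataclasses.replace(cfg.neural, event_amplitudes=amps,
                               drift_slope_per_block=slopes)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """simulate -> ΔF/F -> peri-event -> decode -> stats, writing all
    stage outputs plus ``summary.json`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = iter(ss.generate_state(4 * config.n_sessions_per_condition
                                   + 2 * (config.n_goal_subjects
                                          + config.n_habit_subjects) + 8))
    neural = _scaled_neural(config)

    def _stage(name):
        logger.info("pipeline stage: %s", name)

    # --- simulate & record -------------------------------------------------
    _stage("simulate")
    pems: dict[str, perievent.PeriEventMatrix] = {}
    session_meta = {}
    for cond, value, kind, agent in (
            ("RR", config.rr_value, ScheduleKind.RR, config.rr_agent),
            ("RI", config.ri_value, ScheduleKind.RI, config.ri_agent)):
        spec = ScheduleSpec(kind=kind, value=value,
                            session_cap_s=config.session_duration_s,
                            reward_cap=config.reward_cap)
        mats = []
        n_rewards = []
        for i in range(config.n_sessions_per_condition):
            try:
                session = simulate_session(spec, agent, seed=int(next(seeds)))
                trace = generate_trace(session, neural, seed=int(next(seeds)))
                sid = f"{cond}_{i}"
                write_event_log(session, out / f"events_{sid}.csv", sid)
                write_trace(trace, out / f"trace_{sid}.csv")
                dff = photometry.compute_dff(trace, config.dff)
                mats.append(perievent.extract_perievent(
                    dff, session.events, config.pre_s, config.post_s))
                n_rewards.append(session.n_rewards)
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline stage 'simulate/preprocess' failed for "
                    f"session {cond}_{i}: {exc}") from exc
        pems[cond] = perievent.concat_perievent(mats)
        session_meta[cond] = {"n_sessions": len(mats),
                              "n_rewards": n_rewards,
                              "n_alignable_events": int(pems[cond].n_events)}

    # --- decoding ----------------------------------------------------------
    _stage("decode")
    decode_summary = {}
    for fam in config.event_families:
        try:
            ft = decoding.build_features(pems["RR"], pems["RI"], fam,
                                         input_range=config.input_range)
            res = decoding.run_svm_protocol(ft, k=config.k_folds,
                                            n_resamples=config.n_resamples,
                                            seed=int(next(seeds)))
            s = res.summary()
            s["accuracy_vs_chance"] = decoding.compare_to_chance(res.accuracy)
            decode_summary[fam] = s
            _write_tsv(out / f"decoding_{fam}.tsv",
                       ["resample", "auc", "accuracy", "sensitivity",
                        "specificity"],
                       zip(range(res.n_resamples), res.auc, res.accuracy,
                           res.sensitivity, res.specificity))
            _write_tsv(out / f"roc_{fam}.csv", ["fpr", "mean_tpr"],
                       zip(res.fpr_grid, res.mean_tpr), delimiter=",")
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage 'decode' failed for family {fam!r}: {exc}"
            ) from exc

    # --- trial-progression trends ------------------------------------------
    _stage("blockwise_trend")
    trend_summary = {}
    for cond in ("RR", "RI"):
        for cls in ("NP R+", "NP R-", "M_entry R+"):
            sub = pems[cond]
            key = f"{cond}/{cls}"
            try:
                bs = perievent.blockwise_trend(sub, cls,
                                               n_blocks=config.n_blocks)
                trend_summary[key] = {"slope": bs.slope,
                                      "intercept": bs.intercept,
                                      "slope_p": bs.slope_p}
            except ValueError as exc:
                trend_summary[key] = {"skipped": str(exc)}

    # --- pointwise RR vs RI comparison (NP family) -------------------------
    _stage("pointwise_compare")
    try:
        ranges = perievent.pointwise_group_compare(pems["RR"].subset("NP"),
                                                   pems["RI"].subset("NP"))
        range_summary = [{"start_s": r.start_s, "end_s": r.end_s}
                         for r in ranges]
    except ValueError as exc:
        range_summary = [{"skipped": str(exc)}]

    # --- devaluation statistics --------------------------------------------
    _stage("devaluation")
    deval_summary = {}
    for name, agent, n_sub in (("goal", config.rr_agent,
                                config.n_goal_subjects),
                               ("habit", config.ri_agent,
                                config.n_habit_subjects)):
        pairs = []
        for _ in range(n_sub):
            v = simulate_devaluation_pair(agent, "valued",
                                          config.devaluation_duration_s,
                                          seed=int(next(seeds)))
            d = simulate_devaluation_pair(agent, "devalued",
                                          config.devaluation_duration_s,
                                          seed=int(next(seeds)))
            pairs.append((
                len(v.event_times(EventType.NOSE_POKE_ACTIVE)),
                len(d.event_times(EventType.NOSE_POKE_ACTIVE))))
        res = behavior_stats.devaluation_test(pairs)
        deval_summary[name] = {
            "n_subjects": n_sub,
            "statistic": res.statistic,
            "p_value": res.p_value,
            "mean_devaluation_index": float(np.nanmean(res.devaluation_index)),
        }
        _write_tsv(out / f"devaluation_{name}.tsv",
                   ["subject", "valued", "devalued"],
                   ((i, v, d) for i, (v, d) in enumerate(pairs)))

    summary = {
        "seed": config.seed,
        "sessions": session_meta,
        "decoding": decode_summary,
        "blockwise_trends": trend_summary,
        "np_significant_ranges": range_summary,
        "devaluation": deval_summary,
    }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _write_tsv(path: Path, header, rows, delimiter: str = "\t") -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(header)
        for row in rows:
            w.writerow([x if isinstance(x, str) else repr(float(x))
                        if isinstance(x, float) else x for x in row])


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_fixtures(outdir: str | Path, seed: int = 0) -> list[Path]:
    """Write a small deterministic fixture set: 2 RR20 + 2 RI120
    sessions (300 s each) with coupled traces."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.generate_state(8))
    neural = NeuralGenParams()
    paths = []
    for cond, value, kind, rate in (("RR", 20.0, ScheduleKind.RR, 0.5),
                                    ("RI", 120.0, ScheduleKind.RI, 0.3)):
        spec = ScheduleSpec(kind=kind, value=value, session_cap_s=300.0,
                            reward_cap=60)
        agent = AgentParams(nose_poke_rate_hz=rate)
        for i in range(2):
            sid = f"{cond}_{i}"
            session = simulate_session(spec, agent, seed=int(next(seeds)))
            trace = generate_trace(session, neural, seed=int(next(seeds)))
            paths.append(write_event_log(session, out / f"events_{sid}.csv",
                                         sid))
            paths.append(write_trace(trace, out / f"trace_{sid}.csv"))
    return paths
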