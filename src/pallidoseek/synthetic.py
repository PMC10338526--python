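"""Synthetic operant behavior and fiber-photometry trace generation.

Simulates mouse nose-poke sessions under fixed-ratio (FR), random-ratio
(RR), random-interval (RI) and extinction schedules, the multi-day
training curricula that shape goal-directed (RR track) versus habitual
(RI track) seeking, reward-devaluation extinction pairs, and GCaMP6s-like
fluorescence traces whose transient amplitudes are coupled to the
behavioral events.  Every downstream analysis stage (ΔF/F preprocessing,
peri-event alignment, decoding, devaluation statistics) can therefore be
exercised without any recorded data.

Schedule contracts
------------------
RR ``value``   : each active poke is reinforced independently with
                 probability ``1/value`` (pokes per reward ~ Geometric).
RI ``value``   : a reward is armed at an exponentially distributed delay
                 (mean ``value`` seconds) after the previous reward was
                 collected; the first active poke at/after arming is
                 reinforced.  A uniform arming alternative (same mean) is
                 available via ``ScheduleSpec.ri_arming``.
FR ``value``   : every ``value``-th active poke is reinforced.
EXTINCTION     : no reinforcement.

Sessions stop at ``min(session_cap_s, reward_cap)`` — by default 30 min
or 60 reinforcements, whichever comes first.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_FPS = 30.0
#: latency from a reinforced poke to the magazine entry that collects it
DEFAULT_COLLECT_LATENCY_S = 1.0


class ScheduleKind(str, Enum):
    FR = "FR"
    RR = "RR"
    RI = "RI"
    EXTINCTION = "EXTINCTION"


class EventType(str, Enum):
    NOSE_POKE_ACTIVE = "nose_poke_active"
    NOSE_POKE_INACTIVE = "nose_poke_inactive"
    MAGAZINE_ENTRY = "magazine_entry"
    MAGAZINE_EXIT = "magazine_exit"
    REWARD_DELIVERY = "reward_delivery"


# sort priority for simultaneous events
_EVENT_ORDER = {
    EventType.NOSE_POKE_ACTIVE: 0,
    EventType.NOSE_POKE_INACTIVE: 0,
    EventType.REWARD_DELIVERY: 1,
    EventType.MAGAZINE_ENTRY: 2,
    EventType.MAGAZINE_EXIT: 3,
}


@dataclass(frozen=True)
class ScheduleSpec:
    """Reinforcement schedule parameters.

    ``value`` is responses/reward for FR/RR, mean seconds for RI, and is
    ignored for EXTINCTION.  ``session_cap_s`` may be ``math.inf`` and
    ``reward_cap`` may be ``None`` to disable a cap (calibration use).
    """

    kind: ScheduleKind
    value: float = 1.0
    session_cap_s: float = 1800.0
    reward_cap: int | None = 60
    ri_arming: str = "exponential"  # or "uniform" on [0, 2*value]

    def __post_init__(self) -> None:
        kind = ScheduleKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind is not ScheduleKind.EXTINCTION and not self.value > 0:
            raise ValueError(f"schedule value must be > 0, got {self.value}")
        if not self.session_cap_s > 0:
            raise ValueError("session_cap_s must be > 0")
        if self.reward_cap is not None and not self.reward_cap > 0:
            raise ValueError("reward_cap must be > 0 or None")
        if self.ri_arming not in ("exponential", "uniform"):
            raise ValueError(f"unknown ri_arming {self.ri_arming!r}")


@dataclass(frozen=True)
class AgentParams:
    """Stochastic responder model.

    Responding per event type is a homogeneous Poisson process
    (``deterministic_pokes=True`` switches active pokes to a regular
    1/rate grid, used for schedule calibration).  ``devaluation_factor``
    multiplies the active-poke rate in devalued extinction sessions: a
    goal-directed agent has a factor < 1, a habitual agent 1.
    """

    nose_poke_rate_hz: float = 0.5
    inactive_rate_hz: float = 0.05
    magazine_check_rate_hz: float = 0.1
    magazine_dwell_s: float = 2.0
    devaluation_factor: float = 1.0
    reward_collect_latency_s: float = DEFAULT_COLLECT_LATENCY_S
    deterministic_pokes: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("nose_poke_rate_hz", "inactive_rate_hz",
                     "magazine_check_rate_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"degenerate agent: {name} must be >= 0")
        if not self.magazine_dwell_s > 0:
            raise ValueError("magazine_dwell_s must be > 0")
        if not 0.0 <= self.devaluation_factor <= 1.0:
            raise ValueError("devaluation_factor must be in [0, 1]")


@dataclass(frozen=True)
class BehavioralEvent:
    time_s: float
    event_type: EventType
    rewarded: bool


@dataclass
class SessionRecord:
    schedule: ScheduleSpec
    events: list[BehavioralEvent]
    duration_s: float
    n_rewards: int
    termination: str | None  # "time_cap" | "reward_cap" | None (loaded)
    condition_label: str | None = None  # "RR" | "RI" for decoding

    def event_times(self, event_type: EventType,
                    rewarded: bool | None = None) -> np.ndarray:
        return np.array(
            [e.time_s for e in self.events
             if e.event_type is event_type
             and (rewarded is None or e.rewarded == rewarded)])


# ---------------------------------------------------------------------------
# reinforcement engine internals (shared by simulate_session and calibration)
# ---------------------------------------------------------------------------

def _poisson_times(rate_hz: float, t_max: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Homogeneous Poisson event times on (0, t_max]."""
    if rate_hz <= 0 or t_max <= 0:
        return np.empty(0)
    times: list[np.ndarray] = []
    t = 0.0
    n_guess = max(int(rate_hz * t_max * 1.2) + 20, 64)
    while True:
        gaps = rng.exponential(1.0 / rate_hz, n_guess)
        chunk = t + np.cumsum(gaps)
        times.append(chunk)
        t = chunk[-1]
        if t > t_max:
            break
    all_t = np.concatenate(times)
    return all_t[all_t <= t_max]


def _regular_times(rate_hz: float, t_max: float) -> np.ndarray:
    if rate_hz <= 0 or t_max <= 0:
        return np.empty(0)
    period = 1.0 / rate_hz
    n = int(math.floor(t_max / period))
    return period * np.arange(1, n + 1)


def _rr_rewarded_mask(n_pokes: int, value: float,
                      rng: np.random.Generator) -> np.ndarray:
    if value == 1:
        return np.ones(n_pokes, dtype=bool)
    return rng.random(n_pokes) < 1.0 / value


def _fr_rewarded_mask(n_pokes: int, value: float) -> np.ndarray:
    step = int(round(value))
    return (np.arange(1, n_pokes + 1) % step) == 0


def _ri_arming_delay(value: float, arming: str,
                     rng: np.random.Generator) -> float:
    if arming == "uniform":
        return rng.uniform(0.0, 2.0 * value)
    return rng.exponential(value)


def _ri_reward_indices(poke_times: np.ndarray, value: float,
                       collect_latency_s: float, rng: np.random.Generator,
                       arming: str = "exponential") -> np.ndarray:
    """Indices of reinforced pokes under the RI contract.

    The arming clock (re)starts when the previous reward is collected
    (reinforced poke + collection latency); at session start it starts
    at t = 0.
    """
    out: list[int] = []
    armed = _ri_arming_delay(value, arming, rng)
    n = len(poke_times)
    i = int(np.searchsorted(poke_times, armed, side="left"))
    while i < n:
        out.append(i)
        collected = poke_times[i] + collect_latency_s
        armed = collected + _ri_arming_delay(value, arming, rng)
        i = int(np.searchsorted(poke_times, armed, side="left"))
    return np.asarray(out, dtype=np.int64)


# ---------------------------------------------------------------------------
# session simulation
# ---------------------------------------------------------------------------

def simulate_session(schedule: ScheduleSpec, agent: AgentParams,
                     seed: int | None = None,
                     condition_label: str | None = None) -> SessionRecord:
    """Simulate one operant session under ``schedule``.

    Reinforced pokes trigger a reward delivery at the poke time and a
    rewarded magazine entry/exit pair (entry after the collection
    latency, dwell ~ Exponential).  Unrewarded magazine checks are an
    independent Poisson process; checks that would overlap an ongoing
    magazine visit are dropped so entries/exits strictly alternate.
    The session terminates at the time cap or once the reward cap has
    been delivered, whichever comes first.
    """
    if seed is None:
        seed = agent.seed
    if schedule.kind is not ScheduleKind.EXTINCTION \
            and agent.nose_poke_rate_hz <= 0 \
            and not math.isfinite(schedule.session_cap_s):
        raise ValueError("degenerate agent: zero poke rate with no time cap")
    if not math.isfinite(schedule.session_cap_s) and schedule.reward_cap is None:
        raise ValueError("at least one of the session caps must be finite")

    if math.isfinite(schedule.session_cap_s):
        horizon = schedule.session_cap_s
    else:
        # expected time to hit the reward cap, with head-room; doubled on
        # undershoot (the RNG is restarted so results stay deterministic)
        rate = max(agent.nose_poke_rate_hz, 1e-9)
        if schedule.kind is ScheduleKind.RI:
            per_reward = schedule.value + agent.reward_collect_latency_s + 1.0 / rate
        else:
            per_reward = schedule.value / rate
        horizon = 1.5 * (schedule.reward_cap or 1) * max(per_reward, 1e-6) + 60.0

    while True:
        session = _simulate_once(schedule, agent, seed, horizon, condition_label)
        if session is not None:
            return session
        horizon *= 2.0


def _simulate_once(schedule: ScheduleSpec, agent: AgentParams,
                   seed: int | None, horizon: float,
                   condition_label: str | None) -> SessionRecord | None:
    rng = np.random.default_rng(seed)
    latency = agent.reward_collect_latency_s

    if agent.deterministic_pokes:
        pokes = _regular_times(agent.nose_poke_rate_hz, horizon)
    else:
        pokes = _poisson_times(agent.nose_poke_rate_hz, horizon, rng)

    kind = schedule.kind
    if kind is ScheduleKind.EXTINCTION:
        reward_idx = np.empty(0, dtype=np.int64)
    elif kind is ScheduleKind.RR:
        reward_idx = np.flatnonzero(
            _rr_rewarded_mask(len(pokes), schedule.value, rng))
    elif kind is ScheduleKind.FR:
        reward_idx = np.flatnonzero(
            _fr_rewarded_mask(len(pokes), schedule.value))
    elif kind is ScheduleKind.RI:
        reward_idx = _ri_reward_indices(pokes, schedule.value, latency, rng,
                                        schedule.ri_arming)
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown schedule kind {kind}")

    reward_times = pokes[reward_idx]
    cap = schedule.reward_cap
    if cap is not None and len(reward_times) >= cap:
        reward_times = reward_times[:cap]
        dwells = rng.exponential(agent.magazine_dwell_s, len(reward_times))
        t_end = min(float(reward_times[-1] + latency + dwells[-1]),
                    schedule.session_cap_s)
        termination = "reward_cap"
    else:
        if not math.isfinite(schedule.session_cap_s):
            return None  # undershoot: caller doubles the horizon
        dwells = rng.exponential(agent.magazine_dwell_s, len(reward_times))
        t_end = schedule.session_cap_s
        termination = "time_cap"

    n_rewards = len(reward_times)
    rewarded_mask = np.zeros(len(pokes), dtype=bool)
    rewarded_mask[reward_idx[:n_rewards]] = True

    # magazine intervals: rewarded collections + unrewarded checks
    entries = reward_times + latency
    intervals = [(float(e), float(e + d), True)
                 for e, d in zip(entries, dwells)]
    checks = _poisson_times(agent.magazine_check_rate_hz, t_end, rng)
    check_dwells = rng.exponential(agent.magazine_dwell_s, len(checks))
    intervals += [(float(e), float(e + d), False)
                  for e, d in zip(checks, check_dwells)]
    intervals.sort(key=lambda iv: iv[0])

    magazine: list[tuple[float, float, bool]] = []
    prev_exit = -math.inf
    for entry, exit_, rewarded in intervals:
        if entry < prev_exit:
            if not rewarded:
                continue  # drop overlapping unrewarded check
            entry = prev_exit + 1e-9  # still in magazine: collect next reward
            exit_ = max(exit_, entry + 1e-9)
        magazine.append((entry, exit_, rewarded))
        prev_exit = exit_

    inactive = _poisson_times(agent.inactive_rate_hz, t_end, rng)

    # once the final reinforcement is delivered the hole is inactive:
    # no further pokes are recorded while the reward is collected
    poke_cutoff = float(reward_times[-1]) if termination == "reward_cap" \
        else t_end
    events: list[BehavioralEvent] = []
    for t, rew in zip(pokes, rewarded_mask):
        if t > poke_cutoff:
            break
        events.append(BehavioralEvent(float(t), EventType.NOSE_POKE_ACTIVE,
                                      bool(rew)))
    for t in reward_times:
        events.append(BehavioralEvent(float(t), EventType.REWARD_DELIVERY, True))
    for entry, exit_, rewarded in magazine:
        if entry > t_end:
            continue
        events.append(BehavioralEvent(entry, EventType.MAGAZINE_ENTRY, rewarded))
        events.append(BehavioralEvent(min(exit_, t_end),
                                      EventType.MAGAZINE_EXIT, rewarded))
    for t in inactive:
        events.append(BehavioralEvent(float(t), EventType.NOSE_POKE_INACTIVE,
                                      False))
    events.sort(key=lambda e: (e.time_s, _EVENT_ORDER[e.event_type]))

    if condition_label is None:
        condition_label = {ScheduleKind.RR: "RR", ScheduleKind.FR: "RR",
                           ScheduleKind.RI: "RI"}.get(kind)
    return SessionRecord(schedule=schedule, events=events,
                         duration_s=float(t_end), n_rewards=n_rewards,
                         termination=termination,
                         condition_label=condition_label)


# ---------------------------------------------------------------------------
# schedule calibration (uncapped, vectorized; same engine internals)
# ---------------------------------------------------------------------------

def calibrate_schedule(kind: ScheduleKind | str, value: float,
                       n_rewards: int = 1000,
                       poke_rate_hz: float = DEFAULT_FPS,
                       seed: int | None = None,
                       deterministic_pokes: bool = True,
                       collect_latency_s: float = DEFAULT_COLLECT_LATENCY_S,
                       ri_arming: str = "exponential") -> dict:
    """Run the reinforcement engine uncapped until ``n_rewards``.

    Returns, for RI, the realized inter-reinforcement intervals (mean and
    SEM), and for RR/FR the active pokes per reinforcement.  Uses the
    identical ``_ri_reward_indices`` / ``_rr_rewarded_mask`` internals as
    :func:`simulate_session`, on a long vectorized poke stream, so large
    calibration runs do not materialize millions of event objects.
    """
    kind = ScheduleKind(kind)
    if n_rewards < 1:
        raise ValueError("n_rewards must be >= 1")
    rng = np.random.default_rng(seed)

    if kind is ScheduleKind.RI:
        factor = 1.3
        while True:
            horizon = n_rewards * (value + collect_latency_s
                                   + 1.0 / poke_rate_hz) * factor + 10.0
            rng = np.random.default_rng(seed)
            if deterministic_pokes:
                pokes = _regular_times(poke_rate_hz, horizon)
            else:
                pokes = _poisson_times(poke_rate_hz, horizon, rng)
            idx = _ri_reward_indices(pokes, value, collect_latency_s, rng,
                                     ri_arming)
            if len(idx) >= n_rewards:
                break
            factor *= 1.5
        deliveries = pokes[idx[:n_rewards]]
        intervals = np.diff(deliveries, prepend=0.0)
        return {
            "kind": kind.value, "value": value, "n_rewards": n_rewards,
            "intervals_s": intervals,
            "mean_interval_s": float(intervals.mean()),
            "sem_interval_s": float(intervals.std(ddof=1)
                                    / math.sqrt(len(intervals))),
        }

    if kind in (ScheduleKind.RR, ScheduleKind.FR):
        factor = 1.5
        while True:
            rng = np.random.default_rng(seed)
            n_pokes = int(n_rewards * value * factor) + 64
            if kind is ScheduleKind.RR:
                mask = _rr_rewarded_mask(n_pokes, value, rng)
            else:
                mask = _fr_rewarded_mask(n_pokes, value)
            pos = np.flatnonzero(mask)
            if len(pos) >= n_rewards:
                break
            factor *= 1.5
        pos = pos[:n_rewards]
        counts = np.diff(pos + 1, prepend=0)
        return {
            "kind": kind.value, "value": value, "n_rewards": n_rewards,
            "responses_per_reward": counts,
            "mean_responses_per_reward": float(counts.mean()),
            "sem_responses_per_reward": float(counts.std(ddof=1)
                                              / math.sqrt(len(counts))),
        }

    raise ValueError(f"cannot calibrate schedule kind {kind}")


# ---------------------------------------------------------------------------
# curricula and devaluation assay
# ---------------------------------------------------------------------------

#: (schedule value, (min days, max days)) per training stage
RR_TRACK_STAGES: tuple[tuple[float, tuple[int, int]], ...] = (
    (2, (1, 2)), (5, (2, 3)), (10, (2, 3)), (20, (2, 3)))
RI_TRACK_STAGES: tuple[tuple[float, tuple[int, int]], ...] = (
    (30, (2, 2)), (60, (2, 3)), (120, (4, 4)))


def simulate_curriculum(kind: str, agent: AgentParams,
                        seed: int | None = None,
                        days: Mapping[float, int] | None = None,
                        session_cap_s: float = 1800.0,
                        reward_cap: int | None = 60) -> list[SessionRecord]:
    """Simulate the multi-day RR (goal) or RI (habit) training track.

    ``days`` optionally sets the number of sessions per stage value; it
    must stay within the published per-stage ranges.  Defaults use the
    minimum day counts (RI: 30,30,60,60,120,120,120,120).
    """
    if kind == "RR_track":
        stages, sched_kind = RR_TRACK_STAGES, ScheduleKind.RR
    elif kind == "RI_track":
        stages, sched_kind = RI_TRACK_STAGES, ScheduleKind.RI
    else:
        raise ValueError(f"unknown curriculum kind {kind!r}")
    if days is not None and len(days) == 0:
        raise ValueError("empty curriculum config")

    values: list[float] = []
    for value, (lo, hi) in stages:
        n = lo if days is None else int(days.get(value, lo))
        if not lo <= n <= hi:
            raise ValueError(
                f"stage {sched_kind.value}{value:g} allows {lo}-{hi} days, got {n}")
        values.extend([value] * n)

    child_seeds = np.random.SeedSequence(seed).generate_state(len(values))
    sessions = []
    for value, s in zip(values, child_seeds):
        spec = ScheduleSpec(kind=sched_kind, value=value,
                            session_cap_s=session_cap_s, reward_cap=reward_cap)
        sessions.append(simulate_session(spec, agent, seed=int(s)))
    return sessions


def simulate_devaluation_pair(agent: AgentParams, condition: str,
                              duration_s: float = 600.0,
                              seed: int | None = None) -> SessionRecord:
    """One nonreinforced (extinction) test session, valued or devalued.

    In the devalued condition the active-poke rate is multiplied by the
    agent's ``devaluation_factor`` (goal-directed < 1, habitual = 1).
    """
    if not duration_s > 0:
        raise ValueError("duration_s must be > 0")
    if condition == "valued":
        eff = agent
    elif condition == "devalued":
        eff = replace(agent, nose_poke_rate_hz=(agent.nose_poke_rate_hz
                                                * agent.devaluation_factor))
    else:
        raise ValueError(f"condition must be 'valued' or 'devalued', got {condition!r}")
    spec = ScheduleSpec(kind=ScheduleKind.EXTINCTION, value=1.0,
                        session_cap_s=duration_s, reward_cap=None)
    return simulate_session(spec, eff, seed=seed)


# ---------------------------------------------------------------------------
# photometry trace generation
# ---------------------------------------------------------------------------

def default_event_amplitudes() -> dict:
    """Transient amplitudes by condition/event (≈ peak ΔF/F at f0 = 1).

    Encodes the condition orderings the analyses must recover: RI > RR
    around nose pokes and rewarded magazine entry, RR > RI at rewarded
    magazine exit, no schedule effect for unrewarded entry/exit.
    """
    NP, EN, EX = (EventType.NOSE_POKE_ACTIVE, EventType.MAGAZINE_ENTRY,
                  EventType.MAGAZINE_EXIT)
    return {
        ("RI", NP, True): 0.8, ("RI", NP, False): 0.6,
        ("RR", NP, True): 0.4, ("RR", NP, False): 0.25,
        ("RI", EN, True): 0.8, ("RR", EN, True): 0.4,
        ("RI", EN, False): 0.3, ("RR", EN, False): 0.3,
        ("RR", EX, True): 0.6, ("RI", EX, True): 0.3,
        ("RR", EX, False): 0.3, ("RI", EX, False): 0.3,
    }


def default_drift_slopes() -> dict:
    """Per-decile amplitude increments (session-progression drift)."""
    NP, EN, EX = (EventType.NOSE_POKE_ACTIVE, EventType.MAGAZINE_ENTRY,
                  EventType.MAGAZINE_EXIT)
    return {
        ("RI", NP): 0.03, ("RI", EN): 0.03,
        ("RR", NP): 0.015, ("RR", EN): 0.015,
        ("RR", EX): -0.02, ("RI", EX): -0.02,
    }


@dataclass(frozen=True)
class NeuralGenParams:
    """GCaMP6s-like trace generator parameters.

    The indicator kernel is a peak-normalized double exponential with
    the given rise/decay constants; transient amplitudes are in the same
    arbitrary units as the baseline ``f0``, so with the default f0 = 1 an
    amplitude approximates the peak ΔF/F it produces after
    preprocessing.  ``drift_slope_per_block`` adds ``block * slope`` to
    the base amplitude, where ``block`` (0-9) is the event's decile
    within its (event type, rewarded) class for the session.
    """

    f0: float = 1.0
    kernel_rise_s: float = 0.2
    kernel_decay_s: float = 1.0
    event_amplitudes: Mapping = field(default_factory=default_event_amplitudes)
    drift_slope_per_block: Mapping = field(default_factory=default_drift_slopes)
    noise_sd: float = 0.02  # same units as f0, i.i.d. Gaussian per frame
    fps: float = DEFAULT_FPS
    n_drift_blocks: int = 10
    max_duration_s: float = 7200.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.f0 > 0:
            raise ValueError("f0 must be > 0")
        if not self.kernel_decay_s > self.kernel_rise_s > 0:
            raise ValueError("need kernel_decay_s > kernel_rise_s > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class RawTrace:
    """Per-frame raw fluorescence, arbitrary units, strictly positive."""

    fps: float
    values: np.ndarray
    t0_s: float = 0.0

    @property
    def duration_s(self) -> float:
        return (len(self.values) - 1) / self.fps


def kernel_peak_lag_s(rise_s: float, decay_s: float) -> float:
    """Closed-form time-to-peak of the double-exponential kernel."""
    return (rise_s * decay_s / (decay_s - rise_s)) * math.log(decay_s / rise_s)


def _kernel(dt: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Double-exponential kernel normalized to peak value 1 (dt >= 0)."""
    t_peak = kernel_peak_lag_s(rise_s, decay_s)
    k0 = math.exp(-t_peak / decay_s) - math.exp(-t_peak / rise_s)
    return (np.exp(-dt / decay_s) - np.exp(-dt / rise_s)) / k0


def generate_trace(session: SessionRecord, params: NeuralGenParams,
                   seed: int | None = None) -> RawTrace:
    """Render a raw fluorescence trace for a simulated session.

    F_RAW(t) = f0 + Σ_events amplitude * K(t - t_event) + noise, clipped
    to a small positive floor.  Amplitudes depend on the session
    condition label, the event type/rewarded class, and the event's
    decile block within that class.
    """
    if not params.fps > 0:
        raise ValueError("fps must be > 0")
    if session.duration_s > params.max_duration_s:
        raise ValueError(
            f"session duration {session.duration_s:.0f}s exceeds "
            f"max_duration_s={params.max_duration_s:.0f}")
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)

    fps = params.fps
    n = int(math.floor(session.duration_s * fps)) + 1
    t = np.arange(n) / fps
    f = np.full(n, params.f0, dtype=float)

    support_s = 8.0 * params.kernel_decay_s
    n_support = int(math.ceil(support_s * fps))
    nb = params.n_drift_blocks
    cond = session.condition_label

    by_class: dict[tuple, list[float]] = {}
    for ev in session.events:
        by_class.setdefault((ev.event_type, ev.rewarded), []).append(ev.time_s)

    for (etype, rewarded), times in by_class.items():
        base = params.event_amplitudes.get((cond, etype, rewarded), 0.0)
        slope = params.drift_slope_per_block.get((cond, etype), 0.0)
        if base == 0.0 and slope == 0.0:
            continue
        n_class = len(times)
        for i, te in enumerate(times):
            block = (i * nb) // n_class  # 0..nb-1 decile index
            amp = max(0.0, base + block * slope)
            if amp == 0.0:
                continue
            i0 = int(math.ceil(te * fps - 1e-9))
            i0 = max(i0, 0)
            i1 = min(i0 + n_support, n)
            if i0 >= i1:
                continue
            f[i0:i1] += amp * _kernel(t[i0:i1] - te,
                                      params.kernel_rise_s,
                                      params.kernel_decay_s)

    if params.noise_sd > 0:
        f += rng.normal(0.0, params.noise_sd, n)
    np.maximum(f, 1e-3 * params.f0, out=f)
    return RawTrace(fps=fps, values=f, t0_s=0.0)
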