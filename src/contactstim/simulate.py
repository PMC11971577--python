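"""Synthetic operant behavior and landmark streams.

The generator exists so that every other module is testable without a camera,
hardware, or human participants.  It models a participant's *attempts* to
touch the desk objects as a phase-conditional Poisson process — baseline
1.0 attempts/min, intervention 3.5/min (values chosen so recorded per-session
counts land in the study's printed per-phase ranges of roughly 3-6.5 and
10-19.5 once the 10-s post-response lockout is applied), control 0.8/min
(responding declines under response-independent stimulation).  This is a
model of the *system under test*, not of operant acquisition: the intervention
rate is simply higher, standing in for contingency-driven responding; an
optional within-phase rate ramp is available as a learning-curve hook but off
by default.

Alerting events transiently raise the attempt hazard by a multiplicative
factor (``alert_boost``, default 2.0) that decays exponentially
(``alert_decay_s``, default 10 s) — an invented, unvalidated transient meant
to emulate the vigilance function of alerts.  Because alerts depend on
responses and responses on attempts, sessions are generated by an event-level
closed-loop co-simulation that mirrors the engine's alert clock (same seed,
same draw sequence), then rendered to a landmark stream and run through the
real detector and engine; all recorded counts come from the engine.

Attempts are rendered as the five fingertips entering a randomly chosen
region, dwelling 0.5-2 s, and leaving, with sub-threshold positional jitter;
between attempts the hand rests outside all regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from shapely.geometry import Point

from .analysis import PhaseSeries
from .detection import FINGERTIP_LANDMARKS, DetectorConfig, ObjectRegion
from .engine import SessionConfig, SessionLog, response_frequency, run_session
from .streams import ArrayFrameStream

PhaseType = Literal["baseline", "intervention", "control"]


@dataclass(frozen=True)
class BehaviorModel:
    """Phase-conditional attempt process (rates in attempts per minute)."""

    baseline_rate: float = 1.0
    intervention_rate: float = 3.5
    control_rate: float = 0.8
    alert_boost: float = 2.0
    alert_decay_s: float = 10.0
    #: Learning-curve hook: linear ramp multiplier applied across the first
    #: intervention phase (1.0 = off).
    intervention_ramp: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.baseline_rate, self.intervention_rate, self.control_rate) < 0:
            raise ValueError("rates must be >= 0")
        if self.alert_boost < 1.0:
            raise ValueError("alert_boost must be >= 1")

    def rate_for(self, phase_type: str) -> float:
        return {
            "baseline": self.baseline_rate,
            "intervention": self.intervention_rate,
            "control": self.control_rate,
        }[phase_type]


@dataclass(frozen=True)
class PhaseDesign:
    """Sessions per phase of the ABACB sequence.

    The default is a desk-scale mini-study: the minimum printed lengths for
    A1/B1/A2/C and a shortened Intervention II (the study ran 43-74 sessions
    there; 15 keeps simulations tractable and PEM well-defined).
    """

    a1: int = 5
    b1: int = 15
    a2: int = 5
    c: int = 5
    b2: int = 15

    def schedule(self) -> list[tuple[str, PhaseType, int]]:
        return [
            ("A1", "baseline", self.a1),
            ("B1", "intervention", self.b1),
            ("A2", "baseline", self.a2),
            ("C", "control", self.c),
            ("B2", "intervention", self.b2),
        ]


def default_regions() -> tuple[ObjectRegion, ...]:
    """Two desk objects in fixed positions (image-normalized footprints)."""
    return (
        ObjectRegion.from_bbox("left_object", 0.20, 0.55, 0.35, 0.75, label="sponge"),
        ObjectRegion.from_bbox("right_object", 0.65, 0.55, 0.80, 0.75, label="small box"),
    )


def default_session_config(
    participant_id: str = "sim",
    phase_type: PhaseType = "baseline",
    rng_seed: int = 0,
    fps: float = 10.0,
    regions: Sequence[ObjectRegion] | None = None,
) -> SessionConfig:
    """Session config matched to the simulator's frame rate.

    Debounce/release are set to 0.2 s worth of frames at ``fps`` (the library
    default of 3 frames assumes a >= 15 fps camera).
    """
    frames = max(1, round(0.2 * fps))
    return SessionConfig(
        participant_id=participant_id,
        phase_type=phase_type,
        regions=tuple(regions) if regions is not None else default_regions(),
        detector=DetectorConfig(debounce_frames=frames, release_frames=frames),
        rng_seed=rng_seed,
    )


def _hazard(t: float, rate_s: float, boost: float, tau: float, last_alert: float) -> float:
    if last_alert < 0 or boost == 1.0:
        return rate_s
    return rate_s * (1.0 + (boost - 1.0) * math.exp(-(t - last_alert) / tau))


def simulate_attempts(
    model: BehaviorModel,
    phase_type: PhaseType,
    duration_s: float,
    seed: int | np.random.Generator,
    alert_times: Sequence[float] = (),
) -> np.ndarray:
    """Open-loop attempt timestamps for one session (Ogata thinning).

    The attempt process is homogeneous Poisson at the phase rate, with the
    hazard transiently multiplied by ``alert_boost`` (exponentially decaying)
    after each of the given ``alert_times``.  Seeded and reproducible.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate_s = model.rate_for(phase_type) / 60.0
    if rate_s <= 0:
        return np.empty(0)
    lam_max = rate_s * model.alert_boost
    alerts = sorted(alert_times)
    out: list[float] = []
    t = 0.0
    ai = 0
    last_alert = -1.0
    while True:
        t += rng.exponential(1.0 / lam_max)
        if t >= duration_s:
            break
        while ai < len(alerts) and alerts[ai] <= t:
            last_alert = alerts[ai]
            ai += 1
        lam = _hazard(t, rate_s, model.alert_boost, model.alert_decay_s, last_alert)
        if rng.uniform() * lam_max < lam:
            out.append(t)
    return np.asarray(out)


def cosimulate_session(
    model: BehaviorModel,
    cfg: SessionConfig,
    attempt_rng: np.random.Generator,
    min_hold_s: float = 0.2,
    rate_scale: float = 1.0,
) -> tuple[list[tuple[float, float]], list[float]]:
    """Closed-loop event simulation of one session's behavior.

    Returns ``(attempts, alerts)`` where attempts are ``(time, dwell_s)``
    pairs.  The alert clock replicates the engine's (same seed, same uniform
    draw sequence: one draw at session start, one after every recorded
    response and every fired alert), so the boost feedback sees alerts at —
    up to frame quantization — the times the engine will log.  Lockout
    filtering is applied as the engine will apply it, including a response at
    lockout end when a touch begun during lockout is still held at least
    ``min_hold_s`` past it (the debounce time).
    """
    alert_rng = np.random.default_rng(cfg.rng_seed)
    lo, hi = cfg.alert_window_s
    draw = lambda: round(float(alert_rng.uniform(lo, hi)), 3)

    duration = cfg.session_duration_s
    lockout = float(cfg.lockout_s)
    rate_s = model.rate_for(cfg.phase_type) * rate_scale / 60.0
    boost, tau = model.alert_boost, model.alert_decay_s
    lam_max = rate_s * boost if rate_s > 0 else 0.0

    attempts: list[tuple[float, float]] = []
    alerts: list[float] = []
    last_alert = -1.0
    next_alert = draw()
    lockout_until = -1.0
    contact_until = -1.0
    cross_at = math.inf  # pending response at lockout end (touch held across it)
    next_cand = (
        attempt_rng.exponential(1.0 / lam_max) if lam_max > 0 else math.inf
    )

    while True:
        nxt = min(next_cand, next_alert, cross_at)
        if nxt >= duration:
            break
        if cross_at <= min(next_cand, next_alert):
            t = cross_at
            cross_at = math.inf
            lockout_until = t + lockout
            next_alert = t + draw()
            continue
        if next_alert <= next_cand:
            t = next_alert
            if t < lockout_until:  # cannot fire during a monitoring halt
                next_alert = lockout_until
                continue
            alerts.append(t)
            last_alert = t
            next_alert = t + draw()
            continue
        t = next_cand
        next_cand = t + attempt_rng.exponential(1.0 / lam_max)
        lam = _hazard(t, rate_s, boost, tau, last_alert)
        if attempt_rng.uniform() * lam_max >= lam:
            continue  # thinned candidate
        dwell = float(attempt_rng.uniform(0.5, 2.0))
        attempts.append((t, dwell))
        contact_until = max(contact_until, t + dwell)
        if t >= lockout_until:
            # recorded response: lockout starts, alert clock resets
            lockout_until = t + lockout
            next_alert = t + draw()
            cross_at = math.inf
        elif contact_until >= lockout_until + min_hold_s:
            cross_at = lockout_until

    return attempts, alerts


_FINGER_OFFSETS = np.array(
    [
        (-0.012, 0.004),
        (-0.006, -0.008),
        (0.000, -0.010),
        (0.006, -0.008),
        (0.012, 0.004),
    ]
)

_SAFE_MARGIN = 0.03  # centroid clearance needed to guarantee containment
_OUT_MARGIN = 0.035  # rest/approach clearance to guarantee non-contact
_JITTER_SD = 0.003
_JITTER_CLIP = 0.012
_APPROACH_S = 0.3


def _rest_point(regions: Sequence[ObjectRegion]) -> np.ndarray:
    for cand in ((0.5, 0.2), (0.5, 0.1), (0.1, 0.1), (0.9, 0.1), (0.5, 0.9)):
        if all(r.shape.distance(Point(cand)) > _OUT_MARGIN for r in regions):
            return np.asarray(cand)
    raise ValueError("could not place a rest point outside all regions")


def _dwell_center(region: ObjectRegion) -> np.ndarray:
    c = region.shape.centroid
    if region.shape.exterior.distance(c) >= _SAFE_MARGIN:
        return np.array([c.x, c.y])
    p = region.shape.representative_point()
    return np.array([p.x, p.y])


def _approach_point(
    region: ObjectRegion, rest: np.ndarray, regions: Sequence[ObjectRegion]
) -> np.ndarray:
    """A point just outside ``region`` on the way from the rest position."""
    center = _dwell_center(region)
    for s in np.linspace(0.05, 1.0, 20):
        p = center + s * (rest - center)
        if all(r.shape.distance(Point(p)) > _OUT_MARGIN for r in regions):
            return p
    return rest


def _merge_intervals(
    attempts: Sequence[tuple[float, float]], region_choices: Sequence[int]
) -> list[tuple[float, float, int]]:
    """Union of dwell intervals; overlaps merge into one contact run."""
    spans = sorted(
        (t, t + d, region_choices[i]) for i, (t, d) in enumerate(attempts)
    )
    merged: list[tuple[float, float, int]] = []
    for s, e, r in spans:
        if merged and s <= merged[-1][1]:
            ps, pe, pr = merged[-1]
            merged[-1] = (ps, max(pe, e), pr)  # keep the first attempt's region
        else:
            merged.append((s, e, r))
    return merged


def attempts_to_landmark_stream(
    attempts: Sequence[tuple[float, float]] | Sequence[float] | np.ndarray,
    regions: Sequence[ObjectRegion],
    fps: float,
    seed: int | np.random.Generator,
    duration_s: float = 300.0,
) -> ArrayFrameStream:
    """Render attempts as a fingertip landmark stream at ``fps``.

    ``attempts`` may be bare timestamps (dwells are then drawn uniformly from
    0.5-2 s) or ``(time, dwell)`` pairs.  Each attempt targets a uniformly
    chosen region; overlapping dwells merge into one contact run.  Jitter is
    clipped well below the geometric margins, so containment during a dwell
    (and non-contact outside one) is exact.
    """
    if fps < 5:
        raise ValueError("fps must be >= 5")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    attempts = list(attempts)
    pairs: list[tuple[float, float]] = []
    for a in attempts:
        if np.ndim(a) == 0:
            pairs.append((float(a), float(rng.uniform(0.5, 2.0))))
        else:
            pairs.append((float(a[0]), float(a[1])))

    n = int(round(duration_s * fps))
    ts = np.arange(n) / fps
    rest = _rest_point(regions)
    centers = np.tile(rest, (n, 1))

    choices = rng.integers(0, len(regions), size=len(pairs)) if pairs else []
    merged = _merge_intervals(pairs, list(choices))

    # pass 1: approach / retreat ramps (kept outside every region)
    for s, e, ri in merged:
        approach = _approach_point(regions[ri], rest, regions)
        for lo_t, hi_t, p0, p1 in (
            (s - _APPROACH_S, s, rest, approach),
            (e, e + _APPROACH_S, approach, rest),
        ):
            mask = (ts >= lo_t) & (ts < hi_t)
            if mask.any():
                frac = ((ts[mask] - lo_t) / _APPROACH_S)[:, None]
                centers[mask] = p0 * (1 - frac) + p1 * frac
    # pass 2: dwells win over any overlapping ramp
    for s, e, ri in merged:
        mask = (ts >= s) & (ts <= e)
        centers[mask] = _dwell_center(regions[ri])

    jitter = np.clip(
        rng.normal(0.0, _JITTER_SD, size=(n, len(_FINGER_OFFSETS), 2)),
        -_JITTER_CLIP,
        _JITTER_CLIP,
    )
    coords = np.clip(centers[:, None, :] + _FINGER_OFFSETS[None, :, :] + jitter, 0.0, 1.0)
    return ArrayFrameStream(
        timestamps=ts,
        landmark_names=FINGERTIP_LANDMARKS,
        coords=coords,
        hand_id="right",
    )


@dataclass
class StudyResult:
    """Everything a simulated ABACB study produced."""

    series: PhaseSeries
    logs: dict[str, list[SessionLog]] = field(default_factory=dict)
    configs: dict[str, list[SessionConfig]] = field(default_factory=dict)
    model: BehaviorModel | None = None
    design: PhaseDesign | None = None
    seed: int | None = None


def simulate_session(
    model: BehaviorModel,
    cfg: SessionConfig,
    fps: float = 10.0,
    attempt_seed: int | np.random.Generator = 0,
    stream_seed: int | np.random.Generator = 1,
    rate_scale: float = 1.0,
) -> tuple[SessionLog, ArrayFrameStream]:
    """Co-simulate behavior, render the stream, and run the real engine."""
    attempt_rng = (
        attempt_seed
        if isinstance(attempt_seed, np.random.Generator)
        else np.random.default_rng(attempt_seed)
    )
    min_hold = cfg.detector.debounce_frames / fps
    attempts, _alerts = cosimulate_session(
        model, cfg, attempt_rng, min_hold_s=min_hold, rate_scale=rate_scale
    )
    stream = attempts_to_landmark_stream(
        attempts, cfg.regions, fps, stream_seed, duration_s=cfg.session_duration_s
    )
    log = run_session(cfg, stream)
    return log, stream


def simulate_study(
    model: BehaviorModel | None = None,
    design: PhaseDesign | None = None,
    participant_id: str = "sim",
    seed: int = 0,
    fps: float = 10.0,
    regions: Sequence[ObjectRegion] | None = None,
    keep_logs: bool = True,
) -> StudyResult:
    """Run a full synthetic ABACB study through the real engine, per session.

    Seeded end-to-end: per-session alert/attempt/stream seeds are drawn from
    one master generator, so the same ``seed`` reproduces the identical study.
    """
    model = model or BehaviorModel()
    design = design or PhaseDesign()
    master = np.random.default_rng(seed)
    phases: list[tuple[str, list[int]]] = []
    logs: dict[str, list[SessionLog]] = {}
    configs: dict[str, list[SessionConfig]] = {}
    for label, phase_type, n_sessions in design.schedule():
        counts: list[int] = []
        logs[label] = []
        configs[label] = []
        for k in range(n_sessions):
            alert_seed, attempt_seed, stream_seed = (
                int(s) for s in master.integers(0, 2**31, size=3)
            )
            cfg = default_session_config(
                participant_id=participant_id,
                phase_type=phase_type,
                rng_seed=alert_seed,
                fps=fps,
                regions=regions,
            )
            ramp = 1.0
            if label == "B1" and model.intervention_ramp != 1.0 and n_sessions > 1:
                # linear ramp from 1/ramp up to full rate across Intervention I
                frac = k / (n_sessions - 1)
                ramp = (1.0 / model.intervention_ramp) * (1 - frac) + 1.0 * frac
            log, _stream = simulate_session(
                model,
                cfg,
                fps=fps,
                attempt_seed=attempt_seed,
                stream_seed=stream_seed,
                rate_scale=ramp,
            )
            counts.append(response_frequency(log))
            if keep_logs:
                logs[label].append(log)
                configs[label].append(cfg)
        phases.append((label, counts))
    series = PhaseSeries(participant_id=participant_id, phases=phases)
    return StudyResult(
        series=series,
        logs=logs if keep_logs else {},
        configs=configs if keep_logs else {},
        model=model,
        design=design,
        seed=seed,
    )
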