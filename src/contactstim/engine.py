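"""Deterministic session state machine for contingent stimulation.

One session lasts ``session_duration_s`` (default 300 s = 5 min) and runs in
one of three phases:

* **baseline** — responses are recorded and alerting events are presented
  after 30-40 s of no responding, but no stimulation follows responses;
* **intervention** — each recorded response additionally triggers a 10-s
  period of preferred stimulation, delivered immediately;
* **control** — stimulation plays continuously for the whole session
  (changing every ``control_change_s`` to limit habituation) and responses,
  while logged, never trigger anything.

After every recorded response — in *every* phase, for cross-phase consistency
— hand-position monitoring is halted for ``lockout_s`` (coupled to the
stimulation duration, default 10 s) so no new response can be recorded; a
sustained touch therefore counts once, and the structural ceiling on responses
per session is ``ceil(session_duration_s / lockout_s)`` (30 by default).

The engine is a pure function of (config, seed, frame stream): the only
randomness is the alert-interval draw, taken uniformly from
``alert_window_s`` with a seeded generator, so identical inputs give
byte-identical logs and a replay with a different seed can move alerts but
never responses.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .actuation import MockActuator, MockSmartPlug, StimulusDescriptor
from .detection import (
    ContactDebouncer,
    DetectorConfig,
    LandmarkFrame,
    ObjectRegion,
    contact_series,
    iter_checked,
)
from .errors import (
    ActuatorError,
    LogParseError,
    ReplayMismatchError,
    TruncationError,
)
from .streams import ArrayFrameStream, read_frames_jsonl

PhaseType = Literal["baseline", "intervention", "control"]

#: Event ordering at equal timestamps (stim_off of a previous response sorts
#: before the next response that becomes possible at the same instant).
_EVENT_PRIORITY = {
    "session_start": 0,
    "stim_off": 1,
    "alert": 2,
    "response": 3,
    "stim_on": 4,
    "stim_change": 5,
    "contact_ignored": 6,
    "session_end": 9,
}

EVENT_TYPES = tuple(_EVENT_PRIORITY)


def _default_stimuli() -> tuple[StimulusDescriptor, ...]:
    return (StimulusDescriptor(stimulus_id="preferred_music", modality="audio"),)


def _default_alerts() -> tuple[StimulusDescriptor, ...]:
    return (
        StimulusDescriptor(
            stimulus_id="verbal_encouragement", modality="audio", duration_s=2.0
        ),
    )


class SessionConfig(BaseModel):
    """All memorized per-participant session parameters.

    The same config is applied across every session of a participant so that
    conditions stay identical; only ``phase_type`` and ``rng_seed`` change
    between sessions.  ``lockout_s`` is coupled to ``stim_duration_s`` (the
    post-response monitoring halt equals the stimulation period in all
    phases); leaving it None adopts the coupling, setting it to a different
    value is a validation error.
    """

    model_config = ConfigDict(frozen=True)

    participant_id: str
    phase_type: PhaseType = "baseline"
    session_duration_s: float = Field(default=300.0, gt=0)
    stim_duration_s: float = Field(default=10.0, gt=0)
    lockout_s: Optional[float] = None
    alert_window_s: tuple[float, float] = (30.0, 40.0)
    control_change_s: float = Field(default=60.0, gt=0)
    regions: tuple[ObjectRegion, ...] = Field(min_length=1)
    detector: DetectorConfig = Field(default_factory=DetectorConfig)
    stimuli: tuple[StimulusDescriptor, ...] = Field(default_factory=_default_stimuli)
    alert_events: tuple[StimulusDescriptor, ...] = Field(default_factory=_default_alerts)
    rng_seed: int = 0
    coverage_tolerance_s: float = Field(default=1.0, ge=0)
    #: Human-procedure annotation only (practice touches guided before the
    #: session); never logged as responses.
    practice_trials: Optional[int] = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _check_couplings(self) -> "SessionConfig":
        if self.stim_duration_s > self.session_duration_s:
            raise ValueError("stim_duration_s must not exceed session_duration_s")
        if self.lockout_s is None:
            object.__setattr__(self, "lockout_s", self.stim_duration_s)
        elif self.lockout_s != self.stim_duration_s:
            raise ValueError(
                "lockout_s is coupled to stim_duration_s (the post-response "
                "monitoring halt equals the stimulation period in all phases)"
            )
        lo, hi = self.alert_window_s
        if not (0 < lo <= hi):
            raise ValueError("alert_window_s must satisfy 0 < min <= max")
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate region ids: {ids}")
        return self


def config_hash(cfg: SessionConfig) -> str:
    """Stable sha256 over the canonical JSON form of a config."""
    payload = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


@dataclass(frozen=True)
class Event:
    t: float
    type: str
    payload: dict = field(default_factory=dict)


@dataclass
class SessionLog:
    """Ordered, typed record of everything that happened in one session."""

    header: dict
    events: list[Event]

    def of_type(self, event_type: str) -> list[Event]:
        return [e for e in self.events if e.type == event_type]

    @property
    def response_times(self) -> list[float]:
        return [e.t for e in self.of_type("response")]

    @property
    def alert_times(self) -> list[float]:
        return [e.t for e in self.of_type("alert")]


def response_frequency(log: SessionLog) -> int:
    """Number of recorded responses in a session log."""
    if not isinstance(log, SessionLog):
        raise LogParseError(f"expected a SessionLog, got {type(log).__name__}")
    for e in log.events:
        if e.type not in _EVENT_PRIORITY:
            raise LogParseError(f"unknown event type {e.type!r} at t={e.t}")
    return len(log.of_type("response"))


def _materialize(frame_source, detector: DetectorConfig, regions):
    """Evaluate contact for the whole stream; returns (ts, in_contact, region_ids)."""
    subset = frozenset(detector.landmark_subset) if detector.landmark_subset else None
    if isinstance(frame_source, ArrayFrameStream):
        ts = frame_source.timestamps
        from .detection import series_from_points

        frame_idx, xs, ys = frame_source.flat_points(subset)
        in_contact, ids = series_from_points(
            frame_idx, xs, ys, len(ts), regions, detector
        )
        return ts, in_contact, ids
    frames = list(iter_checked(frame_source))
    ts = np.asarray([f.timestamp for f in frames], dtype=float)
    in_contact, ids = contact_series(frames, regions, detector)
    return ts, in_contact, ids


def run_session(
    cfg: SessionConfig,
    frame_source: Iterable[LandmarkFrame] | ArrayFrameStream,
    actuator: MockActuator | None = None,
    plug: MockSmartPlug | None = None,
) -> SessionLog:
    """Run one session over a landmark stream and return its event log.

    The frame source must cover the session duration (to within
    ``coverage_tolerance_s``); otherwise a :class:`TruncationError` names the
    last covered timestamp.  Response timestamps are back-dated to the
    contact-onset frame; an alert whose due time falls while a debounce streak
    is still unconfirmed is held back until the streak resolves, so an alert
    can precede a response but never trails one within the alert window.
    """
    actuator = actuator or MockActuator()
    duration = cfg.session_duration_s
    lockout_s = float(cfg.lockout_s)  # validator guarantees it is set
    ts, in_contact, region_ids = _materialize(frame_source, cfg.detector, cfg.regions)

    if ts.size == 0:
        raise TruncationError(last_covered_s=0.0, required_s=duration)
    last_covered = float(ts[-1])
    if last_covered < duration - cfg.coverage_tolerance_s:
        raise TruncationError(last_covered_s=last_covered, required_s=duration)

    events: list[Event] = [Event(0.0, "session_start", {})]
    add = events.append

    rng = np.random.default_rng(cfg.rng_seed)
    lo, hi = cfg.alert_window_s

    def draw() -> float:
        # 3-decimal draws keep log timestamps exact under the serialization
        # contract, so inter-alert gaps are >= lo exactly.
        return round(float(rng.uniform(lo, hi)), 3)

    def dispatch(desc: StimulusDescriptor, dur: float, at: float) -> dict:
        """Fail-open actuator dispatch; returns extra payload on failure."""
        extra: dict = {}
        try:
            report = actuator.play(desc, dur, at_time=at)
            if not report.ok:
                extra["actuator_error"] = report.error or "playback failed"
        except ActuatorError as exc:
            extra["actuator_error"] = str(exc)
        if plug is not None and desc.modality in ("light", "airflow"):
            try:
                plug.switch(True, desc.source or "default")
            except ActuatorError as exc:
                extra["actuator_error"] = str(exc)
        return extra

    def plug_off(desc: StimulusDescriptor) -> None:
        if plug is not None and desc.modality in ("light", "airflow"):
            try:
                plug.switch(False, desc.source or "default")
            except ActuatorError:
                pass  # fail-open

    alert_idx = 0

    def fire_alert(at: float) -> None:
        nonlocal alert_idx
        desc = cfg.alert_events[alert_idx % len(cfg.alert_events)] if cfg.alert_events else None
        payload: dict = {}
        if desc is not None:
            payload["alert_id"] = desc.stimulus_id
            alert_len = min(desc.duration_s or 2.0, duration - at)
            payload.update(dispatch(desc, alert_len, at))
        add(Event(round(at, 3), "alert", payload))

    # Control phase: continuous, response-independent stimulation with
    # periodic changes; scheduled up front since it does not depend on frames.
    if cfg.phase_type == "control":
        starts = [0.0]
        k = 1
        while k * cfg.control_change_s < duration:
            starts.append(k * cfg.control_change_s)
            k += 1
        for seg, start in enumerate(starts):
            end = starts[seg + 1] if seg + 1 < len(starts) else duration
            desc = cfg.stimuli[seg % len(cfg.stimuli)]
            extra = dispatch(desc, end - start, start)
            payload = {"stimulus_id": desc.stimulus_id, **extra}
            add(Event(round(start, 3), "stim_on" if seg == 0 else "stim_change", payload))
            plug_off(desc)
        add(Event(round(duration, 3), "stim_off", {"stimulus_id": cfg.stimuli[(len(starts) - 1) % len(cfg.stimuli)].stimulus_id}))

    deb = ContactDebouncer(cfg.detector.debounce_frames, cfg.detector.release_frames)
    next_alert = draw()
    lockout_until = -math.inf
    was_in_lockout = False
    ignored_active = False
    n_responses = 0
    stim_idx = 0
    intervention = cfg.phase_type == "intervention"

    ts_l = ts.tolist()
    contact_l = in_contact.tolist()

    for i, t in enumerate(ts_l):
        if t >= duration:
            break
        if t < lockout_until:
            # Monitoring halted: no detection, no alerts; raw contact is
            # audited as non-counted contact_ignored events (rising edge).
            was_in_lockout = True
            if contact_l[i]:
                if not ignored_active:
                    add(Event(round(t, 3), "contact_ignored", {"region_id": region_ids[i]}))
                    ignored_active = True
            else:
                ignored_active = False
            continue
        if was_in_lockout:
            deb.reset()  # an ongoing touch becomes a fresh onset
            was_in_lockout = False
            ignored_active = False
        onset = deb.update(t, contact_l[i], region_ids[i])
        if onset is not None:
            t0, region = onset
            t0 = round(t0, 3)
            # Alerts legitimately due before the (back-dated) onset fire first.
            while next_alert <= t0 and next_alert < duration:
                if next_alert < lockout_until:
                    next_alert = lockout_until  # never inside a monitoring halt
                    continue
                fire_alert(next_alert)
                next_alert = next_alert + draw()
            n_responses += 1
            add(Event(t0, "response", {"region_id": region, "index": n_responses}))
            if intervention:
                desc = cfg.stimuli[stim_idx % len(cfg.stimuli)]
                stim_idx += 1
                stim_end = round(min(t0 + cfg.stim_duration_s, duration), 3)
                extra = dispatch(desc, stim_end - t0, t0)
                add(Event(t0, "stim_on", {"stimulus_id": desc.stimulus_id, **extra}))
                add(Event(stim_end, "stim_off", {"stimulus_id": desc.stimulus_id}))
                plug_off(desc)
            lockout_until = t0 + lockout_s
            next_alert = t0 + draw()  # response resets the no-response clock
            # the touch that triggered this response is still the same contact
            # run; only contacts *begun* during the halt are audited
            ignored_active = True
        elif not deb.pending:
            # Fire alerts only when no unconfirmed contact streak could still
            # back-date a response underneath the alert.
            while next_alert <= t and next_alert < duration:
                if next_alert < lockout_until:
                    next_alert = lockout_until  # deferred to lockout end
                    continue
                fire_alert(next_alert)
                next_alert = next_alert + draw()

    # Alerts still due between the last frame and session end.
    while next_alert < duration:
        if next_alert < lockout_until:
            next_alert = lockout_until
            continue
        fire_alert(next_alert)
        next_alert = next_alert + draw()

    add(Event(round(duration, 3), "session_end", {"responses": n_responses}))
    events.sort(key=lambda e: (e.t, _EVENT_PRIORITY[e.type]))

    header = {
        "participant_id": cfg.participant_id,
        "phase_type": cfg.phase_type,
        "config_hash": config_hash(cfg),
        "seed": cfg.rng_seed,
        "session_duration_s": duration,
        "start_time_s": 0.0,
    }
    return SessionLog(header=header, events=events)


def replay(
    frames: str | Path | Iterable[LandmarkFrame] | ArrayFrameStream,
    cfg: SessionConfig,
    reference: SessionLog | None = None,
    actuator: MockActuator | None = None,
) -> SessionLog:
    """Re-run a recorded frame stream under a config.

    With ``reference`` given, the config must hash-match the reference log's
    header (same memorized parameters); seeded determinism then guarantees a
    bit-identical event list.  Raises :class:`ReplayMismatchError` otherwise.
    """
    if reference is not None:
        expected = reference.header.get("config_hash")
        actual = config_hash(cfg)
        if expected != actual:
            raise ReplayMismatchError(
                f"config hash {actual[:12]}... does not match log header "
                f"{str(expected)[:12]}...; refusing to replay under different "
                "memorized parameters"
            )
    if isinstance(frames, (str, Path)):
        frames = read_frames_jsonl(frames)
    return run_session(cfg, frames, actuator=actuator)
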