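"""Delivery of preferred stimulation and alerting events.

The study hardware is a Bluetooth mini speaker plus an optional smart Wi-Fi
plug for lights or mild airflows; both are commodity devices.  The package
therefore abstracts them behind one contract and ships inert mock
implementations that record everything for inspection — the computational
contribution is the contingency logic, not the drivers.  Actuator failures are
fail-open by design: a broken speaker must never abort a session.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ActuatorError

Modality = Literal["audio", "light", "airflow", "composite"]


class StimulusDescriptor(BaseModel):
    """One preferred stimulus (or alerting event) in the session playlist.

    ``source`` is a media file path or device channel; None means a synthetic
    / mock source (legal in tests and simulations).  ``composite`` stimuli
    (e.g. music combined with lights) list >= 2 children that are started
    simultaneously.
    """

    model_config = ConfigDict(frozen=True)

    stimulus_id: str
    modality: Modality = "audio"
    source: Optional[str] = None
    gain: float = Field(default=1.0, ge=0.0)
    duration_s: Optional[float] = Field(default=None, gt=0.0)
    children: tuple["StimulusDescriptor", ...] = ()

    @model_validator(mode="after")
    def _check_composite(self) -> "StimulusDescriptor":
        if self.modality == "composite" and len(self.children) < 2:
            raise ValueError(
                f"composite stimulus {self.stimulus_id!r} needs >= 2 children"
            )
        if self.modality != "composite" and self.children:
            raise ValueError(
                f"stimulus {self.stimulus_id!r}: children only allowed for composite"
            )
        return self


@dataclass(frozen=True)
class PlayReport:
    """Record of one play() call; ``ok`` False means fail-open error."""

    stimulus_id: str
    started_at: float
    stopped_at: float
    ok: bool = True
    error: str | None = None
    children: tuple["PlayReport", ...] = ()

    @property
    def playtime_s(self) -> float:
        return self.stopped_at - self.started_at


class MockActuator:
    """Inert reference actuator: records (descriptor, start, stop) triples.

    With ``verify_sources=True`` an audio descriptor whose ``source`` path does
    not exist yields an error report with zero playtime (the failure path a
    real speaker adapter would hit); the default never touches the filesystem.
    """

    def __init__(self, verify_sources: bool = False):
        self.verify_sources = verify_sources
        self.records: list[PlayReport] = []

    def play(
        self,
        descriptor: StimulusDescriptor,
        duration_s: float,
        at_time: float = 0.0,
    ) -> PlayReport:
        """Start ``descriptor`` at (simulated) time ``at_time`` for ``duration_s``.

        Composite stimuli fan out to their children with a synchronized start;
        the parent report is ok only if every child is.
        """
        if descriptor.modality == "composite":
            child_reports = tuple(
                self.play(child, duration_s, at_time) for child in descriptor.children
            )
            report = PlayReport(
                stimulus_id=descriptor.stimulus_id,
                started_at=at_time,
                stopped_at=at_time + duration_s,
                ok=all(r.ok for r in child_reports),
                children=child_reports,
            )
            return report
        if (
            self.verify_sources
            and descriptor.modality == "audio"
            and descriptor.source is not None
            and not os.path.exists(descriptor.source)
        ):
            report = PlayReport(
                stimulus_id=descriptor.stimulus_id,
                started_at=at_time,
                stopped_at=at_time,  # zero playtime
                ok=False,
                error=f"missing audio source: {descriptor.source}",
            )
            self.records.append(report)
            return report
        report = PlayReport(
            stimulus_id=descriptor.stimulus_id,
            started_at=at_time,
            stopped_at=at_time + duration_s,
        )
        self.records.append(report)
        return report

    def total_playtime_s(self) -> float:
        """Sum of successful playtimes (top-level composites excluded — their
        children are recorded individually)."""
        return sum(r.playtime_s for r in self.records if r.ok)


@dataclass
class PlugState:
    on: bool = False
    cycles: int = 0  # completed on->off cycles


class MockSmartPlug:
    """Inspectable stand-in for the smart Wi-Fi plug controlling lights/airflow.

    Commands are idempotent: switching an already-on channel on again is a
    no-op.  Unconfigured channels raise :class:`ActuatorError` (callers treat
    it as fail-open).
    """

    def __init__(self, channels: tuple[str, ...] = ("default",)):
        self.states: dict[str, PlugState] = {c: PlugState() for c in channels}
        self.commands: list[tuple[str, bool]] = []

    def switch(self, on: bool, channel: str = "default") -> dict:
        if channel not in self.states:
            raise ActuatorError(f"plug channel {channel!r} is not configured")
        state = self.states[channel]
        self.commands.append((channel, on))
        if on == state.on:
            return {"channel": channel, "on": state.on, "changed": False}
        if not on:
            state.cycles += 1
        state.on = on
        return {"channel": channel, "on": state.on, "changed": True}


def play(
    descriptor: StimulusDescriptor,
    duration_s: float,
    actuator: MockActuator | None = None,
    at_time: float = 0.0,
) -> PlayReport:
    """Module-level convenience over an actuator's :meth:`~MockActuator.play`."""
    actuator = actuator or MockActuator()
    return actuator.play(descriptor, duration_s, at_time)


def switch_plug(
    on: bool, channel: str = "default", plug: MockSmartPlug | None = None
) -> dict:
    plug = plug or MockSmartPlug()
    return plug.switch(on, channel)
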