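"""Configuration persistence, log I/O, and study bundles.

File formats are deliberately human-auditable and diff-able — this is a
clinical-adjacent tool and its session records should survive review:

* configs: schema-versioned JSON (``schema_version`` = "1"), stable key order;
* session logs: a JSON header line followed by one event per line (JSONL),
  timestamps as seconds-from-session-start floats with 3 decimals;
* analysis tables: CSV;
* a *study bundle* is a directory holding the configs, logs, phase map and a
  manifest with config hashes and seeds, so any log can be traced back to the
  exact memorized parameters that produced it.

All outputs are deterministic given seeds and inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from pydantic import ValidationError

from .analysis import PhaseSeries
from .engine import Event, SessionConfig, SessionLog, config_hash
from .errors import ConfigurationError, LogParseError, UnsupportedSchemaError

SCHEMA_VERSION = "1"


def save_config(cfg: SessionConfig, path: str | Path) -> None:
    """Write a schema-versioned JSON config (round-trips via load_config)."""
    payload = {"schema_version": SCHEMA_VERSION, "config": cfg.model_dump(mode="json")}
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")


def load_config(path: str | Path) -> SessionConfig:
    """Read and validate a config file.

    Raises :class:`UnsupportedSchemaError` for unknown schema versions and
    :class:`ConfigurationError` listing the offending fields on validation
    failure.
    """
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"{path}: not valid JSON: {exc}")
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise UnsupportedSchemaError(
            f"{path}: schema version {version!r} is not supported "
            f"(expected {SCHEMA_VERSION!r})"
        )
    try:
        return SessionConfig.model_validate(payload.get("config", {}))
    except ValidationError as exc:
        fields = ", ".join(
            ".".join(str(p) for p in err["loc"]) or "<root>" for err in exc.errors()
        )
        raise ConfigurationError(f"{path}: invalid config fields: {fields}\n{exc}")


def validate_sources(cfg: SessionConfig) -> list[str]:
    """Check that audio stimulus sources exist on disk; returns missing paths."""
    missing: list[str] = []

    def walk(descriptors) -> None:
        for d in descriptors:
            if d.modality == "audio" and d.source is not None:
                if not Path(d.source).exists():
                    missing.append(d.source)
            walk(d.children)

    walk(cfg.stimuli)
    walk(cfg.alert_events)
    return missing


def write_log_jsonl(log: SessionLog, path: str | Path) -> None:
    """Header line + one event per line, 3-decimal timestamps, stable keys."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(json.dumps({"header": log.header}, sort_keys=True) + "\n")
        for e in log.events:
            fh.write(
                json.dumps(
                    {"t": round(e.t, 3), "event": e.type, "payload": e.payload},
                    sort_keys=True,
                )
                + "\n"
            )


def read_log_jsonl(path: str | Path) -> SessionLog:
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise LogParseError(f"{path}: empty log file")
    try:
        header = json.loads(lines[0])["header"]
        events = [
            Event(t=float(rec["t"]), type=rec["event"], payload=rec.get("payload", {}))
            for rec in (json.loads(ln) for ln in lines[1:])
        ]
    except (KeyError, ValueError, TypeError) as exc:
        raise LogParseError(f"{path}: malformed log: {exc}")
    return SessionLog(header=header, events=events)


def log_to_csv(log: SessionLog, path: str | Path) -> None:
    """Flat CSV export (columns t, event, phase, payload-as-JSON)."""
    rows = [
        {
            "t": round(e.t, 3),
            "event": e.type,
            "phase": log.header.get("phase_type", ""),
            "payload": json.dumps(e.payload, sort_keys=True),
        }
        for e in log.events
    ]
    pd.DataFrame(rows, columns=["t", "event", "phase", "payload"]).to_csv(
        path, index=False
    )


def save_bundle(result, directory: str | Path) -> Path:
    """Persist a simulated study (configs + logs + series + manifest)."""
    root = Path(directory)
    (root / "logs").mkdir(parents=True, exist_ok=True)
    (root / "configs").mkdir(exist_ok=True)
    phase_map: dict[str, list[str]] = {}
    manifest: dict = {
        "participant_id": result.series.participant_id,
        "seed": result.seed,
        "sessions": [],
    }
    for label, logs in result.logs.items():
        phase_map[label] = []
        for i, log in enumerate(logs):
            stem = f"{label}_{i:03d}"
            write_log_jsonl(log, root / "logs" / f"{stem}.jsonl")
            cfg = result.configs[label][i]
            save_config(cfg, root / "configs" / f"{stem}.json")
            phase_map[label].append(stem)
            manifest["sessions"].append(
                {
                    "session": stem,
                    "phase": label,
                    "config_hash": config_hash(cfg),
                    "seed": cfg.rng_seed,
                }
            )
    series_payload = {
        "participant_id": result.series.participant_id,
        "phases": [[label, counts] for label, counts in result.series.phases],
    }
    (root / "series.json").write_text(
        json.dumps(series_payload, sort_keys=True, indent=2) + "\n"
    )
    (root / "phase_map.json").write_text(
        json.dumps(phase_map, sort_keys=True, indent=2) + "\n"
    )
    (root / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n"
    )
    return root


def load_series(path: str | Path) -> PhaseSeries:
    payload = json.loads(Path(path).read_text())
    return PhaseSeries(
        participant_id=payload["participant_id"],
        phases=[(label, list(counts)) for label, counts in payload["phases"]],
    )


def load_bundle_series(directory: str | Path) -> PhaseSeries:
    """Phase series of a bundle, recomputed-able from its logs.

    Validates the bundle invariant that every log's header hash matches the
    stored config before trusting the series.
    """
    root = Path(directory)
    phase_map = json.loads((root / "phase_map.json").read_text())
    phases: list[tuple[str, list[int]]] = []
    for label in ("A1", "B1", "A2", "C", "B2"):
        stems = phase_map.get(label, [])
        counts = []
        for stem in stems:
            log = read_log_jsonl(root / "logs" / f"{stem}.jsonl")
            cfg = load_config(root / "configs" / f"{stem}.json")
            if log.header.get("config_hash") != config_hash(cfg):
                raise ConfigurationError(
                    f"bundle {root}: log {stem} header hash does not match its config"
                )
            counts.append(len(log.of_type("response")))
        if counts:
            phases.append((label, counts))
    series = json.loads((root / "series.json").read_text())
    return PhaseSeries(
        participant_id=series["participant_id"], phases=phases
    )
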