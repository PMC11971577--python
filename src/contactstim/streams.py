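"""Frame-source plumbing: array-backed streams and JSONL replay files.

The engine consumes any iterable of :class:`~contactstim.detection.LandmarkFrame`
(the abstract frame-source contract), which is what a live pose-landmark
backend adapter would yield.  For replay and simulation the package uses two
concrete sources:

* :class:`ArrayFrameStream` — a dense array-backed stream (one hand, a fixed
  landmark set, optional per-frame visibility), which the engine can evaluate
  without per-frame Python objects;
* JSONL replay files — one frame per line,
  ``{"t": ..., "hand_id": ..., "landmarks": {name: [x, y, z?]}}``,
  human-auditable and diff-able.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .detection import LandmarkFrame
from .errors import StreamError


@dataclass
class ArrayFrameStream:
    """Dense landmark stream: ``coords[i, j]`` is landmark ``landmark_names[j]``
    at ``timestamps[i]`` (x, y[, z] normalized image coordinates).

    ``present[i]`` False marks frames on which the hand is not visible (the
    frame is emitted with an empty landmark list).
    """

    timestamps: np.ndarray
    landmark_names: tuple[str, ...]
    coords: np.ndarray
    hand_id: str = "unknown"
    present: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n, m = len(self.timestamps), len(self.landmark_names)
        if self.coords.shape[:2] != (n, m):
            raise StreamError(
                f"coords shape {self.coords.shape} does not match "
                f"{n} frames x {m} landmarks"
            )
        if np.any(np.diff(self.timestamps) < 0):
            raise StreamError("timestamps must be monotone non-decreasing")
        if self.present is None:
            self.present = np.ones(n, dtype=bool)
        else:
            self.present = np.asarray(self.present, dtype=bool)

    def __len__(self) -> int:
        return len(self.timestamps)

    def __iter__(self) -> Iterator[LandmarkFrame]:
        for i in range(len(self.timestamps)):
            if self.present[i]:
                landmarks = {
                    name: tuple(self.coords[i, j])
                    for j, name in enumerate(self.landmark_names)
                }
            else:
                landmarks = {}
            yield LandmarkFrame(
                timestamp=float(self.timestamps[i]),
                landmarks=landmarks,
                hand_id=self.hand_id,
            )

    def flat_points(
        self, subset: frozenset[str] | None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(frame_idx, xs, ys) of the landmark subset, visible frames only."""
        if subset is None:
            cols = np.arange(len(self.landmark_names))
        else:
            cols = np.asarray(
                [j for j, nm in enumerate(self.landmark_names) if nm in subset],
                dtype=np.intp,
            )
        rows = np.flatnonzero(self.present)
        if cols.size == 0 or rows.size == 0:
            empty = np.empty(0)
            return np.empty(0, dtype=np.intp), empty, empty
        frame_idx = np.repeat(rows, cols.size)
        pts = self.coords[np.ix_(rows, cols)][..., :2].reshape(-1, 2)
        return frame_idx, pts[:, 0], pts[:, 1]


def write_frames_jsonl(path: str | Path, frames) -> None:
    """Write any frame source as a JSONL replay file (3-decimal timestamps)."""
    path = Path(path)
    with path.open("w") as fh:
        for frame in frames:
            record = {
                "t": round(float(frame.timestamp), 3),
                "hand_id": frame.hand_id,
                "landmarks": {
                    name: [round(float(c), 5) for c in coords]
                    for name, coords in sorted(frame.landmarks.items())
                },
            }
            fh.write(json.dumps(record, sort_keys=True) + "\n")


def read_frames_jsonl(path: str | Path) -> list[LandmarkFrame]:
    """Read a JSONL replay file back into a list of frames."""
    frames: list[LandmarkFrame] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
                frames.append(
                    LandmarkFrame(
                        timestamp=float(record["t"]),
                        landmarks={
                            name: tuple(float(c) for c in coords)
                            for name, coords in record.get("landmarks", {}).items()
                        },
                        hand_id=record.get("hand_id", "unknown"),
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise StreamError(f"{path}:{lineno}: malformed frame record: {exc}")
    return frames
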