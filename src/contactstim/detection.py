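"""Hand-object contact detection from landmark streams.

The sensing model: a webcam looks down at a desk on which a small number of
objects sit in fixed positions.  A pose-landmark backend (or the synthetic
generator) supplies per-frame 2D hand-landmark coordinates normalized to the
image, origin top-left.  An object is described by a fixed polygonal footprint
in the same coordinates (:class:`ObjectRegion`).  A *contact* exists on a frame
when enough of the configured landmark subset falls inside some region; a
*response* is the debounced rising edge of contact — touching an object counts
once, and a new response requires the hand to leave the object and come back.

Contact is decided in the 2D image plane: the objects are fixed on the desktop,
so their footprint in the image is what "touching" means to the camera.  A z
coordinate, when present, is carried but ignored by default.

Geometry is delegated to shapely with the closed-boundary convention (a point
on the polygon edge is inside): flicker at region edges is handled by the
debouncer, not by the containment predicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Iterator, Sequence

import numpy as np
import shapely
from pydantic import BaseModel, ConfigDict, Field, model_validator
from shapely.geometry import Point, Polygon

from .errors import StreamError, ConfigurationError

#: MediaPipe-style fingertip landmark names; the default contact subset.
#: Touching/exploring an object is fingertip-led, so fingertips are what the
#: detector watches unless configured otherwise.
FINGERTIP_LANDMARKS: tuple[str, ...] = (
    "thumb_tip",
    "index_finger_tip",
    "middle_finger_tip",
    "ring_finger_tip",
    "pinky_tip",
)


class ObjectRegion(BaseModel):
    """Fixed planar footprint of one desk object, in normalized image coords.

    ``polygon`` lists >= 3 vertices with x, y in [0, 1] (origin top-left).  An
    axis-aligned bounding box is just the 4-vertex special case; see
    :meth:`from_bbox`.  The polygon must be simple (non-self-intersecting).
    """

    model_config = ConfigDict(frozen=True)

    region_id: str
    polygon: tuple[tuple[float, float], ...] = Field(min_length=3)
    label: str = ""

    @model_validator(mode="after")
    def _check_geometry(self) -> "ObjectRegion":
        for x, y in self.polygon:
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError(f"region {self.region_id!r}: non-finite vertex ({x}, {y})")
            if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
                raise ValueError(
                    f"region {self.region_id!r}: vertex ({x}, {y}) outside [0,1]^2"
                )
        if len(set(self.polygon)) < 3:
            raise ValueError(
                f"region {self.region_id!r}: fewer than 3 distinct vertices"
            )
        poly = Polygon(self.polygon)
        if poly.area <= 0 or not poly.is_valid:
            raise ValueError(
                f"region {self.region_id!r}: polygon is degenerate or self-intersecting"
            )
        return self

    @cached_property
    def shape(self) -> Polygon:
        poly = Polygon(self.polygon)
        if poly.area <= 0 or not poly.is_valid:  # duck-typed / bypassed validation
            raise ConfigurationError(
                f"region {self.region_id!r}: degenerate polygon"
            )
        shapely.prepare(poly)
        return poly

    @classmethod
    def from_bbox(
        cls, region_id: str, x0: float, y0: float, x1: float, y1: float, label: str = ""
    ) -> "ObjectRegion":
        """Axis-aligned box (x0,y0)-(x1,y1) as a 4-vertex region."""
        return cls(
            region_id=region_id,
            polygon=((x0, y0), (x1, y0), (x1, y1), (x0, y1)),
            label=label,
        )


class DetectorConfig(BaseModel):
    """Tunables for turning landmark positions into discrete responses.

    ``landmark_subset``: which landmark names count toward contact (default:
    the five fingertips).  ``min_landmarks_in``: how many of those must fall
    inside a single region for the frame to count as contact.
    ``debounce_frames``: consecutive contact frames required before a contact
    onset is trusted; ``release_frames``: consecutive contact-free frames
    required before the contact is considered released.  Defaults (3 / 3)
    assume a stream of >= 15 fps, i.e. a 0.2 s tolerance against single-frame
    landmark jitter.  ``use_z`` is accepted for forward compatibility but
    contact is evaluated in the 2D image plane.
    """

    model_config = ConfigDict(frozen=True)

    landmark_subset: tuple[str, ...] = FINGERTIP_LANDMARKS
    min_landmarks_in: int = Field(default=1, ge=1)
    debounce_frames: int = Field(default=3, ge=1)
    release_frames: int = Field(default=3, ge=1)
    use_z: bool = False


@dataclass(frozen=True)
class LandmarkFrame:
    """One timestamped observation of hand landmarks.

    ``landmarks`` maps landmark name -> (x, y) or (x, y, z) in normalized image
    coordinates.  An empty mapping is legal and means the hand is not visible.
    """

    timestamp: float
    landmarks: dict[str, tuple[float, ...]] = field(default_factory=dict)
    hand_id: str = "unknown"

    def __post_init__(self) -> None:
        if not (self.timestamp >= 0.0):
            raise StreamError(f"frame timestamp {self.timestamp} is negative")
        for name, coords in self.landmarks.items():
            if not all(math.isfinite(c) for c in coords):
                raise StreamError(f"landmark {name!r} has non-finite coordinates")


@dataclass(frozen=True)
class ContactState:
    """Per-frame contact verdict.  ``region_id`` is None iff not in contact."""

    in_contact: bool
    region_id: str | None = None
    since: float | None = None

    def __post_init__(self) -> None:
        if self.in_contact == (self.region_id is None):
            raise ValueError("region_id must be set iff in_contact")


def point_in_region(point: Sequence[float], region: ObjectRegion) -> bool:
    """Closed containment test: True if ``point`` is inside or on the boundary.

    Raises :class:`ConfigurationError` for a degenerate region polygon and
    :class:`ValueError` for non-finite coordinates.
    """
    x, y = float(point[0]), float(point[1])
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError(f"non-finite point ({x}, {y})")
    return bool(region.shape.covers(Point(x, y)))


def _region_order(regions: Sequence[ObjectRegion]) -> list[int]:
    """Indices of ``regions`` sorted by region_id (tie-break = lowest id wins)."""
    return sorted(range(len(regions)), key=lambda i: regions[i].region_id)


def _qualifying_counts(
    frame_idx: np.ndarray,
    xs: np.ndarray,
    ys: np.ndarray,
    n_frames: int,
    regions: Sequence[ObjectRegion],
) -> np.ndarray:
    """(n_frames, n_regions) matrix of qualifying-landmark counts per region."""
    counts = np.zeros((n_frames, len(regions)), dtype=np.int32)
    if xs.size:
        for j, region in enumerate(regions):
            inside = shapely.intersects_xy(region.shape, xs, ys)
            if inside.any():
                counts[:, j] = np.bincount(
                    frame_idx[inside], minlength=n_frames
                ).astype(np.int32)
    return counts


def _flatten_frames(
    frames: Sequence[LandmarkFrame], subset: frozenset[str] | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten the configured landmark subset of a frame list into point arrays."""
    idx: list[int] = []
    xs: list[float] = []
    ys: list[float] = []
    for i, frame in enumerate(frames):
        for name, coords in frame.landmarks.items():
            if subset is None or name in subset:
                idx.append(i)
                xs.append(coords[0])
                ys.append(coords[1])
    return (
        np.asarray(idx, dtype=np.intp),
        np.asarray(xs, dtype=float),
        np.asarray(ys, dtype=float),
    )


def series_from_points(
    frame_idx: np.ndarray,
    xs: np.ndarray,
    ys: np.ndarray,
    n_frames: int,
    regions: Sequence[ObjectRegion],
    cfg: DetectorConfig,
) -> tuple[np.ndarray, list[str | None]]:
    """Contact verdicts for a stream already flattened to qualifying points.

    Returns ``(in_contact, region_ids)``: a boolean array and, per frame, the
    region containing the most qualifying landmarks (ties broken by lowest
    region_id) or None.
    """
    if not regions:
        raise ConfigurationError("at least one object region is required")
    counts = _qualifying_counts(frame_idx, xs, ys, n_frames, regions)
    order = _region_order(regions)
    ordered = counts[:, order]
    best = np.argmax(ordered, axis=1)  # first max -> lowest region_id
    best_counts = ordered[np.arange(n_frames), best]
    in_contact = best_counts >= cfg.min_landmarks_in
    ids: list[str | None] = [
        regions[order[b]].region_id if hit else None
        for b, hit in zip(best, in_contact)
    ]
    return in_contact, ids


def contact_series(
    frames: Sequence[LandmarkFrame],
    regions: Sequence[ObjectRegion],
    cfg: DetectorConfig,
) -> tuple[np.ndarray, list[str | None]]:
    """Vectorized per-frame contact evaluation for a whole frame list."""
    subset = frozenset(cfg.landmark_subset) if cfg.landmark_subset else None
    frame_idx, xs, ys = _flatten_frames(frames, subset)
    return series_from_points(frame_idx, xs, ys, len(frames), regions, cfg)


def frame_contact(
    frame: LandmarkFrame,
    regions: Sequence[ObjectRegion],
    cfg: DetectorConfig | None = None,
) -> ContactState:
    """Single-frame contact verdict.

    ``since`` is the frame's own timestamp when in contact: a single frame
    cannot know the true onset; streaming callers track onsets through
    :class:`ContactDebouncer`.
    """
    cfg = cfg or DetectorConfig()
    in_contact, ids = contact_series([frame], regions, cfg)
    if in_contact[0]:
        return ContactState(True, ids[0], frame.timestamp)
    return ContactState(False, None, None)


class ContactDebouncer:
    """Turn a per-frame contact signal into debounced contact-onset events.

    A contact must persist for ``debounce_frames`` consecutive frames before
    its onset (the first frame of the run) is emitted; once confirmed, the
    contact survives gaps shorter than ``release_frames`` and emits nothing
    further until released and re-established (rising-edge semantics).
    """

    def __init__(self, debounce_frames: int = 3, release_frames: int = 3):
        if debounce_frames < 1 or release_frames < 1:
            raise ConfigurationError("debounce/release frame counts must be >= 1")
        self.debounce_frames = debounce_frames
        self.release_frames = release_frames
        self.reset()

    def reset(self) -> None:
        """Forget all state; an ongoing physical contact becomes a fresh onset."""
        self._confirmed = False
        self._pending = 0
        self._release = 0
        self._onset_t: float | None = None
        self._onset_region: str | None = None

    @property
    def pending(self) -> bool:
        """True while an unconfirmed contact streak is building."""
        return self._pending > 0

    @property
    def confirmed(self) -> bool:
        return self._confirmed

    def update(
        self, timestamp: float, in_contact: bool, region_id: str | None = None
    ) -> tuple[float, str | None] | None:
        """Feed one frame; returns ``(onset_timestamp, region_id)`` when a new
        debounced contact is confirmed, else None."""
        if in_contact:
            self._release = 0
            if self._confirmed:
                return None
            if self._pending == 0:
                self._onset_t = timestamp
                self._onset_region = region_id
            self._pending += 1
            if self._pending >= self.debounce_frames:
                self._confirmed = True
                self._pending = 0
                return (self._onset_t, self._onset_region)  # type: ignore[return-value]
            return None
        self._pending = 0
        if self._confirmed:
            self._release += 1
            if self._release >= self.release_frames:
                self._confirmed = False
                self._release = 0
        return None


def detect_responses(
    stream: Iterable[LandmarkFrame],
    regions: Sequence[ObjectRegion],
    cfg: DetectorConfig | None = None,
) -> list[float]:
    """Discrete "new response" timestamps from a time-ordered landmark stream.

    Emits the onset timestamp of each debounced contact; a sustained touch
    counts once, and a new response requires the contact to be lost for
    ``release_frames`` frames and re-established.  Raises
    :class:`StreamError` on decreasing timestamps.
    """
    cfg = cfg or DetectorConfig()
    frames = list(stream)
    if not frames:
        return []
    ts = np.asarray([f.timestamp for f in frames], dtype=float)
    if np.any(np.diff(ts) < 0):
        bad = int(np.argmax(np.diff(ts) < 0)) + 1
        raise StreamError(
            f"out-of-order timestamp at frame {bad}: "
            f"{ts[bad]:.3f} < {ts[bad - 1]:.3f}"
        )
    in_contact, _ = contact_series(frames, regions, cfg)
    deb = ContactDebouncer(cfg.debounce_frames, cfg.release_frames)
    onsets: list[float] = []
    for t, hit in zip(ts, in_contact):
        event = deb.update(float(t), bool(hit))
        if event is not None:
            onsets.append(event[0])
    return onsets


def iter_checked(frames: Iterable[LandmarkFrame]) -> Iterator[LandmarkFrame]:
    """Yield frames, enforcing monotone non-decreasing timestamps."""
    last = -math.inf
    for i, frame in enumerate(frames):
        if frame.timestamp < last:
            raise StreamError(
                f"out-of-order timestamp at frame {i}: "
                f"{frame.timestamp:.3f} < {last:.3f}"
            )
        last = frame.timestamp
        yield frame
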