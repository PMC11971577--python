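import numpy as np
import pytest

from contactstim import (
    DetectorConfig,
    FINGERTIP_LANDMARKS,
    ObjectRegion,
    SessionConfig,
)
from contactstim.simulate import default_regions, default_session_config
from contactstim.streams import ArrayFrameStream

# Fingertip offsets mirroring the simulator's hand shape, small enough that a
# hand "at" a region centroid puts all five tips inside it.
_OFFSETS = np.array(
    [(-0.012, 0.004), (-0.006, -0.008), (0.0, -0.01), (0.006, -0.008), (0.012, 0.004)]
)


@pytest.fixture
def bbox_region() -> ObjectRegion:
    return ObjectRegion.from_bbox("A", 0.40, 0.60, 0.50, 0.70)


@pytest.fixture
def regions() -> tuple[ObjectRegion, ...]:
    return default_regions()


@pytest.fixture
def detector() -> DetectorConfig:
    return DetectorConfig(debounce_frames=2, release_frames=2)


@pytest.fixture
def session_config(regions) -> SessionConfig:
    return default_session_config(phase_type="baseline", rng_seed=0)


def contact_stream(
    flags, regions, fps: float = 10.0, duration_s: float | None = None
) -> ArrayFrameStream:
    """Frame stream whose per-frame contact truth equals ``flags``.

    True frames put the whole hand at the first region's centroid; False
    frames put it at an outside rest point.  ``duration_s`` pads with
    non-contact frames so the stream covers a session.
    """
    flags = list(flags)
    fps = float(fps)
    n = len(flags)
    if duration_s is not None:
        total = int(round(duration_s * fps))
        flags = flags + [False] * max(0, total - n)
        n = len(flags)
    ts = np.arange(n) / fps
    inside = np.array(regions[0].shape.centroid.coords[0])
    outside = np.array([0.5, 0.2])
    centers = np.where(np.asarray(flags, dtype=bool)[:, None], inside, outside)
    coords = centers[:, None, :] + _OFFSETS[None, :, :]
    return ArrayFrameStream(
        timestamps=ts, landmark_names=FINGERTIP_LANDMARKS, coords=coords
    )


def run_length_response_oracle(flags, debounce: int, release: int) -> list[int]:
    """Independent run-length oracle for debounced rising-edge responses.

    Encode the boolean contact sequence as runs; a contact run of length >=
    ``debounce`` starts a confirmed contact (response at its first index) if
    none is active; a gap run of length >= ``release`` ends the active
    contact; shorter runs change nothing.
    """
    runs = []
    i = 0
    flags = list(flags)
    while i < len(flags):
        j = i
        while j < len(flags) and flags[j] == flags[i]:
            j += 1
        runs.append((flags[i], i, j - i))
        i = j
    confirmed = False
    onsets = []
    for value, start, length in runs:
        if value:
            if not confirmed and length >= debounce:
                confirmed = True
                onsets.append(start)
        elif length >= release:
            confirmed = False
    return onsets
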