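"""Dense optical flow and region-integrated motion ("average speed").

The motion measure used throughout the package is the area-normalized
integral of the optical-flow magnitude over a region of interest: for a
flow field (u, v) and a pixel mask M,

    average speed = (1 / |M|) * sum_{p in M} sqrt(u_p^2 + v_p^2)   [px/frame]

It is non-negative and invariant to the direction and coherence of the
motion; fast motion in a small area and slow distributed motion can give
the same value. Conversion to px/s happens only at 1 Hz resampling
(see :mod:`audiencemotion.series`).

Coordinate convention (used package-wide): 8-bit grayscale frames, origin
at the top-left corner, x rightward (columns), y downward (rows), positions
measured at pixel centers, 0-based.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterator, Sequence

import numpy as np
from skimage.registration import optical_flow_ilk

logger = logging.getLogger(__name__)

#: Default hard bound on per-pixel displacement estimates, px/frame.
DEFAULT_MAX_DISPLACEMENT = 8.0

#: Minimum frame side length for flow estimation, px.
MIN_FLOW_SIZE = 16


class InputError(ValueError):
    """Raised when an operation's input violates its contract."""


class ConfigurationError(ValueError):
    """Raised when a configuration object violates its invariants."""


@dataclasses.dataclass
class FrameSequence:
    """Ordered grayscale frames with a frame rate.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Gray levels; uint8 on disk, any real dtype in memory.
    fps : float
        Frames per second, > 0.
    t0 : float
        Start time of the first frame, seconds.
    """

    frames: np.ndarray
    fps: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise InputError(
                f"frames must be a (n, h, w) stack, got ndim={self.frames.ndim}"
            )
        if len(self.frames) < 2:
            raise InputError("a frame sequence needs at least 2 frames")
        if not self.fps > 0:
            raise InputError(f"fps must be > 0, got {self.fps}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration(self) -> float:
        """Nominal duration in seconds."""
        return len(self.frames) / self.fps


@dataclasses.dataclass
class FlowField:
    """Per-pixel displacement between two consecutive frames, px/frame."""

    u: np.ndarray  # horizontal (x) displacement
    v: np.ndarray  # vertical (y) displacement

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape:
            raise InputError("u and v must have the same shape")
        if not (np.isfinite(self.u).all() and np.isfinite(self.v).all()):
            raise InputError("flow field contains non-finite values")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


class RegionMask:
    """Boolean pixel-inclusion mask over a frame.

    Backed either by an explicit boolean array or, for axis-aligned
    rectangles, by the rectangle bounds alone (materialized on demand),
    which keeps per-frame hand-region masks cheap.
    """

    __slots__ = ("shape", "_mask", "_rect")

    def __init__(self, mask: np.ndarray):
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim != 2:
            raise InputError("mask must be 2-D")
        self.shape = mask.shape
        self._mask = mask
        self._rect = None

    @classmethod
    def from_rect(
        cls, shape: tuple[int, int], x0: int, y0: int, x1: int, y1: int
    ) -> "RegionMask":
        """Rectangle covering columns [x0, x1) and rows [y0, y1), clipped."""
        obj = cls.__new__(cls)
        h, w = shape
        obj.shape = (h, w)
        obj._mask = None
        obj._rect = (
            max(0, min(w, x0)),
            max(0, min(h, y0)),
            max(0, min(w, x1)),
            max(0, min(h, y1)),
        )
        return obj

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "RegionMask":
        return cls.from_rect(shape, 0, 0, 0, 0)

    @classmethod
    def full(cls, shape: tuple[int, int]) -> "RegionMask":
        return cls.from_rect(shape, 0, 0, shape[1], shape[0])

    @property
    def mask(self) -> np.ndarray:
        if self._mask is not None:
            return self._mask
        x0, y0, x1, y1 = self._rect
        m = np.zeros(self.shape, dtype=bool)
        m[y0:y1, x0:x1] = True
        return m

    @property
    def area(self) -> int:
        if self._rect is not None:
            x0, y0, x1, y1 = self._rect
            return max(0, x1 - x0) * max(0, y1 - y0)
        return int(self._mask.sum())

    def union(self, other: "RegionMask") -> "RegionMask":
        if self.shape != other.shape:
            raise InputError("mask shapes differ")
        return RegionMask(self.mask | other.mask)

    def minus(self, other: "RegionMask") -> "RegionMask":
        if self.shape != other.shape:
            raise InputError("mask shapes differ")
        return RegionMask(self.mask & ~other.mask)


@dataclasses.dataclass
class MotionSeries:
    """Per-entity, per-body-part average-speed time series.

    ``values`` are px/frame at the native frame rate and px/s once
    resampled to 1 Hz. Missing samples are NaN.
    """

    entity_id: str
    body_part: str
    values: np.ndarray
    rate: float  # Hz
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InputError("values must be 1-D")
        if not self.rate > 0:
            raise InputError("rate must be > 0")
        finite = self.values[np.isfinite(self.values)]
        if (finite < -1e-12).any():
            raise InputError("average speed values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    def mean(self) -> float:
        """Mean over non-missing samples."""
        return float(np.nanmean(self.values))


def estimate_flow(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    *,
    max_displacement: float = DEFAULT_MAX_DISPLACEMENT,
    radius: int = 7,
    num_warp: int = 3,
) -> FlowField:
    """Estimate the dense displacement field from ``frame_a`` to ``frame_b``.

    The engine is pluggable in principle; this reference implementation is
    scikit-image's coarse-to-fine iterative Lucas-Kanade, which satisfies
    the package's translation contracts (a d-pixel rigid shift of a
    textured scene yields a median estimate within 0.2 px of d for
    |d| <= max_displacement). Output is clipped to ``max_displacement``.
    """
    a = np.asarray(frame_a, dtype=np.float64)
    b = np.asarray(frame_b, dtype=np.float64)
    if a.shape != b.shape:
        raise InputError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 2 or min(a.shape) < MIN_FLOW_SIZE:
        raise InputError(f"frames must be 2-D and at least {MIN_FLOW_SIZE}px a side")
    # skimage returns (row, col) displacement such that content at (r, c)
    # in frame_a appears at (r + v, c + u) in frame_b.
    v, u = optical_flow_ilk(a, b, radius=radius, num_warp=num_warp)
    u = np.clip(np.nan_to_num(u), -max_displacement, max_displacement)
    v = np.clip(np.nan_to_num(v), -max_displacement, max_displacement)
    return FlowField(u=u, v=v)


def integrate_magnitude(field: FlowField, mask: RegionMask) -> float:
    """Area-normalized integral of the flow magnitude over ``mask``.

    Returns ``sum_{p in mask} |flow_p| / area(mask)`` in px/frame.
    """
    if field.u.shape != mask.shape:
        raise InputError("flow field and mask shapes differ")
    area = mask.area
    if area == 0:
        raise InputError("cannot integrate over an empty mask")
    return float(np.hypot(field.u, field.v)[mask.mask].sum() / area)


def iter_flow_fields(seq: FrameSequence, **flow_kwargs) -> Iterator[FlowField]:
    """Yield the flow field for each consecutive frame pair (n-1 fields)."""
    for i in range(len(seq) - 1):
        yield estimate_flow(seq.frames[i], seq.frames[i + 1], **flow_kwargs)


def frame_motion_series(
    seq: FrameSequence,
    *,
    entity_id: str = "stage",
    body_part: str = "stage",
    fields: Sequence[FlowField] | None = None,
    **flow_kwargs,
) -> MotionSeries:
    """Whole-frame average speed per consecutive frame pair.

    This is the measure applied to the performers' video: one value per
    frame pair, integrating over the full frame. Length is n_frames - 1.
    Precomputed ``fields`` may be passed to share flow across measures.
    """
    full = RegionMask.full(seq.frame_shape)
    if fields is None:
        fields = iter_flow_fields(seq, **flow_kwargs)
    values = [integrate_magnitude(f, full) for f in fields]
    if len(values) != len(seq) - 1:
        raise InputError("fields length must equal n_frames - 1")
    return MotionSeries(
        entity_id=entity_id,
        body_part=body_part,
        values=np.array(values),
        rate=seq.fps,
        t0=seq.t0,
    )
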