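"""Per-person body-part average-speed series and 1 Hz resampling.

Three series are extracted per audience member:

* **upper_body** — flow magnitude integrated over the person's static
  polygonal envelope;
* **hands** — integrated over the union of the two wristband-anchored
  hand rectangles (a single "hands" variable, not one per hand);
* **head_torso** — integrated over the envelope minus the hand
  rectangles, as a per-frame *mask* difference. Because a hand rectangle
  may extend outside the envelope, this is not the arithmetic difference
  of the upper-body and hands series.

All native-rate values are px/frame; 1 Hz resampling converts to px/s.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .flow import (
    FlowField,
    FrameSequence,
    InputError,
    MotionSeries,
    RegionMask,
    integrate_magnitude,
    iter_flow_fields,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Polygon rasterization (even-odd rule, pixel-center inclusion)
# ---------------------------------------------------------------------------

def points_in_polygon(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Even-odd (ray crossing) point-in-polygon test, vectorized.

    A point is inside if a horizontal ray from it crosses the polygon
    boundary an odd number of times. Points are (x, y); the polygon is a
    closed loop of (x, y) vertices (closure implicit).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
        raise InputError("polygon needs at least 3 (x, y) vertices")
    px, py = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    x1, y1 = poly[-1]
    for x2, y2 in poly:
        crosses = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = (x2 - x1) * (py - y1) / (y2 - y1) + x1
        inside ^= crosses & (px < xint)
        x1, y1 = x2, y2
    return inside


def polygon_mask(polygon: np.ndarray, shape: tuple[int, int]) -> RegionMask:
    """Rasterize a polygon: pixel included iff its center is inside."""
    poly = np.asarray(polygon, dtype=float)
    h, w = shape
    # Restrict the test to the polygon's bounding box for speed.
    x0 = max(0, int(np.floor(poly[:, 0].min())))
    y0 = max(0, int(np.floor(poly[:, 1].min())))
    x1 = min(w, int(np.ceil(poly[:, 0].max())) + 1)
    y1 = min(h, int(np.ceil(poly[:, 1].max())) + 1)
    mask = np.zeros((h, w), dtype=bool)
    if x0 < x1 and y0 < y1:
        yy, xx = np.mgrid[y0:y1, x0:x1]
        pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        mask[y0:y1, x0:x1] = points_in_polygon(pts, poly).reshape(yy.shape)
    return RegionMask(mask)


def _envelope_mask(envelope: np.ndarray, shape: tuple[int, int]) -> RegionMask:
    m = polygon_mask(envelope, shape)
    if m.area == 0:
        raise InputError("degenerate envelope polygon: zero rasterized area")
    return m


# ---------------------------------------------------------------------------
# Body-part series
# ---------------------------------------------------------------------------

def _resolve_fields(
    seq: FrameSequence, fields: Sequence[FlowField] | None, **flow_kwargs
) -> Iterable[FlowField]:
    if fields is not None:
        if len(fields) != len(seq) - 1:
            raise InputError("fields length must equal n_frames - 1")
        return fields
    return iter_flow_fields(seq, **flow_kwargs)


def upper_body_series(
    seq: FrameSequence,
    envelope: np.ndarray,
    *,
    entity_id: str = "person",
    fields: Sequence[FlowField] | None = None,
    **flow_kwargs,
) -> MotionSeries:
    """Average speed over the person's static polygonal envelope.

    Motion outside the envelope does not contribute to the integral.
    """
    mask = _envelope_mask(envelope, seq.frame_shape)
    values = [
        integrate_magnitude(f, mask)
        for f in _resolve_fields(seq, fields, **flow_kwargs)
    ]
    return MotionSeries(entity_id, "upper_body", np.array(values), seq.fps, seq.t0)


def hands_series(
    seq: FrameSequence,
    hand_masks: Sequence[tuple[RegionMask, RegionMask]],
    *,
    entity_id: str = "person",
    fields: Sequence[FlowField] | None = None,
    **flow_kwargs,
) -> MotionSeries:
    """Average speed over the union of the two hand rectangles.

    The pair-t value uses the hand masks anchored at frame t (the first
    frame of the pair). Overlapping left/right rectangles are counted
    once. A pair whose masks are both empty (wrist not tracked) yields a
    missing (NaN) sample; if every frame is maskless, that is an error.
    """
    if len(hand_masks) != len(seq):
        raise InputError("need one (left, right) mask pair per frame")
    if all(l.area == 0 and r.area == 0 for l, r in hand_masks):
        raise InputError("all hand masks are empty for the entire sequence")
    values = []
    for t, f in enumerate(_resolve_fields(seq, fields, **flow_kwargs)):
        left, right = hand_masks[t]
        union = left.union(right)
        if union.area == 0:
            values.append(np.nan)
        else:
            values.append(integrate_magnitude(f, union))
    return MotionSeries(entity_id, "hands", np.array(values), seq.fps, seq.t0)


def head_torso_series(
    seq: FrameSequence,
    envelope: np.ndarray,
    hand_masks: Sequence[tuple[RegionMask, RegionMask]],
    *,
    entity_id: str = "person",
    fields: Sequence[FlowField] | None = None,
    **flow_kwargs,
) -> MotionSeries:
    """Average speed over envelope minus the per-frame hand rectangles."""
    if len(hand_masks) != len(seq):
        raise InputError("need one (left, right) mask pair per frame")
    env = _envelope_mask(envelope, seq.frame_shape)
    values = []
    for t, f in enumerate(_resolve_fields(seq, fields, **flow_kwargs)):
        left, right = hand_masks[t]
        diff = env.minus(left.union(right))
        if diff.area == 0:
            values.append(np.nan)
        else:
            values.append(integrate_magnitude(f, diff))
    return MotionSeries(entity_id, "head_torso", np.array(values), seq.fps, seq.t0)


# ---------------------------------------------------------------------------
# Resampling and summaries
# ---------------------------------------------------------------------------

def resample_1hz(series: MotionSeries) -> MotionSeries:
    """Resample a native-rate series to 1 Hz, converting px/frame to px/s.

    Each [t, t+1) second bin (from t0) averages the native samples whose
    start time falls in the bin, excluding missing values, then scales by
    the native rate. A trailing partial bin is dropped; a bin whose
    samples are all missing stays missing (NaN).
    """
    if series.rate < 1.0:
        raise InputError("resampling to 1 Hz requires a native rate >= 1 Hz")
    n = len(series.values)
    n_bins = int(np.floor(n / series.rate))
    if n_bins == 0:
        raise InputError("series shorter than one second")
    idx = np.floor(np.arange(n) / series.rate).astype(int)
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        chunk = series.values[idx == b]
        good = chunk[np.isfinite(chunk)]
        if good.size:
            out[b] = good.mean() * series.rate
    return MotionSeries(series.entity_id, series.body_part, out, 1.0, series.t0)


def bodypart_summary(
    series_by_segment: Mapping[str, Iterable[MotionSeries]],
) -> pd.DataFrame:
    """Mean average speed per body part per segment (performance part).

    Pools all samples of all series sharing a (segment, body_part) cell.
    Returns a tidy frame with columns segment, body_part, mean_speed,
    n_series, n_samples.
    """
    rows = []
    any_series = False
    for segment, series_list in series_by_segment.items():
        by_part: dict[str, list[np.ndarray]] = {}
        counts: dict[str, int] = {}
        for s in series_list:
            any_series = True
            by_part.setdefault(s.body_part, []).append(s.values)
            counts[s.body_part] = counts.get(s.body_part, 0) + 1
        for part, chunks in by_part.items():
            pooled = np.concatenate(chunks)
            good = pooled[np.isfinite(pooled)]
            rows.append(
                {
                    "segment": segment,
                    "body_part": part,
                    "mean_speed": float(good.mean()) if good.size else np.nan,
                    "n_series": counts[part],
                    "n_samples": int(good.size),
                }
            )
    if not any_series:
        raise InputError("no series to summarize")
    return pd.DataFrame(rows)
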