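"""Reflective wristband detection and per-person wrist track linking.

Wristbands are rendered (or filmed) as the brightest objects in the
scene, so detection is connected-component labeling above a brightness
threshold. Detections are assigned to persons by envelope membership and
to left/right hands by minimum-total-displacement matching against the
previous frame; short detection gaps are linearly interpolated, longer
ones left missing. A correction table can override stretches of a track,
replacing the fully manual repair step a human operator would perform on
real footage.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from skimage import measure

from .flow import InputError, RegionMask
from .series import points_in_polygon

logger = logging.getLogger(__name__)

DEFAULT_MIN_BLOB_SIZE = 9  # px
DEFAULT_MAX_JUMP = 12.0  # px/frame
DEFAULT_MAX_GAP = 5  # frames
DEFAULT_HAND_BOX = (40, 40)  # px (width, height)

#: Per-frame position source codes.
SOURCE_MISSING = "missing"
SOURCE_DETECTED = "detected"
SOURCE_INTERPOLATED = "interpolated"
SOURCE_CORRECTED = "corrected"

HANDS = ("left", "right")


@dataclasses.dataclass
class BlobDetection:
    """One bright connected component."""

    centroid: tuple[float, float]  # (x, y), unweighted pixel mean
    pixel_count: int
    peak_brightness: float


@dataclasses.dataclass
class WristTrack:
    """Per-frame positions of one wrist; NaN rows are missing frames."""

    person_id: int
    hand: str  # "left" | "right"
    positions: np.ndarray  # (n_frames, 2) float, (x, y)
    source: np.ndarray  # (n_frames,) object array of source codes

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise InputError("positions must be (n_frames, 2)")
        if len(self.source) != len(self.positions):
            raise InputError("source flags must match frame count")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.positions).all(axis=1)

    def validate_jumps(self, max_jump: float) -> None:
        """Check that adjacent non-missing positions are <= max_jump apart."""
        ok = ~self.missing
        for t in range(len(self) - 1):
            if ok[t] and ok[t + 1]:
                d = np.linalg.norm(self.positions[t + 1] - self.positions[t])
                if d > max_jump:
                    raise InputError(
                        f"track person {self.person_id} {self.hand}: jump of "
                        f"{d:.1f} px at frame {t + 1} exceeds max_jump={max_jump}"
                    )


def default_threshold(frame: np.ndarray) -> float:
    """Default detection threshold for a frame.

    Halfway between the frame's 90th brightness percentile (inside the
    clothing/body texture range) and its maximum (the markers). The
    midpoint — rather than a high percentile alone — keeps every marker
    pixel above and every non-marker pixel below the threshold as long as
    markers are much brighter than clothing and occupy less than 10% of
    the frame, which holds for any plausible seated-audience framing.
    """
    frame = np.asarray(frame, dtype=float)
    return 0.5 * (np.percentile(frame, 90.0) + frame.max())


def detect_blobs(
    frame: np.ndarray,
    threshold: float,
    min_blob_size: int = DEFAULT_MIN_BLOB_SIZE,
) -> list[BlobDetection]:
    """Bright connected components (8-connectivity) of pixels >= threshold.

    Components smaller than ``min_blob_size`` pixels are discarded.
    Output is sorted by centroid (y, x); an empty list is valid.
    """
    if not 0 < threshold < 255:
        raise InputError("threshold must lie in (0, 255)")
    frame = np.asarray(frame, dtype=float)
    labels = measure.label(frame >= threshold, connectivity=2)
    blobs = []
    for region in measure.regionprops(labels, intensity_image=frame):
        if region.num_pixels < min_blob_size:
            continue
        cy, cx = region.centroid
        blobs.append(
            BlobDetection(
                centroid=(float(cx), float(cy)),
                pixel_count=int(region.num_pixels),
                peak_brightness=float(region.intensity_max),
            )
        )
    blobs.sort(key=lambda b: (b.centroid[1], b.centroid[0]))
    return blobs


def _match_two(
    prev: list[tuple[int, np.ndarray]], cands: list[np.ndarray]
) -> list[tuple[int, int]]:
    """Minimum-total-displacement assignment of <=2 candidates to <=2 hands.

    ``prev`` holds (hand_index, last_position); returns (hand, candidate)
    pairs. With at most 2x2 the optimum is found by enumerating both
    pairings.
    """
    if not prev or not cands:
        return []
    if len(prev) == 1 or len(cands) == 1:
        best = min(
            ((h, c, np.linalg.norm(p - cands[c]))
             for h, p in prev for c in range(len(cands))),
            key=lambda t: t[2],
        )
        return [(best[0], best[1])]
    (h0, p0), (h1, p1) = prev[0], prev[1]
    straight = np.linalg.norm(p0 - cands[0]) + np.linalg.norm(p1 - cands[1])
    crossed = np.linalg.norm(p0 - cands[1]) + np.linalg.norm(p1 - cands[0])
    if straight <= crossed:
        return [(h0, 0), (h1, 1)]
    return [(h0, 1), (h1, 0)]


def link_tracks(
    detections: Sequence[Sequence[BlobDetection]],
    envelopes: Sequence[np.ndarray],
    max_jump: float = DEFAULT_MAX_JUMP,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[WristTrack]:
    """Link per-frame detections into left/right wrist tracks per person.

    Detections are routed to persons by envelope membership. Within an
    envelope, blobs are matched to the previous wrist positions by
    minimum total displacement, gated at ``max_jump`` px against the
    immediately preceding detected position. At track birth the leftmost
    blob is the left hand. If more than two blobs persist in an envelope
    the smallest (by pixel count) are dropped with a warning. Gaps of at
    most ``max_gap`` frames are linearly interpolated and flagged.
    """
    n_frames = len(detections)
    if n_frames == 0:
        raise InputError("no frames of detections")
    n_persons = len(envelopes)
    pos = np.full((n_persons, 2, n_frames, 2), np.nan)
    last_pos: list[list[np.ndarray | None]] = [[None, None] for _ in range(n_persons)]
    last_detected: list[list[bool]] = [[False, False] for _ in range(n_persons)]

    for t, frame_blobs in enumerate(detections):
        if frame_blobs:
            cents = np.array([b.centroid for b in frame_blobs], dtype=float)
        else:
            cents = np.empty((0, 2))
        for p, env in enumerate(envelopes):
            inside = (
                points_in_polygon(cents, np.asarray(env, dtype=float))
                if len(cents)
                else np.zeros(0, dtype=bool)
            )
            blobs = [frame_blobs[i] for i in np.flatnonzero(inside)]
            if len(blobs) > 2:
                logger.warning(
                    "frame %d person %d: %d blobs in envelope, dropping the "
                    "smallest %d", t, p, len(blobs), len(blobs) - 2,
                )
                blobs = sorted(blobs, key=lambda b: -b.pixel_count)[:2]
            cand = [np.array(b.centroid) for b in blobs]
            born = last_pos[p][0] is None and last_pos[p][1] is None
            assigned = [False, False]
            if born:
                order = np.argsort([c[0] for c in cand])  # leftmost first
                for hand, ci in zip(range(len(cand)), order):
                    pos[p, hand, t] = cand[ci]
                    last_pos[p][hand] = cand[ci]
                    last_detected[p][hand] = True
                    assigned[hand] = True
            else:
                prev = [
                    (h, last_pos[p][h]) for h in range(2) if last_pos[p][h] is not None
                ]
                used = set()
                for hand, ci in _match_two(prev, cand):
                    if ci in used:
                        continue
                    d = np.linalg.norm(cand[ci] - last_pos[p][hand])
                    # Gate only against an immediately preceding detection;
                    # after a gap, re-acquire freely.
                    if last_detected[p][hand] and d > max_jump:
                        continue
                    pos[p, hand, t] = cand[ci]
                    last_pos[p][hand] = cand[ci]
                    used.add(ci)
                    assigned[hand] = True
                # A leftover candidate may found a not-yet-born hand.
                free = [ci for ci in range(len(cand)) if ci not in used]
                for hand in range(2):
                    if last_pos[p][hand] is None and free:
                        ci = free.pop(0)
                        pos[p, hand, t] = cand[ci]
                        last_pos[p][hand] = cand[ci]
                        assigned[hand] = True
            for hand in range(2):
                last_detected[p][hand] = assigned[hand]

    tracks = []
    for p in range(n_persons):
        for hand in range(2):
            positions = pos[p, hand]
            source = np.array(
                [
                    SOURCE_DETECTED if np.isfinite(positions[t]).all()
                    else SOURCE_MISSING
                    for t in range(n_frames)
                ],
                dtype=object,
            )
            _interpolate_gaps(positions, source, max_gap)
            tracks.append(
                WristTrack(person_id=p, hand=HANDS[hand],
                           positions=positions, source=source)
            )
    return tracks


def _interpolate_gaps(positions: np.ndarray, source: np.ndarray, max_gap: int):
    """Fill runs of <= max_gap missing frames between detections, in place."""
    n = len(positions)
    detected = np.flatnonzero(np.isfinite(positions).all(axis=1))
    for a, b in zip(detected[:-1], detected[1:]):
        gap = b - a - 1
        if 0 < gap <= max_gap:
            for t in range(a + 1, b):
                w = (t - a) / (b - a)
                positions[t] = (1 - w) * positions[a] + w * positions[b]
                source[t] = SOURCE_INTERPOLATED


@dataclasses.dataclass
class Correction:
    """One manual-override instruction for a track stretch.

    ``action`` is ``set`` (place the wrist at (x, y) over the frame
    range), ``swap`` (exchange the person's left/right tracks), or
    ``drop`` (mark the range missing).
    """

    person_id: int
    hand: str
    frame_start: int
    frame_end: int  # inclusive
    action: str
    x: float = np.nan
    y: float = np.nan


def apply_corrections(
    tracks: list[WristTrack],
    corrections: Sequence[Correction],
    max_jump: float = DEFAULT_MAX_JUMP,
) -> list[WristTrack]:
    """Apply a correction table and re-validate all track invariants.

    Returns new tracks; the inputs are not modified. Corrections that
    reference unknown persons/hands/frames, or whose splice violates the
    ``max_jump`` continuity invariant, raise an input error naming the
    offending reference or frame.
    """
    out = [
        WristTrack(t.person_id, t.hand, t.positions.copy(), t.source.copy())
        for t in tracks
    ]
    index = {(t.person_id, t.hand): t for t in out}
    for c in corrections:
        if c.action not in ("set", "swap", "drop"):
            raise InputError(f"unknown correction action {c.action!r}")
        key = (c.person_id, c.hand if c.action != "swap" else "left")
        if c.action == "swap":
            left = index.get((c.person_id, "left"))
            right = index.get((c.person_id, "right"))
            if left is None or right is None:
                raise InputError(f"no tracks for person {c.person_id}")
            targets = [left, right]
        else:
            track = index.get((c.person_id, c.hand))
            if track is None:
                raise InputError(
                    f"no track for person {c.person_id} hand {c.hand!r}"
                )
            targets = [track]
        n = len(targets[0])
        if not (0 <= c.frame_start <= c.frame_end < n):
            raise InputError(
                f"correction frames [{c.frame_start}, {c.frame_end}] out of "
                f"range for {n}-frame track"
            )
        sl = slice(c.frame_start, c.frame_end + 1)
        if c.action == "set":
            if not (np.isfinite(c.x) and np.isfinite(c.y)):
                raise InputError("'set' correction needs finite x, y")
            targets[0].positions[sl] = (c.x, c.y)
            targets[0].source[sl] = SOURCE_CORRECTED
        elif c.action == "drop":
            targets[0].positions[sl] = np.nan
            targets[0].source[sl] = SOURCE_MISSING
        else:  # swap
            left, right = targets
            lp = left.positions[sl].copy()
            left.positions[sl] = right.positions[sl]
            right.positions[sl] = lp
            ls = left.source[sl].copy()
            left.source[sl] = right.source[sl]
            right.source[sl] = ls
            left.source[sl] = np.where(
                left.source[sl] == SOURCE_MISSING, SOURCE_MISSING, SOURCE_CORRECTED
            )
            right.source[sl] = np.where(
                right.source[sl] == SOURCE_MISSING, SOURCE_MISSING, SOURCE_CORRECTED
            )
    for t in out:
        t.validate_jumps(max_jump)
    return out


def hand_regions(
    track: WristTrack,
    box: tuple[int, int] = DEFAULT_HAND_BOX,
    frame_size: tuple[int, int] | None = None,
) -> list[RegionMask]:
    """Axis-aligned hand rectangle anchored on the wrist, per frame.

    The box is centered on the wrist position and integer-aligned by
    flooring (center - half extent); even sizes therefore bias one pixel
    toward the top-left. Rectangles are clipped to the frame; missing
    frames yield empty masks. ``frame_size`` is (width, height).
    """
    bw, bh = box
    if bw <= 0 or bh <= 0:
        raise InputError("hand box must be positive")
    if frame_size is None:
        raise InputError("frame_size (width, height) is required")
    w, h = frame_size
    shape = (h, w)
    masks = []
    for t in range(len(track)):
        x, y = track.positions[t]
        if not (np.isfinite(x) and np.isfinite(y)):
            masks.append(RegionMask.empty(shape))
            continue
        x0 = int(np.floor(x - bw / 2))
        y0 = int(np.floor(y - bh / 2))
        masks.append(RegionMask.from_rect(shape, x0, y0, x0 + bw, y0 + bh))
    return masks


def paired_hand_masks(
    left: list[RegionMask], right: list[RegionMask]
) -> list[tuple[RegionMask, RegionMask]]:
    """Zip per-hand mask lists into the (left, right) pairs series expect."""
    if len(left) != len(right):
        raise InputError("left/right mask lists differ in length")
    return list(zip(left, right))
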