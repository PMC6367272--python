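"""Synthetic audience scenes, coupled series, and ratings tables.

Every downstream stage of the pipeline (blob tracking, flow integration,
Granger scans, mixed models) is exercised against data from this module,
which provides ground truth no real recording can: exact wrist
trajectories, exact per-person motion, programmed engagement levels,
known lagged couplings, and known rating effects.

The rendered world: N seated persons, each confined to a static polygonal
envelope, drawn as a speckle-textured torso ellipse plus head disc (so
optical flow has gray-value gradients to work with), with two bright
marker discs at the wrists emulating reflective wristbands. Two motion
processes drive each person:

* **sway** — slow sinusoidal drift of the whole body (head/torso postural
  sway), peak per-frame displacement ``sway_amplitude`` px/frame;
* **fidgeting** — short hand excursions that leave and return to a rest
  position. Bursts occur once per interval of length 60/``fidget_rate``
  seconds, uniformly jittered within the interval, each displacing one
  randomly chosen hand along a random direction with a smooth
  rise-and-return kernel whose peak per-frame displacement is
  ``fidget_amplitude`` px/frame.

A jittered-regular burst train is used instead of a homogeneous Poisson
process so that the programmed fidget intensity is tightly controlled:
the generator is a calibration instrument, and Poisson count noise at the
short durations tests can afford would blur the programmed effect sizes
while adding no realism the pipeline is sensitive to.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi

from .flow import ConfigurationError, FrameSequence, InputError

logger = logging.getLogger(__name__)

# Gray-level layout of the rendered world (8-bit). The background is a
# static low-contrast speckle (venue clutter: seats, floor, clothing of
# out-of-envelope neighbors) rather than a flat field: optical flow is
# ill-posed on untextured regions, and a flat background would turn
# sensor noise into large spurious flow no real recording exhibits.
BACKGROUND_MIN = 10
BACKGROUND_MAX = 36
TEXTURE_MIN = 40
TEXTURE_MAX = 120

#: Rise-and-return kernel time constant for fidget bursts, seconds.
FIDGET_TAU = 0.4

#: Postural sway angular frequencies, rad/s (x and y components).
SWAY_OMEGA = (2 * math.pi * 0.25, 2 * math.pi * 0.17)


def _as_per_person(value, n: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.full(n, arr.item())
    if arr.size != n:
        raise ConfigurationError(f"{name} must be scalar or length {n}")
    return arr


@dataclasses.dataclass
class SceneConfig:
    """Parameters of a synthetic audience scene.

    ``fidget_rate``, ``fidget_amplitude`` and ``sway_amplitude`` accept a
    scalar (shared by all persons) or one value per person, which is how
    distinct programmed engagement levels are expressed.
    """

    n_persons: int = 2
    frame_size: tuple[int, int] = (256, 256)  # (width, height)
    fps: float = 30.0
    duration: float = 30.0  # seconds
    envelopes: list[np.ndarray] | None = None  # one polygon per person
    fidget_rate: float | Sequence[float] = 12.0  # bursts/minute
    fidget_amplitude: float | Sequence[float] = 2.0  # px/frame, peak
    sway_amplitude: float | Sequence[float] = 0.3  # px/frame, peak
    marker_brightness: int = 255
    marker_radius: float = 3.0  # px
    background_noise_sd: float = 3.0  # gray levels, truncated at 3 sd
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ConfigurationError("n_persons must be >= 1")
        if self.envelopes is None:
            self.envelopes = default_envelopes(self.n_persons, self.frame_size)
        self.envelopes = [np.asarray(e, dtype=float) for e in self.envelopes]
        if len(self.envelopes) != self.n_persons:
            raise ConfigurationError(
                f"{len(self.envelopes)} envelopes for {self.n_persons} persons"
            )
        for e in self.envelopes:
            if e.ndim != 2 or e.shape[0] < 3 or e.shape[1] != 2:
                raise ConfigurationError("each envelope needs >= 3 (x, y) vertices")
        if self.marker_brightness <= TEXTURE_MAX + 6 * self.background_noise_sd:
            raise ConfigurationError(
                "marker_brightness must exceed the brightest non-marker gray "
                f"level ({TEXTURE_MAX} + noise) by at least 3 noise sd"
            )

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))


@dataclasses.dataclass
class SceneGroundTruth:
    """Exact trajectories and programmed engagement behind a rendered scene."""

    true_wrist_paths: np.ndarray  # (n_persons, 2 hands, n_frames, 2) x,y
    true_person_speed: np.ndarray  # (n_persons, n_frames - 1)
    true_engagement: np.ndarray  # (n_persons,) in [0, 1]
    body_centers: np.ndarray  # (n_persons, n_frames, 2)


def default_envelopes(
    n_persons: int, frame_size: tuple[int, int], margin: float = 0.04
) -> list[np.ndarray]:
    """Rectangular envelopes on a near-square grid covering the frame."""
    w, h = frame_size
    ncols = int(math.ceil(math.sqrt(n_persons)))
    nrows = int(math.ceil(n_persons / ncols))
    cw, ch = w / ncols, h / nrows
    out = []
    for i in range(n_persons):
        r, c = divmod(i, ncols)
        x0, y0 = c * cw + margin * cw, r * ch + margin * ch
        x1, y1 = (c + 1) * cw - margin * cw, (r + 1) * ch - margin * ch
        out.append(np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]]))
    return out


def _check_disjoint(envelopes: list[np.ndarray], frame_size: tuple[int, int]) -> None:
    # Disjointness is checked on the rasterized masks, i.e. under the same
    # pixel-center convention every downstream mask uses.
    from .series import polygon_mask

    shape = (frame_size[1], frame_size[0])
    acc = np.zeros(shape, dtype=bool)
    for i, env in enumerate(envelopes):
        m = polygon_mask(env, shape).mask
        if (acc & m).any():
            raise ConfigurationError(f"envelope {i} overlaps an earlier envelope")
        acc |= m


def _burst_times(rng: np.random.Generator, rate_per_min: float, duration: float):
    """One burst per interval of 60/rate s, uniformly placed within it."""
    if rate_per_min <= 0:
        return np.empty(0)
    delta = 60.0 / rate_per_min
    n = int(math.floor(duration / delta))
    return (np.arange(n) + rng.uniform(0.0, 1.0, size=n)) * delta


def _fidget_offsets(
    rng: np.random.Generator,
    amplitude: float,
    rate_per_min: float,
    n_frames: int,
    fps: float,
) -> np.ndarray:
    """Per-hand wrist offsets, shape (2 hands, n_frames, 2).

    Each burst displaces one hand by D * K((t - t_b)) along a random unit
    direction, with K(s) = (s/tau) * exp(1 - s/tau): a smooth excursion
    that rises from and returns to the rest position. D is chosen so the
    peak per-frame displacement equals ``amplitude`` px/frame.
    """
    offsets = np.zeros((2, n_frames, 2))
    times = _burst_times(rng, rate_per_min, n_frames / fps)
    if amplitude <= 0 or times.size == 0:
        return offsets
    peak_disp = amplitude * FIDGET_TAU * fps / math.e
    t = np.arange(n_frames) / fps
    for t_b in times:
        hand = rng.integers(0, 2)
        theta = rng.uniform(0, 2 * math.pi)
        direction = np.array([math.cos(theta), math.sin(theta)])
        s = t - t_b
        k = np.where(s > 0, (s / FIDGET_TAU) * np.exp(1 - s / FIDGET_TAU), 0.0)
        offsets[hand] += peak_disp * np.outer(k, direction)
    return offsets


def _sway_offsets(
    rng: np.random.Generator, amplitude: float, n_frames: int, fps: float
) -> np.ndarray:
    """Whole-body sinusoidal offset path, shape (n_frames, 2)."""
    t = np.arange(n_frames) / fps
    out = np.zeros((n_frames, 2))
    phases = rng.uniform(0, 2 * math.pi, size=2)
    if amplitude <= 0:
        return out
    for axis, (omega, phi) in enumerate(zip(SWAY_OMEGA, phases)):
        # Peak per-frame displacement of each component = amplitude / sqrt(2).
        a = amplitude * fps / omega / math.sqrt(2.0)
        out[:, axis] = a * np.sin(omega * t + phi)
    return out


def _speckle_texture(
    shape: tuple[int, int],
    rng: np.random.Generator,
    lo: float = TEXTURE_MIN,
    hi: float = TEXTURE_MAX,
) -> np.ndarray:
    """Fixed random speckle with spatial gradients, scaled into [lo, hi]."""
    tex = rng.uniform(0.0, 1.0, size=shape)
    tex = ndi.gaussian_filter(tex, 0.8, mode="wrap")
    tmin, tmax = tex.min(), tex.max()
    tex = (tex - tmin) / max(tmax - tmin, 1e-12)
    return lo + tex * (hi - lo)


def _draw_disc(frame: np.ndarray, center: np.ndarray, radius: float, value: float):
    h, w = frame.shape
    cx, cy = center
    x0, x1 = max(0, int(cx - radius) - 1), min(w, int(cx + radius) + 2)
    y0, y1 = max(0, int(cy - radius) - 1), min(h, int(cy + radius) + 2)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    frame[y0:y1, x0:x1][inside] = value


class _PersonGeometry:
    """Static body layout of one person within an envelope bounding box."""

    def __init__(self, envelope: np.ndarray, rng: np.random.Generator):
        x0, y0 = envelope.min(axis=0)
        x1, y1 = envelope.max(axis=0)
        self.bbox = (x0, y0, x1, y1)
        w, h = x1 - x0, y1 - y0
        self.center = np.array([(x0 + x1) / 2, (y0 + y1) / 2])
        self.torso_center = self.center + [0.0, 0.12 * h]
        self.torso_axes = (0.26 * w, 0.30 * h)
        self.head_center = self.center + [0.0, -0.22 * h]
        self.head_radius = 0.13 * min(w, h)
        self.wrist_base = np.stack(
            [
                self.center + [-0.28 * w, 0.18 * h],  # left
                self.center + [0.28 * w, 0.18 * h],  # right
            ]
        )
        self.texture = _speckle_texture(
            (int(math.ceil(h)) + 4, int(math.ceil(w)) + 4), rng
        )

    def paint(self, frame: np.ndarray, offset: np.ndarray) -> None:
        """Draw the textured body translated by ``offset`` (bilinear subpixel)."""
        h, w = frame.shape
        x0, y0, x1, y1 = self.bbox
        gx0 = max(0, int(math.floor(x0 + offset[0])) - 2)
        gy0 = max(0, int(math.floor(y0 + offset[1])) - 2)
        gx1 = min(w, int(math.ceil(x1 + offset[0])) + 2)
        gy1 = min(h, int(math.ceil(y1 + offset[1])) + 2)
        if gx0 >= gx1 or gy0 >= gy1:
            return
        yy, xx = np.mgrid[gy0:gy1, gx0:gx1]
        tcx, tcy = self.torso_center + offset
        hcx, hcy = self.head_center + offset
        a, b = self.torso_axes
        body = ((xx - tcx) / a) ** 2 + ((yy - tcy) / b) ** 2 <= 1.0
        body |= (xx - hcx) ** 2 + (yy - hcy) ** 2 <= self.head_radius**2
        if not body.any():
            return
        # Texture sampled in body-local coordinates, so it translates rigidly.
        ty = yy[body] - (y0 + offset[1]) + 2.0
        tx = xx[body] - (x0 + offset[0]) + 2.0
        vals = ndi.map_coordinates(
            self.texture, np.stack([ty, tx]), order=1, mode="nearest"
        )
        region = frame[gy0:gy1, gx0:gx1]
        region[body] = vals


def generate_scene(config: SceneConfig) -> tuple[FrameSequence, SceneGroundTruth]:
    """Render a seeded audience scene and return it with its ground truth.

    Deterministic given ``config.seed``: the same configuration yields
    bit-identical frames. ``true_person_speed`` is the mean, over the
    person's three tracked points (two wrists and the body center), of the
    per-frame displacement magnitude along the stored true paths.
    """
    n_frames = config.n_frames
    if n_frames < 2:
        raise InputError("duration * fps must be at least 2 frames")
    _check_disjoint(config.envelopes, config.frame_size)

    n = config.n_persons
    rates = _as_per_person(config.fidget_rate, n, "fidget_rate")
    amps = _as_per_person(config.fidget_amplitude, n, "fidget_amplitude")
    sways = _as_per_person(config.sway_amplitude, n, "sway_amplitude")
    w, h = config.frame_size
    rng = np.random.default_rng(config.seed)

    geoms = [_PersonGeometry(env, rng) for env in config.envelopes]
    sway_paths = np.stack(
        [_sway_offsets(rng, sways[p], n_frames, config.fps) for p in range(n)]
    )
    fidget_paths = np.stack(
        [
            _fidget_offsets(rng, amps[p], rates[p], n_frames, config.fps)
            for p in range(n)
        ]
    )  # (n, 2, n_frames, 2)

    wrist_paths = np.empty((n, 2, n_frames, 2))
    centers = np.empty((n, n_frames, 2))
    for p in range(n):
        centers[p] = geoms[p].center + sway_paths[p]
        for hand in range(2):
            wrist_paths[p, hand] = (
                geoms[p].wrist_base[hand] + sway_paths[p] + fidget_paths[p, hand]
            )

    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    base = _speckle_texture((h, w), rng, BACKGROUND_MIN, BACKGROUND_MAX)
    for t in range(n_frames):
        frame = base.copy()
        if config.background_noise_sd > 0:
            noise = rng.normal(0.0, config.background_noise_sd, size=(h, w))
            lim = 3 * config.background_noise_sd
            frame += np.clip(noise, -lim, lim)
        for p in range(n):
            geoms[p].paint(frame, sway_paths[p, t])
            for hand in range(2):
                _draw_disc(
                    frame,
                    wrist_paths[p, hand, t],
                    config.marker_radius,
                    config.marker_brightness,
                )
        frames[t] = np.clip(frame, 0, 255).astype(np.uint8)

    # Ground-truth speed by direct differencing of the stored paths.
    pts = np.concatenate([wrist_paths, centers[:, None]], axis=1)  # (n, 3, T, 2)
    step = np.linalg.norm(np.diff(pts, axis=2), axis=-1)  # (n, 3, T-1)
    true_speed = step.mean(axis=1)

    # Programmed engagement: a fixed monotone-decreasing map of fidget
    # intensity (rate * amplitude), normalized by the default intensity.
    ref = 12.0 * 2.0
    engagement = np.exp(-(rates * amps) / ref)

    seq = FrameSequence(frames=frames, fps=config.fps)
    truth = SceneGroundTruth(
        true_wrist_paths=wrist_paths,
        true_person_speed=true_speed,
        true_engagement=engagement,
        body_centers=centers,
    )
    return seq, truth


def generate_stage(
    frame_size: tuple[int, int] = (256, 256),
    fps: float = 30.0,
    duration: float = 30.0,
    motion_level: float = 2.0,
    seed: int = 0,
) -> FrameSequence:
    """A separate performer-view sequence with a programmed motion level.

    Two textured elliptical figures translate along slow Lissajous paths
    whose peak per-frame displacement is ``motion_level`` px/frame.
    """
    if motion_level < 0:
        raise InputError("motion_level must be >= 0")
    w, h = frame_size
    n_frames = int(round(duration * fps))
    if n_frames < 2:
        raise InputError("duration * fps must be at least 2 frames")
    rng = np.random.default_rng(seed)
    figures = []
    for cx in (0.3 * w, 0.7 * w):
        env = np.array(
            [
                [cx - 0.18 * w, 0.25 * h],
                [cx + 0.18 * w, 0.25 * h],
                [cx + 0.18 * w, 0.85 * h],
                [cx - 0.18 * w, 0.85 * h],
            ]
        )
        geom = _PersonGeometry(env, rng)
        path = _sway_offsets(rng, motion_level, n_frames, fps)
        figures.append((geom, path))
    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    base = _speckle_texture((h, w), rng, BACKGROUND_MIN, BACKGROUND_MAX)
    for t in range(n_frames):
        frame = base.copy()
        frame += np.clip(rng.normal(0.0, 2.0, size=(h, w)), -6, 6)
        for geom, path in figures:
            geom.paint(frame, path[t])
        frames[t] = np.clip(frame, 0, 255).astype(np.uint8)
    return FrameSequence(frames=frames, fps=fps)


def generate_coupled_series(
    n: int, lag: int, coupling: float, noise_sd: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """A pair of 1 Hz series with a known lagged linear dependence.

    ``y_t = coupling * x_{t-lag} + eps_t`` with white-noise x ~ N(0, 1)
    and eps ~ N(0, noise_sd^2); the first ``lag`` samples of y are noise
    only. Used to calibrate the Granger-causality scan.
    """
    if lag <= 0:
        raise InputError("lag must be a positive number of samples")
    if not n > 10 * lag:
        raise InputError("n must exceed 10 * lag")
    if not abs(coupling) < 1:
        raise InputError("|coupling| must be < 1")
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, size=n)
    eps = rng.normal(0.0, noise_sd, size=n)
    y = eps.copy()
    y[lag:] += coupling * x[:-lag]
    return x, y


def generate_ratings(
    n_participants: int,
    n_clips: int,
    effect: float,
    seed: int,
    *,
    baseline: float = 5.0,
    participant_sd: float = 1.0,
    noise_sd: float = 1.0,
) -> "pd.DataFrame":
    """Simulated engagement ratings for movement-extreme audience clips.

    Each participant rates every clip on the 0-10 engagement scale; half
    the clips are labeled ``moving``, half ``non_moving``. The generating
    model is ``rating = baseline + b_participant + effect * [non_moving]
    + noise``, truncated to [0, 10]. ``dance_connection`` (performer vs
    non-performer) and ``attendance`` (0-4 yearly) are participant-level
    covariates with no programmed effect.
    """
    import pandas as pd

    if n_participants < 0 or n_clips < 0:
        raise InputError("counts must be non-negative")
    if n_clips % 2 != 0:
        raise InputError("n_clips must be even (half moving, half non-moving)")
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, participant_sd, size=n_participants)
    connection = rng.permutation(
        ["performer" if i < n_participants // 2 else "non_performer"
         for i in range(n_participants)]
    )
    attendance = rng.integers(0, 5, size=n_participants)
    states = ["non_moving" if c < n_clips // 2 else "moving" for c in range(n_clips)]
    rows = []
    for p in range(n_participants):
        for c in range(n_clips):
            state = states[c]
            value = baseline + b[p] + effect * (state == "non_moving")
            if noise_sd > 0:
                value += rng.normal(0.0, noise_sd)
            rows.append(
                {
                    "participant_id": f"p{p:02d}",
                    "clip_id": f"clip{c:02d}",
                    "movement_state": state,
                    "engagement": float(np.clip(value, 0.0, 10.0)),
                    "dance_connection": connection[p],
                    "attendance": int(attendance[p]),
                }
            )
    return pd.DataFrame(rows)
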