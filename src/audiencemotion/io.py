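"""File formats, configuration, logging setup, and the pipeline runner.

On-disk formats (all plain text or PNG):

* frames: directory of zero-padded grayscale PNGs plus a ``frames.json``
  sidecar ``{"fps", "width", "height", "t0"}``;
* envelopes: JSON list of ``{"person_id", "polygon": [[x, y], ...]}``
  in 0-based pixel coordinates, top-left origin;
* series CSV: ``entity_id, body_part, rate_hz, t_start_s, value`` —
  one row per sample, values printed with 9 significant digits, missing
  samples as an empty field;
* tracks CSV: ``person_id, hand, frame, x, y, source``;
* corrections CSV: ``person_id, hand, frame_start, frame_end, action,
  x, y`` with action in {set, swap, drop};
* GC report CSV: ``part, pairing, direction, lag_s, F, df1, df2, p,
  significant_0.05``.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import pathlib
from typing import Any, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import causality, series as series_mod, stats, synthetic, tracking
from .flow import (
    FrameSequence,
    InputError,
    MotionSeries,
    iter_flow_fields,
    frame_motion_series,
)

logger = logging.getLogger("audiencemotion")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


class ParseError(ValueError):
    """Malformed input file; carries the offending path and line."""


# ---------------------------------------------------------------------------
# Frames
# ---------------------------------------------------------------------------

def write_frames(seq: FrameSequence, directory) -> pathlib.Path:
    """Write a sequence as zero-padded PNGs plus a JSON sidecar."""
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    digits = max(5, len(str(len(seq) - 1)))
    for i, frame in enumerate(seq.frames):
        iio.imwrite(
            directory / f"frame_{i:0{digits}d}.png",
            np.asarray(frame, dtype=np.uint8),
        )
    h, w = seq.frame_shape
    sidecar = {"fps": seq.fps, "width": w, "height": h, "t0": seq.t0}
    (directory / "frames.json").write_text(json.dumps(sidecar, indent=2))
    return directory


def read_frames(directory) -> FrameSequence:
    directory = pathlib.Path(directory)
    sidecar_path = directory / "frames.json"
    if not sidecar_path.exists():
        raise ParseError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    paths = sorted(directory.glob("frame_*.png"))
    if len(paths) < 2:
        raise ParseError(f"{directory}: fewer than 2 frames")
    frames = np.stack([iio.imread(p) for p in paths])
    return FrameSequence(
        frames=frames, fps=float(sidecar["fps"]), t0=float(sidecar.get("t0", 0.0))
    )


# ---------------------------------------------------------------------------
# Envelopes
# ---------------------------------------------------------------------------

def write_envelopes(envelopes: Sequence[np.ndarray], path) -> None:
    payload = [
        {"person_id": i, "polygon": np.asarray(e, dtype=float).tolist()}
        for i, e in enumerate(envelopes)
    ]
    pathlib.Path(path).write_text(json.dumps(payload, indent=2))


def read_envelopes(path) -> list[np.ndarray]:
    """Read the envelopes JSON; polygons are validated (>= 3 vertices)."""
    path = pathlib.Path(path)
    if not path.exists():
        raise ParseError(f"envelopes file not found: {path}")
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
    out = []
    for i, entry in enumerate(payload):
        poly = np.asarray(entry["polygon"], dtype=float)
        if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
            raise ParseError(
                f"{path}: entry {i}: polygon needs >= 3 (x, y) vertices"
            )
        out.append(poly)
    return out


# ---------------------------------------------------------------------------
# Series CSV
# ---------------------------------------------------------------------------

def write_series_csv(series_list: Sequence[MotionSeries], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["entity_id", "body_part", "rate_hz", "t_start_s", "value"])
        for s in series_list:
            for i, v in enumerate(s.values):
                t = s.t0 + i / s.rate
                writer.writerow(
                    [
                        s.entity_id,
                        s.body_part,
                        f"{s.rate:.9g}",
                        f"{t:.9g}",
                        "" if not np.isfinite(v) else f"{v:.9g}",
                    ]
                )


def read_series_csv(path) -> list[MotionSeries]:
    path = pathlib.Path(path)
    if not path.exists():
        raise ParseError(f"series file not found: {path}")
    groups: dict[tuple[str, str], dict[str, Any]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                key = (row["entity_id"], row["body_part"])
                rec = groups.setdefault(
                    key,
                    {"rate": float(row["rate_hz"]),
                     "t0": float(row["t_start_s"]),
                     "values": []},
                )
                v = row["value"]
                rec["values"].append(float(v) if v != "" else np.nan)
            except (KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return [
        MotionSeries(entity_id=k[0], body_part=k[1],
                     values=np.array(rec["values"]),
                     rate=rec["rate"], t0=rec["t0"])
        for k, rec in groups.items()
    ]


# ---------------------------------------------------------------------------
# Tracks and corrections CSV
# ---------------------------------------------------------------------------

def write_tracks_csv(tracks: Sequence[tracking.WristTrack], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["person_id", "hand", "frame", "x", "y", "source"])
        for t in tracks:
            for f in range(len(t)):
                x, y = t.positions[f]
                writer.writerow(
                    [
                        t.person_id, t.hand, f,
                        "" if not np.isfinite(x) else f"{x:.9g}",
                        "" if not np.isfinite(y) else f"{y:.9g}",
                        t.source[f],
                    ]
                )


def read_tracks_csv(path) -> list[tracking.WristTrack]:
    path = pathlib.Path(path)
    if not path.exists():
        raise ParseError(f"tracks file not found: {path}")
    rows: dict[tuple[int, str], list[tuple[int, float, float, str]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                key = (int(row["person_id"]), row["hand"])
                x = float(row["x"]) if row["x"] != "" else np.nan
                y = float(row["y"]) if row["y"] != "" else np.nan
                rows.setdefault(key, []).append(
                    (int(row["frame"]), x, y, row["source"])
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    tracks = []
    for (pid, hand), recs in sorted(rows.items()):
        recs.sort()
        positions = np.array([[x, y] for _, x, y, _ in recs])
        source = np.array([s for _, _, _, s in recs], dtype=object)
        tracks.append(
            tracking.WristTrack(person_id=pid, hand=hand,
                                positions=positions, source=source)
        )
    return tracks


def read_corrections_csv(path) -> list[tracking.Correction]:
    path = pathlib.Path(path)
    if not path.exists():
        raise ParseError(f"corrections file not found: {path}")
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(
                    tracking.Correction(
                        person_id=int(row["person_id"]),
                        hand=row["hand"],
                        frame_start=int(row["frame_start"]),
                        frame_end=int(row["frame_end"]),
                        action=row["action"],
                        x=float(row["x"]) if row.get("x") else np.nan,
                        y=float(row["y"]) if row.get("y") else np.nan,
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PartConfig:
    """One performance part of a synthetic study.

    Engagement modulates fidgeting as a whole — bursty hand movement and
    the slower head/torso sway — so a disengaged part raises both
    ``fidget_amplitude`` and ``sway_amplitude``. ``sway_amplitude`` of
    None inherits the pipeline-level default.
    """

    label: str
    fidget_amplitude: float | Sequence[float] = 2.0
    fidget_rate: float | Sequence[float] = 12.0
    sway_amplitude: float | Sequence[float] | None = None
    stage_motion_level: float = 2.0


@dataclasses.dataclass
class PipelineConfig:
    """Everything the end-to-end runner needs.

    Either ``frames_dir``/``envelopes_path`` point at recorded input, or
    ``parts`` describes a synthetic study to simulate. All tracking, flow
    and analysis parameters are explicit so runs are reproducible.
    """

    output_dir: str = "audiencemotion_out"
    frames_dir: str | None = None
    envelopes_path: str | None = None
    # synthetic study
    parts: list[PartConfig] | None = None
    n_persons: int = 4
    frame_size: tuple[int, int] = (128, 128)
    fps: float = 15.0
    duration: float = 60.0
    sway_amplitude: float = 0.3
    # tracking
    threshold: float | None = None  # None -> per-frame default
    min_blob_size: int = tracking.DEFAULT_MIN_BLOB_SIZE
    max_jump: float = tracking.DEFAULT_MAX_JUMP
    max_gap: int = tracking.DEFAULT_MAX_GAP
    hand_box: tuple[int, int] = tracking.DEFAULT_HAND_BOX
    corrections_path: str | None = None
    # flow
    max_displacement: float = 8.0
    # analysis
    max_lag: int = causality.DEFAULT_MAX_LAG
    window_s: float = stats.DEFAULT_WINDOW_S
    k_per_polarity: int = stats.DEFAULT_K_PER_POLARITY
    alpha: float = causality.DEFAULT_ALPHA
    seed: int = 0

    def validate(self) -> None:
        synth = self.parts is not None
        recorded = self.frames_dir is not None
        if not synth and not recorded:
            raise InputError(
                "config must provide either 'parts' (synthetic) or "
                "'frames_dir' (recorded input)"
            )
        if recorded and self.envelopes_path is None:
            raise InputError("recorded input requires 'envelopes_path'")
        if recorded and not pathlib.Path(self.frames_dir).exists():
            raise InputError(f"frames_dir does not exist: {self.frames_dir}")
        if self.envelopes_path is not None and not pathlib.Path(
            self.envelopes_path
        ).exists():
            raise InputError(
                f"envelopes file does not exist: {self.envelopes_path}"
            )


def load_config(path) -> PipelineConfig:
    """Load a YAML or JSON pipeline configuration."""
    path = pathlib.Path(path)
    if not path.exists():
        raise ParseError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config must be a mapping")
    parts = raw.pop("parts", None)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    if parts is not None:
        cfg.parts = [PartConfig(**p) for p in parts]
    if isinstance(cfg.frame_size, list):
        cfg.frame_size = tuple(cfg.frame_size)
    if isinstance(cfg.hand_box, list):
        cfg.hand_box = tuple(cfg.hand_box)
    return cfg


# ---------------------------------------------------------------------------
# Pipeline runner
# ---------------------------------------------------------------------------

def _track_scene(seq: FrameSequence, envelopes, cfg: PipelineConfig):
    thr = cfg.threshold if cfg.threshold is not None else (
        tracking.default_threshold(seq.frames[0])
    )
    detections = [
        tracking.detect_blobs(frame, thr, cfg.min_blob_size)
        for frame in seq.frames
    ]
    tracks = tracking.link_tracks(detections, envelopes, cfg.max_jump, cfg.max_gap)
    if cfg.corrections_path:
        tracks = tracking.apply_corrections(
            tracks, read_corrections_csv(cfg.corrections_path), cfg.max_jump
        )
    return tracks


def _scene_series(seq, envelopes, tracks, cfg: PipelineConfig):
    """All per-person body-part series for one scene, sharing flow fields."""
    h, w = seq.frame_shape
    fields = list(iter_flow_fields(seq, max_displacement=cfg.max_displacement))
    by_person = {}
    for t in tracks:
        by_person.setdefault(t.person_id, {})[t.hand] = t
    out = []
    for pid, env in enumerate(envelopes):
        eid = f"person{pid}"
        out.append(
            series_mod.upper_body_series(seq, env, entity_id=eid, fields=fields)
        )
        hands = by_person.get(pid, {})
        if "left" in hands and "right" in hands:
            masks = tracking.paired_hand_masks(
                tracking.hand_regions(hands["left"], cfg.hand_box, (w, h)),
                tracking.hand_regions(hands["right"], cfg.hand_box, (w, h)),
            )
            out.append(
                series_mod.hands_series(seq, masks, entity_id=eid, fields=fields)
            )
            out.append(
                series_mod.head_torso_series(
                    seq, env, masks, entity_id=eid, fields=fields
                )
            )
    return out


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full pipeline and write the report bundle.

    Stages: simulate (or load) -> track wrists -> body-part series ->
    1 Hz resampling -> body-part summary -> movement-extreme clip windows
    -> Granger scans (matched + mismatched when >= 2 parts) -> Spearman
    of per-part audience movement against programmed engagement rank.
    Deterministic given the config seed.
    """
    config.validate()
    out_dir = pathlib.Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: seed=%d output=%s", config.seed, out_dir)

    if config.parts is not None:
        part_data = _run_synthetic_parts(config)
    else:
        seq = read_frames(config.frames_dir)
        envelopes = read_envelopes(config.envelopes_path)
        tracks = _track_scene(seq, envelopes, config)
        native = _scene_series(seq, envelopes, tracks, config)
        part_data = {
            "recorded": {
                "tracks": tracks,
                "native": native,
                "stage": None,
                "engagement": None,
            }
        }

    bundle: dict[str, Any] = {"config_seed": config.seed, "parts": {}}
    series_by_segment: dict[str, list[MotionSeries]] = {}
    audience_1hz: dict[str, np.ndarray] = {}
    stage_1hz: dict[str, np.ndarray] = {}
    part_mean_movement: dict[str, float] = {}

    for label, data in part_data.items():
        native = data["native"]
        resampled = [series_mod.resample_1hz(s) for s in native]
        if data["stage"] is not None:
            stage_native = frame_motion_series(data["stage"])
            stage_res = series_mod.resample_1hz(stage_native)
            resampled.append(stage_res)
            stage_1hz[label] = stage_res.values
        series_by_segment[label] = resampled
        write_tracks_csv(data["tracks"], out_dir / f"{label}_tracks.csv")
        write_series_csv(native, out_dir / f"{label}_series_native.csv")
        write_series_csv(resampled, out_dir / f"{label}_series_1hz.csv")
        upper = [s for s in resampled if s.body_part == "upper_body"]
        if upper:
            pooled = np.nanmean(np.stack([s.values for s in upper]), axis=0)
            audience_1hz[label] = pooled
            part_mean_movement[label] = float(np.nanmean(pooled))
            mean_series = MotionSeries(
                "audience_mean", "upper_body", pooled, 1.0
            )
            try:
                clips = stats.select_extreme_windows(
                    mean_series, config.k_per_polarity, config.window_s,
                    part=label,
                )
            except InputError:
                clips = []
            bundle["parts"].setdefault(label, {})["clip_windows"] = [
                dataclasses.asdict(c) for c in clips
            ]
        bundle["parts"].setdefault(label, {})["engagement"] = (
            None if data["engagement"] is None else list(data["engagement"])
        )

    summary = series_mod.bodypart_summary(series_by_segment)
    summary.to_csv(out_dir / "bodypart_summary.csv", index=False)
    bundle["bodypart_summary"] = summary

    # Granger scans on differenced 1 Hz series.
    gc_frames = []
    if stage_1hz:
        diff_a = {
            k: causality.difference_series(v) for k, v in audience_1hz.items()
        }
        diff_s = {
            k: causality.difference_series(v) for k, v in stage_1hz.items()
        }
        if len(diff_a) >= 2:
            matched, mismatched, gc_summary = causality.mismatch_control(
                diff_a, diff_s, seed=config.seed, max_lag=config.max_lag,
                alpha=config.alpha,
            )
            gc_frames = [r.to_frame() for r in matched + mismatched]
            bundle["gc_summary"] = gc_summary
        else:
            (label, a), = diff_a.items()
            rep = causality.gc_scan(
                a, diff_s[label], config.max_lag, part=label, alpha=config.alpha
            )
            gc_frames = [rep.to_frame()]
        gc_report = pd.concat(gc_frames, ignore_index=True)
        gc_report.to_csv(out_dir / "gc_report.csv", index=False)
        bundle["gc_report"] = gc_report

    # Across-part rank agreement of movement with programmed engagement.
    engagements = {
        label: data["engagement"]
        for label, data in part_data.items()
        if data["engagement"] is not None
    }
    if 3 <= len(part_mean_movement) <= stats.MAX_EXACT_N and len(engagements) == len(
        part_mean_movement
    ):
        labels = sorted(part_mean_movement)
        movement = [part_mean_movement[lbl] for lbl in labels]
        disengagement = [1.0 - float(np.mean(engagements[lbl])) for lbl in labels]
        rho, p = stats.spearman_exact(movement, disengagement)
        bundle["movement_vs_disengagement"] = {
            "labels": labels, "movement": movement,
            "disengagement": disengagement, "rho": rho, "p": p,
        }
    bundle["part_mean_movement"] = part_mean_movement

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(_jsonable(bundle), fh, indent=2, sort_keys=True)
    logger.info("pipeline done: %d part(s)", len(part_data))
    return bundle


def _run_synthetic_parts(config: PipelineConfig) -> dict[str, dict[str, Any]]:
    part_data: dict[str, dict[str, Any]] = {}
    for i, part in enumerate(config.parts):
        scene_cfg = synthetic.SceneConfig(
            n_persons=config.n_persons,
            frame_size=config.frame_size,
            fps=config.fps,
            duration=config.duration,
            fidget_rate=part.fidget_rate,
            fidget_amplitude=part.fidget_amplitude,
            sway_amplitude=(
                part.sway_amplitude
                if part.sway_amplitude is not None
                else config.sway_amplitude
            ),
            seed=config.seed * 1009 + i,
        )
        logger.info("simulating part %s", part.label)
        seq, truth = synthetic.generate_scene(scene_cfg)
        stage = synthetic.generate_stage(
            frame_size=config.frame_size, fps=config.fps,
            duration=config.duration,
            motion_level=part.stage_motion_level,
            seed=config.seed * 2003 + i,
        )
        tracks = _track_scene(seq, scene_cfg.envelopes, config)
        native = _scene_series(seq, scene_cfg.envelopes, tracks, config)
        part_data[part.label] = {
            "tracks": tracks,
            "native": native,
            "stage": stage,
            "engagement": truth.true_engagement,
        }
    return part_data


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj
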