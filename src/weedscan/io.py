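"""Run harness: frame streams, detection runs, evaluation and benchmarking.

Inputs may be a video file, a directory of PNG/JPEG frames, or a synthetic
battery addressed as ``synthetic:<style>`` (see :mod:`weedscan.scenes`).
Frames are converted to the package's RGB channel convention at this
boundary; everything downstream assumes R, G, B order.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .color import ALGORITHMS, ThresholdProfile, get_profile, load_profile
from .evaluate import EvalResult, load_ground_truth, match_detections, precision_recall
from .pipeline import (
    Detection,
    PipelineConfig,
    annotate_frame,
    detections_to_csv,
    process_frame,
)
from .scenes import BATTERY_STYLES, scene_battery
from .zones import MockRelayBackend, ZoneConfig, assign_zone, drive_backend, schedule_activations

__all__ = ["RunConfig", "RunSummary", "run_detect", "run_evaluate", "run_benchmark"]

log = logging.getLogger(__name__)

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}
_VIDEO_SUFFIXES = {".mp4", ".avi", ".mov", ".mkv"}


@dataclass
class RunConfig:
    input: str  # path or "synthetic:<style>"
    algorithm: str = "exg"
    profile: str = "day"  # "day", "night" or a YAML profile path
    out_dir: str = "weedscan-out"
    min_area: int | None = None
    n_frames: int = 10  # frames to render for synthetic inputs
    seed: int = 0
    frame_interval_ms: float = 100.0
    save_video: bool = False  # annotated frames
    save_frames: bool = False  # raw frames
    write_csv: bool = True
    write_actuation_log: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.input.startswith("synthetic:"):
            style = self.input.split(":", 1)[1]
            if style not in BATTERY_STYLES:
                raise ValueError(f"unknown synthetic style {style!r}")
        elif not Path(self.input).exists():
            raise FileNotFoundError(f"input {self.input} does not exist")

    def resolve_profile(self) -> ThresholdProfile:
        if self.profile in ("day", "night"):
            prof = get_profile(self.profile, self.algorithm)
        else:
            prof = load_profile(self.profile)
        if self.min_area is not None:
            from dataclasses import replace

            prof = replace(prof, min_object_area=self.min_area)
        return prof

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class RunSummary:
    frames: int = 0
    detections: int = 0
    skipped_frames: int = 0
    mean_fps: float = 0.0
    outputs: list[str] = field(default_factory=list)


def _iter_frames(config: RunConfig):
    """Yield RGB uint8 frames from the configured input."""
    src = config.input
    if src.startswith("synthetic:"):
        style = src.split(":", 1)[1]
        for scene in scene_battery(style, config.n_frames, seed=config.seed):
            yield scene.frame
        return
    path = Path(src)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise OSError(f"no PNG/JPEG frames found in directory {path}")
        for p in files:
            frame = iio.imread(p)
            if frame.ndim == 2:
                frame = np.stack([frame] * 3, axis=-1)
            yield frame[..., :3]
        return
    if path.suffix.lower() in _VIDEO_SUFFIXES:
        try:
            for frame in iio.imiter(path):
                yield np.asarray(frame)[..., :3]
        except Exception as exc:  # pragma: no cover - depends on codecs present
            raise OSError(f"could not decode video {path}: {exc}") from exc
        return
    if path.suffix.lower() in _IMAGE_SUFFIXES:
        yield iio.imread(path)[..., :3]
        return
    raise OSError(f"unrecognised input {path}: expected video, image or directory")


def run_detect(config: RunConfig) -> RunSummary:
    """Stream frames through the detection pipeline and zone actuation.

    Writes (as requested) a detection CSV, annotated frames with red
    detection boxes, raw frames, and a mock-relay transition log into
    ``config.out_dir``. Per-frame failures are logged and skipped; the
    summary counts them. Mean FPS is measured wall-clock and is purely
    informational — it depends on the host CPU.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    profile = config.resolve_profile()
    pipe_cfg = PipelineConfig(algorithm=config.algorithm, profile=profile)
    zone_cfg = ZoneConfig(frame_width=pipe_cfg.resize_to[0])

    all_detections: list[Detection] = []
    pending = []
    summary = RunSummary()
    t0 = time.perf_counter()
    for idx, frame in enumerate(_iter_frames(config)):
        try:
            detections = process_frame(frame, pipe_cfg, frame_index=idx)
        except Exception:
            log.exception("frame %d failed; skipping", idx)
            summary.skipped_frames += 1
            continue
        detections = [
            Detection(d.bbox, d.centroid, d.area, d.frame_index,
                      zone=assign_zone(d.centroid[0], zone_cfg))
            for d in detections
        ]
        now = idx * config.frame_interval_ms
        pending = schedule_activations(detections, now, zone_cfg, pending)
        all_detections.extend(detections)
        summary.frames += 1
        log.debug("frame %d: %d detections", idx, len(detections))
        if config.save_video:
            iio.imwrite(out_dir / f"annotated_{idx:05d}.png",
                        annotate_frame(frame, detections))
        if config.save_frames:
            iio.imwrite(out_dir / f"frame_{idx:05d}.png", frame)
    elapsed = time.perf_counter() - t0
    summary.detections = len(all_detections)
    summary.mean_fps = summary.frames / elapsed if elapsed > 0 else 0.0

    if config.write_csv:
        csv_path = out_dir / "detections.csv"
        detections_to_csv(all_detections, csv_path)
        summary.outputs.append(str(csv_path))
    if config.write_actuation_log:
        backend = MockRelayBackend()
        drive_backend(pending, backend)
        log_path = out_dir / "actuation_log.csv"
        backend.write_csv(log_path)
        summary.outputs.append(str(log_path))
    if config.save_video:
        summary.outputs.extend(
            str(p) for p in sorted(out_dir.glob("annotated_*.png"))
        )
    log.info("processed %d frames, %d detections, %.1f FPS",
             summary.frames, summary.detections, summary.mean_fps)
    return summary


def run_evaluate(
    detections_csv: str | Path,
    truth_file: str | Path,
    tolerance: float = 50.0,
) -> EvalResult:
    """Score a detection CSV against a ground-truth file.

    Detections seen in several frames are deduplicated through the matching
    itself: each ground-truth weed counts at most one true positive for the
    whole run.
    """
    df = pd.read_csv(detections_csv)
    missing = {"cx", "cy"} - set(df.columns)
    if missing:
        raise ValueError(
            f"detections file {detections_csv} is missing column(s) {sorted(missing)}"
        )
    detections = [
        Detection(
            bbox=(int(r.get("x", 0)), int(r.get("y", 0)),
                  int(r.get("w", 1)), int(r.get("h", 1))),
            centroid=(float(r["cx"]), float(r["cy"])),
            area=int(r.get("area", 0)),
            frame_index=int(r.get("frame_index", 0)),
        )
        for r in df.to_dict("records")
    ]
    truth = load_ground_truth(truth_file)
    tp, fp = match_detections(detections, truth, tolerance)
    return precision_recall(tp, fp, truth.total_weeds)


def run_benchmark(
    algorithms: list[str] | None = None,
    frames: int = 20,
    input: str = "synthetic:day_green",
    seed: int = 0,
) -> pd.DataFrame:
    """Feed one identical frame stream to each algorithm and time it.

    Returns a table with mean frames-per-second per algorithm. Absolute
    values and even the ordering depend on the host CPU and are reported
    for information only.
    """
    if frames < 1:
        raise ValueError("frames must be >= 1")
    algorithms = list(algorithms or ALGORITHMS)
    cfg = RunConfig(input=input, algorithm="exg", n_frames=frames, seed=seed,
                    write_csv=False, write_actuation_log=False)
    stream = list(_iter_frames(cfg))
    rows = []
    for alg in algorithms:
        preset = "day" if alg not in ("hsv", "exhsv") else "day"
        pipe_cfg = PipelineConfig(algorithm=alg, profile=get_profile(preset, alg))
        t0 = time.perf_counter()
        n_det = sum(len(process_frame(f, pipe_cfg, i)) for i, f in enumerate(stream))
        dt = time.perf_counter() - t0
        rows.append({"algorithm": alg, "frames": len(stream),
                     "detections": n_det, "mean_fps": len(stream) / dt if dt else 0.0})
    table = pd.DataFrame(rows)
    log.info("benchmark FPS ordering: %s",
             ", ".join(table.sort_values("mean_fps", ascending=False)["algorithm"]))
    return table
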