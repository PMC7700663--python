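"""File-format glue: PNG frame directories, feature CSVs, ground-truth JSON.

Videos are exchanged as directories of numbered PNG frames (``frame_000000.png``,
...) with the frame rate stored in a ``meta.json`` sidecar; trajectories as
CSV with header ``frame,x,y,valid,interpolated``; features as a one-row CSV.
All text output is comma-separated, UTF-8, LF.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .features import FeatureVector
from .synthetic import FrameSequence, GroundTruth
from .trajectory import FingerTrajectory

__all__ = [
    "write_frames",
    "read_frames",
    "write_ground_truth",
    "features_to_csv",
    "features_from_csv",
]


def write_frames(seq: FrameSequence, directory) -> Path:
    """Write a frame sequence as numbered PNGs plus a meta.json sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(seq.frames):
        iio.imwrite(directory / f"frame_{i:06d}.png", frame)
    (directory / "meta.json").write_text(
        json.dumps({"fps": seq.fps, "n_frames": len(seq)}) + "\n", encoding="utf-8"
    )
    return directory


def read_frames(directory, fps: float | None = None) -> FrameSequence:
    """Read a PNG frame directory written by :func:`write_frames`."""
    directory = Path(directory)
    paths = sorted(directory.glob("frame_*.png"))
    if not paths:
        raise FileNotFoundError(f"no frame_*.png files in {directory}")
    frames = np.stack([iio.imread(p) for p in paths])
    if fps is None:
        meta = directory / "meta.json"
        fps = (
            json.loads(meta.read_text(encoding="utf-8")).get("fps", 30.0)
            if meta.exists()
            else 30.0
        )
    return FrameSequence(frames=frames, fps=float(fps))


def write_ground_truth(truth: GroundTruth, directory) -> Path:
    """Trajectory CSV plus a labels/epochs sidecar JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth.trajectory.to_csv(directory / "trajectory.csv")
    sidecar = {
        "class_label": truth.class_label,
        "severity_label": truth.severity_label,
        "touch_epochs": [list(e) for e in truth.touch_epochs],
        "initial_path_frames": [list(e) for e in truth.initial_path_frames],
        "return_path_frames": [list(e) for e in truth.return_path_frames],
        "fps": truth.trajectory.fps,
    }
    (directory / "ground_truth.json").write_text(
        json.dumps(sidecar, indent=2) + "\n", encoding="utf-8"
    )
    return directory


def features_to_csv(fv: FeatureVector, path) -> None:
    """One-row CSV: the six features plus run metadata."""
    pd.DataFrame(
        [
            {
                "rmsd": fv.rmsd,
                "accel_variance": fv.accel_variance,
                "histogram_feature": fv.histogram_feature,
                "vertical_swing_count": fv.vertical_swing_count,
                "vertical_swing_fraction": fv.vertical_swing_fraction,
                "time_ratio": fv.time_ratio,
                "avg_travel_distance": fv.avg_travel_distance,
                "movement_threshold": fv.movement_threshold,
                "n_frames": fv.n_frames,
                "fps": fv.fps,
            }
        ]
    ).to_csv(path, index=False, lineterminator="\n")


def features_from_csv(path) -> FeatureVector:
    row = pd.read_csv(path).iloc[0]
    return FeatureVector(
        rmsd=float(row["rmsd"]),
        accel_variance=float(row["accel_variance"]),
        histogram_feature=float(row["histogram_feature"]),
        vertical_swing_count=int(row["vertical_swing_count"]),
        vertical_swing_fraction=float(row["vertical_swing_fraction"]),
        time_ratio=float(row["time_ratio"]),
        avg_travel_distance=float(row["avg_travel_distance"]),
        movement_threshold=float(row.get("movement_threshold", np.nan)),
        n_frames=int(row.get("n_frames", 0)),
        fps=float(row.get("fps", 30.0)),
    )
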