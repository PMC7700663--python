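"""Fingertip trajectory container and CSV serialization.

The trajectory is the pipeline's central intermediate: one record per video
frame with sub-pixel fingertip coordinates in image convention (origin
top-left, x to the right, y downward, 0-based). ``valid`` marks frames where
a marker region was actually found; ``interpolated`` marks frames whose
coordinates were filled in from neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["FingerTrajectory", "TrajectoryError"]


class TrajectoryError(ValueError):
    """Raised for structurally invalid trajectories."""


@dataclass(frozen=True)
class FingerTrajectory:
    """Per-frame fingertip coordinates for one FNF recording.

    Parameters
    ----------
    frame_index : int array, strictly increasing and gapless.
    x, y : float arrays, pixel coordinates (sub-pixel precision).
    valid : bool array, True where a marker was located in that frame.
    interpolated : bool array, True where coordinates were interpolated.
    fps : frames per second of the source video.
    image_shape : (height, width) of the source frames, or None when the
        trajectory was loaded without its video.
    """

    frame_index: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    interpolated: np.ndarray = None  # type: ignore[assignment]
    fps: float = 30.0
    image_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        fi = np.asarray(self.frame_index, dtype=np.int64)
        x = np.asarray(self.x, dtype=np.float64)
        y = np.asarray(self.y, dtype=np.float64)
        valid = np.asarray(self.valid, dtype=bool)
        interp = (
            np.zeros_like(valid)
            if self.interpolated is None
            else np.asarray(self.interpolated, dtype=bool)
        )
        if not (len(fi) == len(x) == len(y) == len(valid) == len(interp)):
            raise TrajectoryError("column lengths differ")
        if len(fi) and np.any(np.diff(fi) != 1):
            raise TrajectoryError("frame_index must be gapless and increasing")
        if self.fps <= 0:
            raise TrajectoryError("fps must be positive")
        object.__setattr__(self, "frame_index", fi)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "valid", valid)
        object.__setattr__(self, "interpolated", interp)

    def __len__(self) -> int:
        return len(self.frame_index)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (x, y) coordinates."""
        return np.column_stack([self.x, self.y])

    def with_(self, **kw) -> "FingerTrajectory":
        return replace(self, **kw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frame_index,
                "x": self.x,
                "y": self.y,
                "valid": self.valid.astype(int),
                "interpolated": self.interpolated.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        """Write the fixed CSV dialect: comma, header, UTF-8, LF."""
        self.to_frame().to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path, fps: float = 30.0) -> "FingerTrajectory":
        df = pd.read_csv(path)
        required = {"frame", "x", "y"}
        missing = required - set(df.columns)
        if missing:
            raise TrajectoryError(f"trajectory CSV missing columns: {sorted(missing)}")
        valid = df["valid"] if "valid" in df else np.ones(len(df), dtype=bool)
        interp = df["interpolated"] if "interpolated" in df else None
        return cls(
            frame_index=df["frame"].to_numpy(),
            x=df["x"].to_numpy(),
            y=df["y"].to_numpy(),
            valid=np.asarray(valid, dtype=bool),
            interpolated=None if interp is None else np.asarray(interp, dtype=bool),
            fps=fps,
        )
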