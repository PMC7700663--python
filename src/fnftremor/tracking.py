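"""Colored-marker fingertip tracking.

Extracts the fingertip trajectory from an FNF video in which the subject's
finger is wrapped in red or green tape. Per frame: convert RGB to HSV,
threshold hue/saturation/value, intersect with the region of interest and a
background-difference mask, label connected components, drop components
whose bounding box is too elongated to be a finger, then pick the component
nearest the previously tracked position. Frames where no component survives
are filled in afterwards by linear interpolation across short gaps.

Coordinates follow the image convention: origin top-left, x to the right,
y downward, 0-based. Hue is expressed in degrees on [0, 360); red needs two
hue intervals because it wraps around 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage import color as _skcolor
from skimage import measure as _skmeasure

from .trajectory import FingerTrajectory

__all__ = [
    "TrackingConfig",
    "Region",
    "TrackingError",
    "TrackingResult",
    "build_background",
    "segment_marker",
    "label_regions",
    "filter_by_aspect_ratio",
    "select_region",
    "interpolate_gaps",
    "track",
]


class TrackingError(RuntimeError):
    """Raised when a recording cannot be tracked (no target, long gap...)."""


@dataclass(frozen=True)
class TrackingConfig:
    """Segmentation and tracking thresholds.

    hue_ranges : list of (low, high) hue intervals in degrees on [0, 360);
        a pixel matches if its hue falls in any interval.
    sat_range, val_range : inclusive bounds on saturation and value in
        [0, 1]; defaults pass nearly everything so hue does the work.
    roi : (x0, y0, x1, y1) half-open rectangle, or None for the full frame.
    aspect_ratio_bounds : allowed bounding-box width/height ratio; the
        finger patch is roughly square, elongated blobs are noise.
    background_tolerance : minimum mean absolute RGB distance from the
        background image for a pixel to count as foreground; None disables
        background differencing.
    max_gap_frames : longest run of marker-less frames that interpolation
        may bridge; longer gaps abort the recording.
    """

    hue_ranges: tuple[tuple[float, float], ...] = ((0.0, 25.0), (335.0, 360.0))
    sat_range: tuple[float, float] = (0.25, 1.0)
    val_range: tuple[float, float] = (0.1, 1.0)
    roi: tuple[int, int, int, int] | None = None
    aspect_ratio_bounds: tuple[float, float] = (0.4, 2.5)
    min_area_px: int = 20
    background_mode: str = "first_frames_median"
    n_background_frames: int = 30
    background_tolerance: float | None = 25.0
    max_gap_frames: int = 5

    def __post_init__(self) -> None:
        for lo, hi in self.hue_ranges:
            if not (0 <= lo < hi <= 360):
                raise ValueError(f"bad hue interval ({lo}, {hi})")
        lo, hi = self.aspect_ratio_bounds
        if not lo < hi:
            raise ValueError("aspect_ratio_bounds must be (min, max) with min < max")
        if self.background_mode not in ("first_frames_median", "provided_image"):
            raise ValueError(f"unknown background_mode {self.background_mode!r}")

    @classmethod
    def for_marker(cls, marker_color: str, **overrides) -> "TrackingConfig":
        """Defaults matched to the synthetic renderer's tape colors."""
        if marker_color == "red":
            hue = ((0.0, 25.0), (335.0, 360.0))
        elif marker_color == "green":
            hue = ((90.0, 150.0),)
        else:
            raise ValueError("marker_color must be 'red' or 'green'")
        return cls(hue_ranges=hue, **overrides)

    def with_(self, **kw) -> "TrackingConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class Region:
    """A connected component of the marker mask."""

    centroid: tuple[float, float]  # (x, y)
    area: int
    bbox: tuple[int, int, int, int]  # (x0, y0, x1, y1), half-open

    @property
    def aspect_ratio(self) -> float:
        x0, y0, x1, y1 = self.bbox
        return (x1 - x0) / (y1 - y0)


def build_background(frames, config: TrackingConfig, background_image=None):
    """Estimate the static scene without the marker.

    In ``provided_image`` mode the given image is returned unchanged. In
    ``first_frames_median`` mode the per-pixel median over the first
    ``n_background_frames`` frames is used: the marker is small and moving,
    so the median at each pixel is the scene behind it.
    """
    if config.background_mode == "provided_image":
        if background_image is None:
            raise ValueError("provided_image mode requires background_image")
        return np.asarray(background_image, dtype=np.float64)
    arr = np.asarray(getattr(frames, "frames", frames), dtype=np.float64)
    if arr.ndim != 4 or len(arr) == 0:
        raise ValueError("need a non-empty (n, H, W, 3) frame stack")
    n = min(len(arr), config.n_background_frames)
    return np.median(arr[:n], axis=0)


def _hsv_mask(frame: np.ndarray, config: TrackingConfig) -> np.ndarray:
    hsv = _skcolor.rgb2hsv(frame.astype(np.float64) / 255.0)
    hue = hsv[..., 0] * 360.0
    sat, val = hsv[..., 1], hsv[..., 2]
    m = np.zeros(hue.shape, dtype=bool)
    for lo, hi in config.hue_ranges:
        m |= (hue >= lo) & (hue <= hi)
    m &= (sat >= config.sat_range[0]) & (sat <= config.sat_range[1])
    m &= (val >= config.val_range[0]) & (val <= config.val_range[1])
    return m


def segment_marker(frame, background, config: TrackingConfig) -> np.ndarray:
    """Binary marker mask: HSV in-range AND in ROI AND off-background."""
    frame = np.asarray(frame)
    background = np.asarray(background)
    if frame.shape != background.shape:
        raise ValueError(
            f"frame shape {frame.shape} != background shape {background.shape}"
        )
    mask = _hsv_mask(frame, config)
    if config.background_tolerance is not None:
        diff = np.abs(frame.astype(np.float64) - background.astype(np.float64))
        mask &= diff.mean(axis=-1) > config.background_tolerance
    if config.roi is not None:
        x0, y0, x1, y1 = config.roi
        roi_mask = np.zeros(mask.shape, dtype=bool)
        roi_mask[y0:y1, x0:x1] = True
        mask &= roi_mask
    return mask


def label_regions(mask: np.ndarray, min_area_px: int = 1) -> list[Region]:
    """8-connected components with area >= min_area_px.

    Centroids are the unweighted mean of member-pixel coordinates.
    """
    labeled = _skmeasure.label(np.asarray(mask, dtype=bool), connectivity=2)
    regions = []
    for rp in _skmeasure.regionprops(labeled):
        if rp.area < min_area_px:
            continue
        cy, cx = rp.centroid  # (row, col) -> (y, x)
        r0, c0, r1, c1 = rp.bbox
        regions.append(
            Region(centroid=(cx, cy), area=int(rp.area), bbox=(c0, r0, c1, r1))
        )
    return regions


def filter_by_aspect_ratio(
    regions: list[Region], bounds: tuple[float, float]
) -> list[Region]:
    """Keep regions whose bbox width/height ratio is plausibly a fingertip."""
    lo, hi = bounds
    return [r for r in regions if lo <= r.aspect_ratio <= hi]


def select_region(
    regions: list[Region], previous_coord: tuple[float, float] | None = None
) -> Region | None:
    """Pick the fingertip among candidate regions.

    With a previous position: nearest centroid (ties broken by larger area,
    then smaller x). On the first frame: largest area.
    """
    if not regions:
        return None
    if previous_coord is None:
        return max(regions, key=lambda r: (r.area, -r.centroid[0]))
    px, py = previous_coord

    def key(r: Region):
        d = (r.centroid[0] - px) ** 2 + (r.centroid[1] - py) ** 2
        return (d, -r.area, r.centroid[0])

    return min(regions, key=key)


def interpolate_gaps(
    traj: FingerTrajectory, max_gap_frames: int = 5
) -> FingerTrajectory:
    """Fill short marker-less gaps by even division of the coordinate step.

    Internal runs of invalid frames up to ``max_gap_frames`` long get
    linearly interpolated x and y between the flanking valid frames and are
    flagged ``interpolated``. Leading/trailing invalid frames are trimmed,
    never extrapolated. A longer gap is a tracking failure.
    """
    valid = traj.valid
    if not valid.any():
        raise TrackingError("no valid frames to interpolate from")
    first, last = np.flatnonzero(valid)[[0, -1]]
    fi = traj.frame_index[first : last + 1]
    x = traj.x[first : last + 1].copy()
    y = traj.y[first : last + 1].copy()
    v = valid[first : last + 1]
    interp = traj.interpolated[first : last + 1].copy()

    gaps = _invalid_runs(v)
    for lo, hi in gaps:
        if hi - lo + 1 > max_gap_frames:
            raise TrackingError(
                f"gap of {hi - lo + 1} frames exceeds max_gap_frames={max_gap_frames}"
            )
    idx = np.arange(len(v))
    x[~v] = np.interp(idx[~v], idx[v], x[v])
    y[~v] = np.interp(idx[~v], idx[v], y[v])
    interp[~v] = True
    return FingerTrajectory(
        frame_index=fi,
        x=x,
        y=y,
        valid=np.ones(len(v), dtype=bool),
        interpolated=interp,
        fps=traj.fps,
        image_shape=traj.image_shape,
    )


def _invalid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    in_run = False
    start = 0
    for i, ok in enumerate(valid):
        if not ok and not in_run:
            in_run, start = True, i
        elif ok and in_run:
            runs.append((start, i - 1))
            in_run = False
    if in_run:
        runs.append((start, len(valid) - 1))
    return runs


@dataclass
class TrackingResult:
    """Trajectory plus the per-frame tracking log."""

    trajectory: FingerTrajectory
    log: list[dict] = field(default_factory=list)
    background: np.ndarray | None = None


def track(frames, config: TrackingConfig, background_image=None) -> TrackingResult:
    """Run the full per-frame extraction pipeline on a video.

    Per frame: segment, label, aspect-ratio filter, nearest-previous
    selection; then gap interpolation. Deterministic given frames + config.
    """
    stack = np.asarray(getattr(frames, "frames", frames))
    fps = getattr(frames, "fps", 30.0)
    if stack.ndim != 4 or len(stack) == 0:
        raise TrackingError("empty or malformed frame sequence")
    bg = build_background(frames, config, background_image)

    n = len(stack)
    xs = np.zeros(n)
    ys = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    log: list[dict] = []
    prev: tuple[float, float] | None = None
    for i in range(n):
        mask = segment_marker(stack[i], bg, config)
        regions = label_regions(mask, config.min_area_px)
        kept = filter_by_aspect_ratio(regions, config.aspect_ratio_bounds)
        chosen = select_region(kept, prev)
        rec = {"frame": i, "n_candidates": len(kept), "n_raw_regions": len(regions)}
        if chosen is not None:
            xs[i], ys[i] = chosen.centroid
            valid[i] = True
            prev = chosen.centroid
            rec["centroid"] = [float(xs[i]), float(ys[i])]
            rec["area"] = chosen.area
        else:
            rec["centroid"] = None
        log.append(rec)

    if not valid.any():
        raise TrackingError("no frame yielded a marker region")
    raw = FingerTrajectory(
        frame_index=np.arange(n),
        x=xs,
        y=ys,
        valid=valid,
        fps=fps,
        image_shape=tuple(stack.shape[1:3]),
    )
    traj = interpolate_gaps(raw, config.max_gap_frames)
    return TrackingResult(trajectory=traj, log=log, background=bg)
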