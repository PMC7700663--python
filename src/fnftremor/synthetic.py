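"""Synthetic finger-nose-finger (FNF) kinematics and video rendering.

The FNF test asks a subject to move their index finger back and forth
between their own nose and the examiner's finger. This module generates
ground-truth fingertip trajectories for three subject classes and renders
them into marker-tracking videos, so the tracking, feature, severity and
classification stages can all be exercised without clinical recordings.

Class-specific tremor structure
-------------------------------
healthy
    Smooth near-constant-speed transits (minimum-jerk ramps into a plateau)
    with dwells at both endpoints; no tremor.
et (essential tremor)
    A regular sinusoidal vertical oscillation (typically 4-12 Hz) riding on
    the transit, amplified while the finger rests at the examiner's finger
    (touch epochs), plus a deceleration of the approach toward the target.
cd (cerebellar disorder)
    Irregular, band-limited Gaussian jitter in both axes whose amplitude
    ramps up with proximity to the target (intention tremor), plus an
    asymmetry that stretches the initial path relative to the return path.

Amplitudes are specified in pixels; the default camera geometry maps
1 cm to about 10 px, so the clinical mild/severe anchors (ET: 1 cm,
CD: 2 cm) correspond to 10 px and 20 px respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .trajectory import FingerTrajectory

__all__ = [
    "KinematicsParams",
    "GroundTruth",
    "generate_trajectory",
    "render_video",
    "FrameSequence",
    "PX_PER_CM",
    "ET_SEVERE_CM",
    "CD_SEVERE_CM",
    "severity_cutoff_px",
]

# Pixel scale at the default ~1-1.5 m camera distance. Configurable per call.
PX_PER_CM = 10.0
# Clinical severity anchors: upper-limb tremor amplitude at/above which the
# recording is labeled severe (ET rating scale / ataxia rating scale anchors).
ET_SEVERE_CM = 1.0
CD_SEVERE_CM = 2.0

SUBJECT_CLASSES = ("healthy", "et", "cd")


def severity_cutoff_px(subject_class: str, px_per_cm: float = PX_PER_CM) -> float:
    """Pixel amplitude at/above which a tremor counts as severe."""
    if subject_class == "et":
        return ET_SEVERE_CM * px_per_cm
    if subject_class == "cd":
        return CD_SEVERE_CM * px_per_cm
    return np.inf


@dataclass(frozen=True)
class KinematicsParams:
    """Parameters of one synthetic FNF recording.

    Durations are in seconds, distances in pixels, frequencies in Hz.
    ``return_asymmetry`` is the ratio of initial-path to return-path
    duration (> 1 means the approach to the target is slower).
    """

    subject_class: str = "healthy"
    cycle_period_s: float = 2.0
    n_cycles: int = 3
    tremor_freq_hz: float = 6.0
    tremor_amp_px: float = 0.0
    irregularity: float = 0.0
    intention_gain: float = 0.0
    slowdown_gain: float = 0.0
    return_asymmetry: float = 1.0
    seed: int = 0
    fps: float = 30.0
    travel_px: float = 400.0
    start_xy: tuple[float, float] = (120.0, 240.0)
    dwell_fraction: float = 0.15
    touch_amplification: float = 2.0
    px_per_cm: float = PX_PER_CM

    def __post_init__(self) -> None:
        if self.subject_class not in SUBJECT_CLASSES:
            raise ValueError(f"unknown subject_class {self.subject_class!r}")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.cycle_period_s <= 0:
            raise ValueError("cycle_period_s must be positive")
        if not (0 < self.tremor_freq_hz < self.fps / 2):
            raise ValueError(
                "tremor_freq_hz must lie in (0, fps/2) to avoid aliasing"
            )
        if self.travel_px <= 0:
            raise ValueError("travel_px must be positive")
        if min(self.irregularity, self.intention_gain, self.slowdown_gain) < 0:
            raise ValueError("gain parameters must be non-negative")
        if self.return_asymmetry <= 0:
            raise ValueError("return_asymmetry must be positive")
        if not 0 < self.dwell_fraction < 0.5:
            raise ValueError("dwell_fraction must lie in (0, 0.5)")
        if self.subject_class == "healthy" and self.tremor_amp_px != 0:
            # Healthy subjects are tremor-free by definition.
            object.__setattr__(self, "tremor_amp_px", 0.0)

    @classmethod
    def for_class(cls, subject_class: str, seed: int = 0, **overrides) -> "KinematicsParams":
        """Realistic defaults per subject class (amplitudes in px)."""
        defaults: dict = {"subject_class": subject_class, "seed": seed}
        if subject_class == "et":
            defaults.update(
                tremor_freq_hz=6.0,
                tremor_amp_px=8.0,
                slowdown_gain=0.6,
                touch_amplification=2.0,
            )
        elif subject_class == "cd":
            defaults.update(
                tremor_amp_px=15.0,
                irregularity=1.0,
                intention_gain=1.5,
                return_asymmetry=1.5,
            )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class GroundTruth:
    """A generated trajectory together with everything a test can check."""

    trajectory: FingerTrajectory
    class_label: str
    severity_label: str  # "mild" | "severe" | "none"
    touch_epochs: list[tuple[int, int]]
    initial_path_frames: list[tuple[int, int]]
    return_path_frames: list[tuple[int, int]]
    params: KinematicsParams = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        epochs = sorted(self.touch_epochs)
        for (a0, a1), (b0, b1) in zip(epochs, epochs[1:]):
            if a1 >= b0:
                raise ValueError("touch epochs must be non-overlapping and ordered")
        if (self.severity_label == "none") != (self.class_label == "healthy"):
            raise ValueError("severity_label is 'none' iff class is healthy")


def _smoothstep(s: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on [0, 1]."""
    return s**3 * (10.0 - 15.0 * s + 6.0 * s**2)


TRANSIT_RAMP = 0.1  # fraction of each transit spent accelerating/decelerating


def _transit_profile(s: np.ndarray, ramp: float = TRANSIT_RAMP) -> np.ndarray:
    """Normalized transit position: smooth ramps, constant-speed plateau.

    Healthy FNF movement is smooth with near-constant speed, so the
    velocity shape is a smoothstep ramp up over the first ``ramp`` fraction
    of the transit, flat in the middle, and a mirrored ramp down. Position
    is the closed-form integral, normalized so P(0)=0, P(1)=1.
    """
    s = np.asarray(s, dtype=np.float64)
    r = ramp

    def _ramp_area(v):  # integral of the smoothstep velocity shape 3v^2-2v^3
        return v**3 - 0.5 * v**4

    total = 1.0 - r  # area under the unnormalized velocity shape
    p = np.empty_like(s)
    lo = s < r
    hi = s > 1.0 - r
    mid = ~(lo | hi)
    p[lo] = r * _ramp_area(s[lo] / r)
    p[mid] = 0.5 * r + (s[mid] - r)
    p[hi] = total - r * _ramp_area((1.0 - s[hi]) / r)
    return p / total


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fps: float, cutoff_hz: float
) -> np.ndarray:
    """Low-pass-filtered unit-variance Gaussian noise."""
    white = rng.standard_normal(n + 60)  # pad to absorb the filter transient
    wn = min(cutoff_hz / (fps / 2.0), 0.99)
    b, a = signal.butter(2, wn)
    low = signal.filtfilt(b, a, white)[60:]
    sd = low.std()
    return low / sd if sd > 0 else low


def generate_trajectory(params: KinematicsParams) -> GroundTruth:
    """Simulate one FNF recording as a ground-truth fingertip trajectory.

    Each round trip is: dwell at the nose, initial transit to the target,
    dwell at the target (a touch epoch), return transit to the nose. The
    initial transit lasts ``return_asymmetry`` times the return transit.
    Deterministic: identical params (including seed) give identical output.
    """
    rng = np.random.default_rng(params.seed)
    fps = params.fps
    frames_per_cycle = int(round(params.cycle_period_s * fps))
    if frames_per_cycle < 8:
        raise ValueError("cycle too short at this fps")
    dwell_n = max(1, int(round(params.dwell_fraction * frames_per_cycle)))
    transit_total = frames_per_cycle - 2 * dwell_n
    if transit_total < 4:
        raise ValueError("dwell_fraction leaves too few transit frames")
    a = params.return_asymmetry
    initial_n = max(2, int(round(transit_total * a / (1.0 + a))))
    return_n = max(2, transit_total - initial_n)

    x0, y0 = params.start_xy
    x1 = x0 + params.travel_px

    xs: list[np.ndarray] = []
    touch_epochs: list[tuple[int, int]] = []
    initial_ranges: list[tuple[int, int]] = []
    return_ranges: list[tuple[int, int]] = []
    pos = 0
    for _ in range(params.n_cycles):
        xs.append(np.full(dwell_n, x0))  # nose dwell
        pos += dwell_n
        s = np.arange(1, initial_n + 1) / initial_n
        if params.slowdown_gain > 0:
            # Decelerate the approach: progress slows as the target nears.
            s = 1.0 - (1.0 - s) ** (1.0 + params.slowdown_gain)
        xs.append(x0 + params.travel_px * _transit_profile(s))
        initial_ranges.append((pos, pos + initial_n - 1))
        pos += initial_n
        xs.append(np.full(dwell_n, x1))  # touch at the examiner's finger
        touch_epochs.append((pos, pos + dwell_n - 1))
        pos += dwell_n
        s = np.arange(1, return_n + 1) / return_n
        xs.append(x1 - params.travel_px * _transit_profile(s))
        return_ranges.append((pos, pos + return_n - 1))
        pos += return_n

    x = np.concatenate(xs)
    n = len(x)
    y = np.full(n, y0)
    t = np.arange(n) / fps

    in_touch = np.zeros(n, dtype=bool)
    for lo, hi in touch_epochs:
        in_touch[lo : hi + 1] = True
    # Proximity to the target in [0, 1], from the tremor-free base path.
    proximity = np.clip((x - x0) / params.travel_px, 0.0, 1.0)

    if params.subject_class == "et" and params.tremor_amp_px > 0:
        amp = params.tremor_amp_px * np.where(
            in_touch, params.touch_amplification, 1.0
        )
        y = y + amp * np.sin(2.0 * np.pi * params.tremor_freq_hz * t)
    elif params.subject_class == "cd" and params.tremor_amp_px > 0:
        # Irregular jitter: band-limited Gaussian displacement whose band
        # widens with `irregularity` and whose amplitude ramps toward the
        # target (intention tremor). RMS matched to a sine of the same
        # peak amplitude so ET/CD comparisons at equal tremor_amp_px are fair.
        cutoff = min(
            params.tremor_freq_hz * (1.0 + params.irregularity), 0.45 * fps
        )
        ramp = 1.0 + params.intention_gain * proximity
        base_rms = params.tremor_amp_px / np.sqrt(2.0)
        y = y + base_rms * ramp * _bandlimited_noise(rng, n, fps, cutoff)
        x = x + 0.35 * base_rms * ramp * _bandlimited_noise(rng, n, fps, cutoff)

    traj = FingerTrajectory(
        frame_index=np.arange(n),
        x=x,
        y=y,
        valid=np.ones(n, dtype=bool),
        fps=fps,
    )
    if params.subject_class == "healthy":
        severity = "none"
    else:
        cutoff_px = severity_cutoff_px(params.subject_class, params.px_per_cm)
        severity = "severe" if params.tremor_amp_px >= cutoff_px else "mild"
    return GroundTruth(
        trajectory=traj,
        class_label=params.subject_class,
        severity_label=severity,
        touch_epochs=touch_epochs,
        initial_path_frames=initial_ranges,
        return_path_frames=return_ranges,
        params=params,
    )


# ---------------------------------------------------------------------------
# Video rendering


MARKER_RGB = {
    "red": (205, 30, 35),
    "green": (35, 185, 45),
}
# Hues close enough to pass a naive marker hue threshold, used for the
# optional static distractor patch.
NEAR_MARKER_RGB = {
    "red": (205, 80, 35),
    "green": (95, 185, 45),
}


@dataclass(frozen=True)
class FrameSequence:
    """Ordered RGB frames (n, H, W, 3) uint8 with fps metadata."""

    frames: np.ndarray
    fps: float = 30.0

    def __post_init__(self) -> None:
        fr = np.asarray(self.frames)
        if fr.ndim != 4 or fr.shape[-1] != 3:
            raise ValueError("frames must have shape (n, H, W, 3)")
        object.__setattr__(self, "frames", fr.astype(np.uint8, copy=False))

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]


def _disk_mask(shape: tuple[int, int], cx: float, cy: float, radius: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.ogrid[:h, :w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


def render_video(
    truth: GroundTruth,
    image_shape: tuple[int, int] = (480, 640),
    marker_color: str = "red",
    background: str = "plain",
    noise_sd: float = 0.0,
    marker_radius: float = 6.0,
    distractor_xy: tuple[float, float] | None = None,
    distractor_half: int = 3,
    noise_seed: int | None = None,
) -> FrameSequence:
    """Render a ground-truth trajectory as a marker-tracking video.

    Each frame shows a filled disk of the marker color centered at the
    ground-truth fingertip coordinate, over a plain gray or textured
    background, with optional seeded Gaussian pixel noise (gray levels).
    ``distractor_xy`` places a static square patch of near-marker hue —
    a fixture for noise-filtering and region-selection tests.
    """
    if marker_color not in MARKER_RGB:
        raise ValueError(f"marker_color must be one of {sorted(MARKER_RGB)}")
    traj = truth.trajectory
    n = len(traj)
    if n == 0:
        raise ValueError("empty trajectory")
    h, w = image_shape
    margin = marker_radius
    if (
        traj.x.min() < margin
        or traj.x.max() > w - 1 - margin
        or traj.y.min() < margin
        or traj.y.max() > h - 1 - margin
    ):
        raise ValueError("trajectory (plus marker radius) exceeds image bounds")

    seed = truth.params.seed if noise_seed is None and truth.params else noise_seed
    rng = np.random.default_rng(0 if seed is None else seed)

    if background == "plain":
        bg = np.full((h, w, 3), 170, dtype=np.float64)
    elif background == "textured":
        # Static smooth low-contrast texture (seeded, same for all frames).
        tex_rng = np.random.default_rng(12345)
        coarse = tex_rng.uniform(130, 200, size=(h // 16 + 2, w // 16 + 2))
        from scipy.ndimage import zoom

        tex = zoom(coarse, 16, order=1)[:h, :w]
        bg = np.repeat(tex[:, :, None], 3, axis=2)
    else:
        raise ValueError("background must be 'plain' or 'textured'")

    if distractor_xy is not None:
        dx, dy = (int(round(v)) for v in distractor_xy)
        color = NEAR_MARKER_RGB[marker_color]
        bg[
            max(dy - distractor_half, 0) : dy + distractor_half + 1,
            max(dx - distractor_half, 0) : dx + distractor_half + 1,
        ] = color

    frames = np.empty((n, h, w, 3), dtype=np.uint8)
    color = np.array(MARKER_RGB[marker_color], dtype=np.float64)
    for i in range(n):
        frame = bg.copy()
        if marker_radius > 0:
            mask = _disk_mask((h, w), traj.x[i], traj.y[i], marker_radius)
            frame[mask] = color
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
        frames[i] = np.clip(frame, 0, 255).astype(np.uint8)
    return FrameSequence(frames=frames, fps=traj.fps)


def render_background(
    image_shape: tuple[int, int] = (480, 640),
    background: str = "plain",
    marker_color: str = "red",
    distractor_xy: tuple[float, float] | None = None,
    distractor_half: int = 3,
) -> np.ndarray:
    """The static scene of :func:`render_video` without the marker or noise."""
    dummy = generate_trajectory(
        KinematicsParams(
            n_cycles=1,
            start_xy=(image_shape[1] // 4, image_shape[0] // 2),
            travel_px=image_shape[1] // 4,
        )
    )
    seq = render_video(
        dummy,
        image_shape=image_shape,
        marker_color=marker_color,
        background=background,
        noise_sd=0.0,
        marker_radius=0.0,
        distractor_xy=distractor_xy,
        distractor_half=distractor_half,
    )
    return seq.frames[0]


# ---------------------------------------------------------------------------
# Cohort builders: seeded collections of recordings for the three classes


def sample_params(
    subject_class: str, rng: np.random.Generator, **overrides
) -> KinematicsParams:
    """Draw one subject's kinematic parameters with realistic variation.

    Ranges mirror the clinical picture: ET tremor at 4.5-8 Hz with 5-15 px
    (0.5-1.5 cm) amplitude and a slowed approach; CD with larger irregular
    tremor, intention ramp and a stretched initial path; healthy subjects
    smooth and tremor-free with only pace variation.
    """
    seed = int(rng.integers(0, 2**31 - 1))
    base: dict = {
        "subject_class": subject_class,
        "seed": seed,
        "cycle_period_s": float(rng.uniform(1.7, 2.6)),
        "n_cycles": 3,
    }
    if subject_class == "et":
        base.update(
            tremor_freq_hz=float(rng.uniform(4.5, 8.0)),
            tremor_amp_px=float(rng.uniform(5.0, 15.0)),
            slowdown_gain=float(rng.uniform(0.4, 0.8)),
            touch_amplification=2.0,
            return_asymmetry=float(rng.uniform(0.95, 1.15)),
        )
    elif subject_class == "cd":
        base.update(
            tremor_amp_px=float(rng.uniform(10.0, 25.0)),
            irregularity=float(rng.uniform(0.8, 1.5)),
            intention_gain=float(rng.uniform(1.0, 2.0)),
            return_asymmetry=float(rng.uniform(1.3, 1.7)),
        )
    else:
        base.update(return_asymmetry=float(rng.uniform(0.9, 1.1)))
    base.update(overrides)
    return KinematicsParams(**base)


def make_labeled_dataset(
    n_per_class: int = 30,
    seed: int = 0,
    classes: tuple[str, ...] = SUBJECT_CLASSES,
    return_truths: bool = False,
):
    """Generate a seeded feature dataset for classification experiments.

    Returns a :class:`~fnftremor.classify.LabeledDataset` (six features per
    recording, class labels "healthy"/"et"/"cd"); with ``return_truths``
    also the underlying :class:`GroundTruth` objects.
    """
    from .classify import LabeledDataset
    from .features import FEATURE_NAMES, extract_features

    rng = np.random.default_rng(seed)
    rows, labels, truths = [], [], []
    for cls_name in classes:
        for _ in range(n_per_class):
            truth = generate_trajectory(sample_params(cls_name, rng))
            fv = extract_features(truth.trajectory)
            rows.append(fv.to_array())
            labels.append(cls_name)
            truths.append(truth)
    dataset = LabeledDataset(
        X=np.array(rows),
        labels=np.array(labels),
        feature_names=tuple(FEATURE_NAMES),
    )
    return (dataset, truths) if return_truths else dataset


def make_severity_cohort(
    rule: str,
    n_per_group: int = 10,
    seed: int = 0,
    mild_amp_px: float | None = None,
    severe_amp_px: float | None = None,
):
    """Seeded mild/severe recordings of one disease class.

    Default amplitudes straddle the clinical severity anchor for the class
    (ET: 1 cm; CD: 2 cm at the default 10 px/cm scale). Returns
    (feature_vectors, severity_labels, ground_truths).
    """
    from .features import extract_features

    if rule not in ("et", "cd"):
        raise ValueError("rule must be 'et' or 'cd'")
    cutoff = severity_cutoff_px(rule)
    mild_amp = 0.5 * cutoff if mild_amp_px is None else mild_amp_px
    severe_amp = 1.5 * cutoff if severe_amp_px is None else severe_amp_px
    rng = np.random.default_rng(seed)
    fvs, labels, truths = [], [], []
    for amp in (mild_amp, severe_amp):
        for _ in range(n_per_group):
            truth = generate_trajectory(
                sample_params(rule, rng, tremor_amp_px=float(amp))
            )
            fvs.append(extract_features(truth.trajectory))
            labels.append(truth.severity_label)
            truths.append(truth)
    return fvs, labels, truths
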