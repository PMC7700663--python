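"""Shared render-and-track evaluation fixture.

Builds a synthetic recording, frames it into a canvas large enough for the
whole (possibly wildly jittering) marker path, optionally adds a static
near-hue distractor in an extended margin strip — guaranteed clear of the
path by more than any plausible single-frame tremor jump, since
marker-distractor overlap would be occlusion, which tracking does not
model — then tracks the rendered video and returns the RMS error against
ground truth.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from fnftremor.synthetic import (
    KinematicsParams,
    generate_trajectory,
    render_video,
)
from fnftremor.tracking import TrackingConfig, track

MARGIN = 12.0  # px between path (incl. marker) and any canvas edge
DISTRACTOR_STRIP = 140  # extra canvas width hosting the distractor


def framed_recording(seed: int, subject_class: str):
    """A seeded 1-cycle recording translated into a fitting canvas."""
    params = KinematicsParams.for_class(
        subject_class, seed=seed, n_cycles=1, travel_px=140.0, start_xy=(40.0, 80.0)
    )
    truth = generate_trajectory(params)
    t = truth.trajectory
    shifted = t.with_(x=t.x + (MARGIN - t.x.min()), y=t.y + (MARGIN - t.y.min()))
    truth = dataclasses.replace(truth, trajectory=shifted)
    h = max(160, int(np.ceil(shifted.y.max() + MARGIN)))
    w = max(240, int(np.ceil(shifted.x.max() + MARGIN)))
    return truth, (h, w)


def render_and_track_error(
    seed: int, noise_sd: float = 0.0, distractor: bool = False
) -> float:
    truth, (h, w) = framed_recording(seed, ["healthy", "et", "cd"][seed % 3])
    distractor_xy = None
    if distractor:
        w += DISTRACTOR_STRIP
        distractor_xy = (w - DISTRACTOR_STRIP / 2, 30.0)
        coords = truth.trajectory.coords
        clearance = float(
            np.hypot(coords[:, 0] - distractor_xy[0], coords[:, 1] - distractor_xy[1]).min()
        )
        assert clearance > 75.0
    seq = render_video(
        truth,
        image_shape=(h, w),
        marker_color="red",
        marker_radius=5.0,
        noise_sd=noise_sd,
        background="textured" if distractor else "plain",
        distractor_xy=distractor_xy,
    )
    cfg = TrackingConfig.for_marker("red")
    if distractor:
        # keep the distractor a live candidate: selection must reject it
        cfg = cfg.with_(background_tolerance=None)
    traj = track(seq, cfg).trajectory
    gt = truth.trajectory
    sl = slice(int(traj.frame_index[0]), int(traj.frame_index[-1]) + 1)
    return float(
        np.sqrt(np.mean((traj.x - gt.x[sl]) ** 2 + (traj.y - gt.y[sl]) ** 2))
    )
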