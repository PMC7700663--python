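"""Generate a synthetic finger-nose-finger recording.

Builds a ground-truth fingertip trajectory for an essential-tremor subject
(6 Hz, 8 px amplitude ~ 0.8 cm), prints its structure, and writes the
trajectory CSV plus labels sidecar. The touch epochs are the frames where
the finger rests on the examiner's finger — where ET tremor is amplified.
"""

from pathlib import Path

import numpy as np

from fnftremor.io import write_ground_truth
from fnftremor.synthetic import KinematicsParams, generate_trajectory

params = KinematicsParams.for_class("et", seed=7)
truth = generate_trajectory(params)
traj = truth.trajectory

print(f"class={truth.class_label}  severity={truth.severity_label}")
print(f"frames={len(traj)}  fps={traj.fps}  duration={len(traj)/traj.fps:.1f} s")
print(f"x range: {traj.x.min():.1f}..{traj.x.max():.1f} px "
      f"(travel {params.travel_px:.0f} px)")
print(f"y peak-to-peak: {np.ptp(traj.y):.1f} px "
      f"(tremor amplitude {params.tremor_amp_px:.0f} px, "
      f"x{params.touch_amplification:.0f} during touches)")
print(f"touch epochs (frames): {truth.touch_epochs}")

out = Path("scratch/example_recording")
write_ground_truth(truth, out)
print(f"wrote {out}/trajectory.csv and {out}/ground_truth.json")
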