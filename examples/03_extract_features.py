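"""The six kinematic tremor features, per subject class.

Extracts the feature vector from one recording of each class and prints
them side by side. Expect: near-zero RMSD and low acceleration variance
for healthy; a high histogram feature (time piled near the target) and
large touch-epoch travel for ET; large RMSD, acceleration variance and
initial/return time ratio for CD.
"""

from fnftremor.features import FEATURE_NAMES, extract_features
from fnftremor.synthetic import KinematicsParams, generate_trajectory

rows = {}
for cls in ("healthy", "et", "cd"):
    truth = generate_trajectory(KinematicsParams.for_class(cls, seed=5))
    rows[cls] = extract_features(truth.trajectory)

print(f"{'feature':<24}" + "".join(f"{c:>12}" for c in rows))
for name in FEATURE_NAMES:
    vals = "".join(f"{rows[c].get(name):>12.3f}" for c in rows)
    print(f"{name:<24}{vals}")
print(f"\nmovement threshold (px/frame): "
      + ", ".join(f"{c}={rows[c].movement_threshold:.2f}" for c in rows))
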