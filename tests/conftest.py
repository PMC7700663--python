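from __future__ import annotations

import numpy as np
import pytest

from fnftremor.synthetic import (
    KinematicsParams,
    generate_trajectory,
    render_video,
)


@pytest.fixture(scope="session")
def small_render_params():
    """Compact recording that fits a 240x320 frame: 2 cycles, 200 px travel."""
    def _make(subject_class="et", seed=0, **overrides):
        base = dict(n_cycles=2, travel_px=200.0, start_xy=(60.0, 120.0))
        base.update(overrides)
        return KinematicsParams.for_class(subject_class, seed=seed, **base)

    return _make


@pytest.fixture(scope="session")
def et_truth(small_render_params):
    return generate_trajectory(small_render_params("et", seed=3))


@pytest.fixture(scope="session")
def et_video(et_truth):
    return render_video(et_truth, image_shape=(240, 320), marker_color="red")


def random_fnf_params(rng: np.random.Generator) -> KinematicsParams:
    """A random but structurally valid FNF recording (any class)."""
    cls = rng.choice(["healthy", "et", "cd"])
    kw = dict(
        subject_class=cls,
        seed=int(rng.integers(0, 2**31 - 1)),
        cycle_period_s=float(rng.uniform(1.7, 2.8)),
        n_cycles=int(rng.integers(2, 4)),
    )
    if cls == "et":
        kw.update(
            tremor_freq_hz=float(rng.uniform(4.0, 9.0)),
            tremor_amp_px=float(rng.uniform(3.0, 18.0)),
            slowdown_gain=float(rng.uniform(0.0, 0.9)),
        )
    elif cls == "cd":
        kw.update(
            tremor_amp_px=float(rng.uniform(6.0, 28.0)),
            irregularity=float(rng.uniform(0.5, 1.6)),
            intention_gain=float(rng.uniform(0.5, 2.2)),
            return_asymmetry=float(rng.uniform(1.0, 1.8)),
        )
    return KinematicsParams(**kw)
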