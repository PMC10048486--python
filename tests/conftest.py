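"""Shared fixtures.

The expensive fixtures are session-scoped renders at the full imaging
regime (256x256 px, 500 frames at 50 Hz) reused by the DDM, DVA and
acceptance tests; everything else is generated small and on the fly.
"""

from __future__ import annotations

import pytest

from gelscope import ddm, synthetic
from gelscope.synthetic import MotionModel, OpticsModel, simulate_trajectories

# Lag list for probe-scale DDM: densely sampled early decay plus a
# long-lag block for the amplitude plateau.
DDM_LAG_FRAMES = [1, 2, 3, 4, 5, 6, 8, 10, 14, 20, 40, 55, 75, 100, 125]


@pytest.fixture(scope="session")
def brownian_movie():
    """Freely diffusing probes in a Newtonian medium: D = 0.4 um^2/s,
    500 particles, 500 frames at 50 Hz on 256x256 px at 0.1 um/px."""
    traj = simulate_trajectories(
        MotionModel.brownian(0.4), 500, 500, 0.02, (25.6, 25.6), seed=42
    )
    stack = synthetic.render_movie(traj, OpticsModel(), seed=7)
    return stack, traj


@pytest.fixture(scope="session")
def brownian_sf(brownian_movie):
    """Structure function of the Brownian movie with A(q), B populated."""
    stack, _ = brownian_movie
    sf = ddm.structure_function(stack, lags=[f * 0.02 for f in DDM_LAG_FRAMES])
    return ddm.estimate_noise_and_amplitude(sf)


@pytest.fixture(scope="session")
def gel_state_movie():
    """The subdiffusive gel-state preset: fBm with H = 1/6."""
    stage = synthetic.GelationSchedule.acid_milk_default().stages[4]
    assert stage.motion.kind == "fbm"
    traj = simulate_trajectories(stage.motion, 500, 500, 0.02, (25.6, 25.6), seed=11)
    stack = synthetic.render_movie(traj, OpticsModel(), seed=12)
    return stack, traj


@pytest.fixture(scope="session")
def viscosity_pair():
    """Two movies whose media differ by exactly 2x in viscosity
    (D = 0.8 and 0.4 um^2/s), for tau-proportionality checks."""
    out = {}
    for name, d, s in [("thin", 0.8, 21), ("thick", 0.4, 22)]:
        traj = simulate_trajectories(
            MotionModel.brownian(d), 300, 500, 0.02, (12.8, 12.8), seed=s
        )
        stack = synthetic.render_movie(
            traj, OpticsModel(image_shape=(128, 128)), seed=s + 100
        )
        out[name] = (stack, traj, d)
    return out
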