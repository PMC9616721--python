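import numpy as np
import pytest

from placepop import preset, synthetic
from placepop.ratemaps import Ratemap, compute_ratemap, split_session
from placepop.synthetic import GaussianField, SimCell


@pytest.fixture(scope="session")
def env_a():
    return preset("A")


@pytest.fixture(scope="session")
def env_d():
    return preset("D")


@pytest.fixture(scope="session")
def traj_a(env_a):
    """15-min foraging session in the smallest arena (protocol scaling)."""
    return synthetic.generate_trajectory(env_a, 900.0, seed=11)


@pytest.fixture(scope="session")
def short_traj(env_a):
    return synthetic.generate_trajectory(env_a, 240.0, seed=7)


@pytest.fixture(scope="session")
def two_bump_session(env_a, traj_a):
    """One cell with two well-separated fields, plus its map splits."""
    cell = SimCell(
        "bump2",
        2.0,
        [
            GaussianField((25.0, 30.0), 8.0, 8.0, 8.0),
            GaussianField((60.0, 95.0), 8.0, 8.0, 8.0),
        ],
        baseline_hz=0.05,
    )
    spikes = synthetic.generate_spikes([cell], traj_a, seed=13)[0]
    rm = compute_ratemap(traj_a, spikes, env_a)
    (ta, sa), (tb, sb) = split_session(traj_a, spikes)
    rm_odd = compute_ratemap(ta, sa, env_a)
    rm_even = compute_ratemap(tb, sb, env_a)
    return cell, spikes, rm, (rm_odd, rm_even)


def analytic_ratemap(env, rate_fn, bin_cm=4.0):
    """Ratemap stub with uniform dwell and an analytic rate surface."""
    nx = int(np.ceil(env.width_cm / bin_cm))
    ny = int(np.ceil(env.height_cm / bin_cm))
    xs = (np.arange(nx) + 0.5) * bin_cm
    ys = (np.arange(ny) + 0.5) * bin_cm
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    rate = rate_fn(gx, gy)
    return Ratemap(
        rate=rate,
        dwell_s=np.ones((nx, ny)),
        spike_count=rate.copy(),
        visited=np.ones((nx, ny), dtype=bool),
        bin_cm=bin_cm,
        env=env,
    )


@pytest.fixture(scope="session")
def make_analytic_ratemap():
    return analytic_ratemap
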