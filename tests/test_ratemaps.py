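"""Ratemap construction, spatial correlation, session splitting."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from scipy.stats import pearsonr

from placepop import synthetic
from placepop.environments import EnvironmentSpec
from placepop.ratemaps import (
    InsufficientDataError,
    compute_ratemap,
    spatial_correlation,
    split_session,
)
from placepop.trajectory import SpikeTrain, Trajectory


class TestComputeRatemap:
    def test_no_spikes_gives_zero_rate_on_visited_bins(self, env_a, short_traj):
        rm = compute_ratemap(short_traj, SpikeTrain("u", np.empty(0)), env_a)
        assert np.all(rm.rate[rm.visited] == 0.0)

    def test_stationary_animal_raises(self, env_a):
        n = 300
        traj = Trajectory(np.arange(n) / 30.0, np.full((n, 2), 40.0), 30.0)
        with pytest.raises(InsufficientDataError):
            compute_ratemap(traj, SpikeTrain("u", np.array([1.0])), env_a)

    def test_rate_equals_brute_force_kernel_ratio(self):
        """Peak rate equals (kernel-weighted counts)/(kernel-weighted dwell)
        computed by direct convolution on a toy grid."""
        env = EnvironmentSpec("toy", 36.0, 36.0)  # 9x9 grid of 4-cm bins
        rate_hz = 30.0
        # snake path visiting every bin uniformly, fast enough to pass the gate
        centers = [(4 * i + 2.0, 4 * j + 2.0) for j in range(9) for i in range(9)]
        reps = 4
        xy = np.array(centers * reps)
        n = len(xy)
        traj = Trajectory(np.arange(n) / rate_hz, xy, rate_hz)
        traj.speed_cm_s = np.full(n, 20.0)  # bypass derived speed for the toy
        # all spikes in the interior bin (4, 4) at its first visit
        t_spike = traj.timestamps[4 * 9 + 4]
        spikes = SpikeTrain("u", np.full(5, t_spike))
        rm = compute_ratemap(traj, spikes, env, sigma_bins=2.0)

        dwell = np.full((9, 9), reps / rate_hz)
        spike_grid = np.zeros((9, 9))
        spike_grid[4, 4] = 5.0
        sm_d = gaussian_filter(dwell, 2.0, mode="constant", truncate=4.0)
        sm_s = gaussian_filter(spike_grid, 2.0, mode="constant", truncate=4.0)
        assert rm.rate[4, 4] == pytest.approx(sm_s[4, 4] / sm_d[4, 4], rel=1e-12)

    def test_unsmoothed_dwell_sums_to_filtered_time(self, env_a, short_traj):
        rm = compute_ratemap(short_traj, SpikeTrain("u", np.empty(0)), env_a)
        t_filtered = (short_traj.speed > 10.0).sum() / short_traj.rate_hz
        assert rm.dwell_s.sum() == pytest.approx(t_filtered, abs=1.0 / short_traj.rate_hz)

    def test_smoothing_conserves_interior_mass(self, env_a, short_traj):
        # a tight field at the arena centre: kernel truncation at the
        # borders loses < 1% of the spike mass
        from placepop.synthetic import GaussianField, SimCell

        cell = SimCell(
            "mid", 1.0, [GaussianField((44.0, 62.0), 6.0, 6.0, 8.0)], baseline_hz=0.0
        )
        spikes = synthetic.generate_spikes([cell], short_traj, seed=8)[0]
        rm = compute_ratemap(short_traj, spikes, env_a)
        sm = gaussian_filter(rm.spike_count, rm.sigma_bins, mode="constant", truncate=4.0)
        assert sm.sum() == pytest.approx(rm.spike_count.sum(), rel=0.01)


class TestSpatialCorrelation:
    def test_self_correlation_is_one(self, two_bump_session):
        *_, rm, _ = two_bump_session
        assert spatial_correlation(rm, rm) == pytest.approx(1.0)

    def test_fewer_than_six_valid_bins_is_undefined(self):
        a = np.full((3, 3), np.nan)
        b = np.full((3, 3), np.nan)
        a[0, :] = [1.0, 2.0, 3.0]
        b[0, :] = [1.0, 2.0, 3.0]
        a[1, 0] = b[1, 0] = 0.5
        a[1, 1] = b[1, 1] = 1.5  # five valid bins
        assert np.isnan(spatial_correlation(a, b))

    def test_matches_manual_pearson_on_hand_grids(self):
        a = np.array([[1.0, 2.0, 0.5], [3.0, 1.0, 2.5], [0.2, 4.0, 1.1]])
        b = np.array([[0.9, 2.2, 0.4], [2.5, 1.5, 2.0], [0.5, 3.0, 1.4]])
        expected = pearsonr(a.ravel(), b.ravel())[0]
        assert spatial_correlation(a, b) == pytest.approx(expected, rel=1e-12)

    def test_rate_floor_excludes_jointly_silent_bins(self):
        a = np.zeros((3, 3))
        b = np.zeros((3, 3))
        a[0] = [1.0, 2.0, 3.0]
        b[0] = [2.0, 4.0, 6.0]
        a[1] = [0.5, 1.5, 2.5]
        b[1] = [1.0, 3.0, 5.0]
        # remaining row is 0/0 in both: excluded by the 0.01-Hz floor
        r = spatial_correlation(a, b)
        manual = pearsonr(
            np.concatenate([a[0], a[1]]), np.concatenate([b[0], b[1]])
        )[0]
        assert r == pytest.approx(manual, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spatial_correlation(np.ones((2, 2)), np.ones((3, 3)))


class TestSplitSession:
    def test_odd_even_partitions_ten_minutes_evenly(self, env_a):
        traj = synthetic.generate_trajectory(env_a, 600.0, seed=1)
        spikes = SpikeTrain("u", np.linspace(0, 599.9, 500))
        (ta, sa), (tb, sb) = split_session(traj, spikes, "odd_even_minutes")
        assert len(ta) == len(tb) == len(traj) // 2
        assert len(sa) + len(sb) == len(spikes)

    def test_first_last_half_splits_at_midpoint(self, env_a):
        traj = synthetic.generate_trajectory(env_a, 600.0, seed=2)
        spikes = SpikeTrain("u", np.array([100.0, 200.0, 400.0]))
        (ta, sa), (tb, sb) = split_session(traj, spikes, "first_last_half")
        assert ta.timestamps.max() < 300.0 <= tb.timestamps.min()
        assert len(sa) == 2 and len(sb) == 1

    def test_spike_at_61s_lands_in_odd_minute_subset(self, env_a):
        traj = synthetic.generate_trajectory(env_a, 180.0, seed=3)
        spikes = SpikeTrain("u", np.array([61.0]))
        (_, sa), (_, sb) = split_session(traj, spikes, "odd_even_minutes")
        assert len(sb) == 1 and len(sa) == 0  # floor(61/60) = 1, odd parity

    def test_subsets_disjoint_and_exhaustive(self, env_a):
        traj = synthetic.generate_trajectory(env_a, 240.0, seed=4)
        spikes = SpikeTrain("u", np.linspace(0.5, 239.5, 97))
        (ta, sa), (tb, sb) = split_session(traj, spikes)
        merged = np.sort(np.concatenate([ta.timestamps, tb.timestamps]))
        np.testing.assert_array_equal(merged, traj.timestamps)
        assert len(set(sa.times) & set(sb.times)) == 0

    def test_too_short_recording_rejected(self, env_a):
        traj = synthetic.generate_trajectory(env_a, 90.0, seed=5)
        with pytest.raises(ValueError):
            split_session(traj, SpikeTrain("u", np.empty(0)), "odd_even_minutes")
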