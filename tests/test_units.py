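"""Unit classification, duplicate detection and cluster quality."""

import numpy as np
import pytest
from scipy.stats import chi2

from placepop.ratemaps import compute_ratemap
from placepop.trajectory import SpikeTrain
from placepop.units import (
    UnitFeatures,
    classify_unit,
    classify_units,
    cluster_quality,
    cross_correlogram,
    detect_duplicates,
)


def place_features(**over):
    base = dict(
        unit_id="u",
        mean_rate_hz=1.2,
        peak_to_trough_ms=0.6,
        half_width_ms=0.2,
        trough_ratio=0.3,
        odd_even_corrs=[0.7],
        half_half_corrs=[0.5],
        field_counts=[2],
        max_spatial_corr=0.8,
        total_spikes=4000,
    )
    base.update(over)
    return UnitFeatures(**base)


class TestClassify:
    def test_typical_place_cell(self):
        assert classify_unit(place_features()) == "place_cell"

    def test_interneuron_by_all_four_criteria(self):
        u = place_features(
            mean_rate_hz=5.0,
            half_width_ms=0.12,
            trough_ratio=0.3,
            max_spatial_corr=0.6,
            odd_even_corrs=[0.1],
            half_half_corrs=[0.1],
            field_counts=[0],
        )
        assert classify_unit(u) == "interneuron"

    def test_no_field_anywhere_rejected(self):
        u = place_features(mean_rate_hz=3.9, field_counts=[0, 0])
        assert classify_unit(u) == "rejected"

    def test_boundary_values_rejected_for_place_criteria(self):
        # strict inequalities: sitting exactly on every threshold fails
        u = place_features(
            peak_to_trough_ms=0.45,
            half_width_ms=0.1,
            trough_ratio=0.175,
            odd_even_corrs=[0.5],
            half_half_corrs=[0.25],
            mean_rate_hz=4.0,
        )
        assert classify_unit(u) == "rejected"

    def test_interneuron_boundaries_inclusive(self):
        u = place_features(
            mean_rate_hz=4.0,
            half_width_ms=0.15,
            trough_ratio=0.4,
            max_spatial_corr=0.75,
            field_counts=[0],
            odd_even_corrs=[0.0],
            half_half_corrs=[0.0],
        )
        assert classify_unit(u) == "interneuron"

    def test_missing_feature_names_field(self):
        u = place_features(half_width_ms=float("nan"))
        with pytest.raises(ValueError, match="half_width_ms"):
            classify_unit(u)

    def test_permutation_invariant(self):
        units = [place_features(unit_id=f"u{i}", mean_rate_hz=r)
                 for i, r in enumerate([1.0, 5.0, 3.0])]
        fwd = classify_units(units)
        rev = classify_units(units[::-1])
        assert fwd == rev


class TestDuplicates:
    def _maps(self, env, traj, trains):
        return [{st.unit_id: compute_ratemap(traj, st, env) for st in trains}]

    def test_identical_trains_flagged_and_larger_removed(self, env_a, traj_a):
        rng = np.random.default_rng(0)
        base = np.sort(rng.uniform(0, 890, 3000))
        a = SpikeTrain("a", base)
        b = SpikeTrain("b", np.sort(np.concatenate([base, [891.0, 892.0]])))
        maps = self._maps(env_a, traj_a, [a, b])
        removed = detect_duplicates([a, b], maps)
        assert removed == ["b"]  # more total spikes -> removed

    def test_independent_poisson_trains_not_flagged(self, env_a, traj_a):
        rng = np.random.default_rng(1)
        # 1-Hz independent trains: expected zero-lag coincidences
        # r1 * r2 * dt * T = 1 * 1 * 0.002 * 900 < 2, far below 200
        a = SpikeTrain("a", np.sort(rng.uniform(0, 890, 900)))
        b = SpikeTrain("b", np.sort(rng.uniform(0, 890, 900)))
        maps = self._maps(env_a, traj_a, [a, b])
        assert detect_duplicates([a, b], maps) == []

    def test_zero_lag_bin_counts_coincidences(self):
        a = SpikeTrain("a", np.array([1.0, 2.0, 3.0]))
        b = SpikeTrain("b", np.array([1.0005, 2.0005, 3.02]))
        centers, counts = cross_correlogram(a, b)
        zero_bin = int(np.argmin(np.abs(centers)))
        assert counts[zero_bin] == 2


class TestClusterQuality:
    def test_well_separated_clusters(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, size=(200, 2))
        b = rng.normal(40, 1, size=(200, 2))
        X = np.vstack([a, b])
        labels = np.array([0] * 200 + [1] * 200)
        out = cluster_quality(X, labels)
        assert out[0][0] < 1e-6  # L-ratio near zero
        assert out[0][1] > 100.0  # isolation distance large

    def test_duplicated_cluster_has_small_isolation_distance(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 1, size=(400, 2))
        labels = np.array([0, 1] * 200)
        out = cluster_quality(pts, labels)
        assert out[0][1] < chi2.ppf(0.99, df=2) * 2

    def test_matches_hand_computed_mahalanobis(self):
        # cluster 0: 8 points on a known covariance; 2 noise points
        X = np.array(
            [
                [0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0],
                [0.5, 0.5], [0.2, 0.8], [0.8, 0.2], [0.5, 0.0],
                [5.0, 5.0], [6.0, 5.0],
            ]
        )
        member = X[:8]
        mu = member.mean(axis=0)
        inv = np.linalg.inv(np.cov(member, rowvar=False))
        d2 = [(x - mu) @ inv @ (x - mu) for x in X[8:]]
        l_ratio = sum(1 - chi2.cdf(d, df=2) for d in d2) / 8
        got = cluster_quality(X, np.array([0] * 8 + [1] * 2))
        assert got[0][0] == pytest.approx(l_ratio, rel=1e-9)
        # isolation distance: 8 members but only 2 non-members -> inf
        assert got[0][1] == np.inf

    def test_singular_covariance_reports_feature_pruning(self):
        X = np.zeros((20, 2))
        X[:, 0] = np.arange(20)
        X[:, 1] = 2 * X[:, 0]  # perfectly collinear features
        with pytest.raises(ValueError, match="prune"):
            cluster_quality(X, np.array([0] * 10 + [1] * 10))


class TestClassificationReport:
    def test_report_flags_match_labels(self):
        from placepop.units import classification_report

        units = [
            place_features(unit_id="p"),
            place_features(
                unit_id="i",
                mean_rate_hz=5.0,
                half_width_ms=0.12,
                trough_ratio=0.3,
                max_spatial_corr=0.6,
                odd_even_corrs=[0.1],
                half_half_corrs=[0.1],
                field_counts=[0],
            ),
        ]
        rep = classification_report(units).set_index("unit")
        assert rep.loc["p", "label"] == "place_cell"
        assert bool(rep.loc["p"].drop("label").all())
        assert rep.loc["i", "label"] == "interneuron"
        assert not rep.loc["i", "has_field"]
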