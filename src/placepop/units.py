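"""Unit classification and cluster-quality metrics.

Place cells, interneurons and duplicate units are identified from
precomputed waveform and stability features.  Place-cell criteria are
strict inequalities ("over" / "lower than"); interneuron criteria
("minimum" / "maximum") are inclusive.  Cluster quality follows the
standard Mahalanobis-distance definitions: the Schmitzer-Torbert L-ratio
and the Harris isolation distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import chi2

from .ratemaps import Ratemap, spatial_correlation
from .trajectory import SpikeTrain

__all__ = [
    "UnitFeatures",
    "classify_units",
    "detect_duplicates",
    "cross_correlogram",
    "cluster_quality",
]


@dataclass
class UnitFeatures:
    """Precomputed per-unit waveform and stability features."""

    unit_id: str
    mean_rate_hz: float
    peak_to_trough_ms: float
    half_width_ms: float
    trough_ratio: float
    odd_even_corrs: list[float] = field(default_factory=list)
    half_half_corrs: list[float] = field(default_factory=list)
    field_counts: list[int] = field(default_factory=list)
    max_spatial_corr: float = float("nan")
    total_spikes: int = 0


_REQUIRED = ("mean_rate_hz", "peak_to_trough_ms", "half_width_ms", "trough_ratio")


def _check(unit: UnitFeatures) -> None:
    for name in _REQUIRED:
        v = getattr(unit, name)
        if v is None or not np.isfinite(v):
            raise ValueError(f"unit {unit.unit_id}: missing feature {name!r}")


def classify_unit(unit: UnitFeatures) -> str:
    """Label one unit as place_cell, interneuron or rejected."""
    _check(unit)
    is_place = (
        unit.peak_to_trough_ms > 0.45
        and unit.half_width_ms > 0.1
        and unit.trough_ratio > 0.175
        and any(c > 0.5 for c in unit.odd_even_corrs if np.isfinite(c))
        and any(c > 0.25 for c in unit.half_half_corrs if np.isfinite(c))
        and any(k >= 1 for k in unit.field_counts)
        and unit.mean_rate_hz < 4.0
    )
    if is_place:
        return "place_cell"
    is_interneuron = (
        unit.mean_rate_hz >= 4.0
        and unit.half_width_ms <= 0.15
        and unit.trough_ratio <= 0.4
        and (
            not np.isfinite(unit.max_spatial_corr) or unit.max_spatial_corr <= 0.75
        )
    )
    return "interneuron" if is_interneuron else "rejected"


def classify_units(units: list[UnitFeatures]) -> dict[str, str]:
    """Pure per-unit filter; permutation-invariant and idempotent."""
    return {u.unit_id: classify_unit(u) for u in units}


def classification_report(units: list[UnitFeatures]):
    """Per-criterion pass/fail table alongside the final label."""
    import pandas as pd

    rows = []
    for u in units:
        _check(u)
        rows.append(
            {
                "unit": u.unit_id,
                "label": classify_unit(u),
                "peak_to_trough_over_0.45ms": u.peak_to_trough_ms > 0.45,
                "half_width_over_0.1ms": u.half_width_ms > 0.1,
                "trough_ratio_over_0.175": u.trough_ratio > 0.175,
                "odd_even_corr_over_0.5": any(
                    c > 0.5 for c in u.odd_even_corrs if np.isfinite(c)
                ),
                "half_half_corr_over_0.25": any(
                    c > 0.25 for c in u.half_half_corrs if np.isfinite(c)
                ),
                "has_field": any(k >= 1 for k in u.field_counts),
                "mean_rate_under_4Hz": u.mean_rate_hz < 4.0,
            }
        )
    return pd.DataFrame(rows)


def cross_correlogram(
    a: SpikeTrain,
    b: SpikeTrain,
    bin_s: float = 0.002,
    max_lag_s: float = 0.025,
) -> tuple[np.ndarray, np.ndarray]:
    """(lag bin centres s, counts) of spike-time differences b - a."""
    n_bins = int(round(2 * max_lag_s / bin_s))
    if n_bins % 2 == 0:
        n_bins += 1  # odd count centres one bin on zero lag
    edges = np.linspace(-max_lag_s, max_lag_s, n_bins + 1)
    counts = np.zeros(n_bins)
    tb = b.times
    for t in a.times:
        lo = np.searchsorted(tb, t - max_lag_s)
        hi = np.searchsorted(tb, t + max_lag_s)
        if hi > lo:
            counts += np.histogram(tb[lo:hi] - t, bins=edges)[0]
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts


def _fitted_sigma_ms(centers_s: np.ndarray, counts: np.ndarray) -> float:
    """Sigma (ms) of a least-squares Gaussian on the cross-correlogram.

    A constant offset absorbs the chance-coincidence floor so that the
    sigma reflects only the central peak's width.
    """

    def gauss(t, amp, mu, sigma, base):
        return base + amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)

    if counts.max() <= 0:
        return float("inf")
    t_ms = centers_s * 1e3
    try:
        popt, _ = curve_fit(
            gauss,
            t_ms,
            counts,
            p0=[counts.max(), 0.0, 2.0, float(np.median(counts))],
            bounds=([0, -25, 1e-3, 0], [np.inf, 25, 50, np.inf]),
            maxfev=2000,
        )
    except RuntimeError:
        return float("inf")
    return float(abs(popt[2]))


def detect_duplicates(
    trains: list[SpikeTrain],
    maps_by_recording: list[dict[str, Ratemap]],
    zero_lag_min: int = 200,
    sigma_max_ms: float = 0.5,
    map_corr_min: float = 0.5,
    min_spikes: int = 200,
) -> list[str]:
    """Unit ids removed as cross-tetrode duplicates.

    A pair is flagged when its +/-25 ms cross-correlogram (2-ms bins) has
    at least ``zero_lag_min`` spikes in the single zero-lag bin, the sigma
    of a fitted Gaussian is below ``sigma_max_ms``, and the mean ratemap
    correlation exceeds ``map_corr_min`` across recordings where both
    units fire at least ``min_spikes`` spikes.  Within a flagged pair the
    unit with more total spikes is removed.
    """
    removed: set[str] = set()
    order = sorted(range(len(trains)), key=lambda i: trains[i].unit_id)
    for ai in range(len(order)):
        for bi in range(ai + 1, len(order)):
            a, b = trains[order[ai]], trains[order[bi]]
            centers, counts = cross_correlogram(a, b)
            zero_bin = int(np.argmin(np.abs(centers)))
            if counts[zero_bin] < zero_lag_min:
                continue
            if _fitted_sigma_ms(centers, counts) >= sigma_max_ms:
                continue
            corrs = []
            for rec in maps_by_recording:
                if a.unit_id not in rec or b.unit_id not in rec:
                    continue
                ma, mb = rec[a.unit_id], rec[b.unit_id]
                if ma.spike_count.sum() < min_spikes or mb.spike_count.sum() < min_spikes:
                    continue
                r = spatial_correlation(ma, mb)
                if np.isfinite(r):
                    corrs.append(r)
            if not corrs or np.mean(corrs) <= map_corr_min:
                continue
            # more spikes -> assumed worse isolated -> removed
            loser = a if len(a) > len(b) else b if len(b) > len(a) else max(
                a, b, key=lambda t: t.unit_id
            )
            removed.add(loser.unit_id)
    return sorted(removed)


def cluster_quality(
    features: np.ndarray, labels: np.ndarray
) -> dict[object, tuple[float, float]]:
    """Per-cluster (L-ratio, isolation distance) in the supplied feature space.

    Both metrics use squared Mahalanobis distances of non-member spikes to
    the cluster.  L-ratio sums ``1 - chi2.cdf(D^2, df)`` over non-members,
    normalised by the cluster spike count; isolation distance is the
    ``n_c``-th smallest non-member ``D^2`` (infinite when fewer than n_c
    non-members exist).
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    n, f = X.shape
    out: dict[object, tuple[float, float]] = {}
    evaluable = [
        c for c in np.unique(labels) if (labels == c).sum() >= f + 1
    ]
    if not evaluable:
        raise ValueError("no cluster has at least n_features+1 spikes")
    for c in evaluable:
        member = labels == c
        n_c = int(member.sum())
        mu = X[member].mean(axis=0)
        cov = np.cov(X[member], rowvar=False)
        try:
            inv = np.linalg.inv(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"cluster {c!r}: singular covariance; prune correlated features"
            ) from exc
        diff = X[~member] - mu
        d2 = np.einsum("ij,jk,ik->i", diff, inv, diff)
        l_ratio = float(np.sum(1.0 - chi2.cdf(d2, df=f)) / n_c)
        d2_sorted = np.sort(d2)
        iso = float(d2_sorted[n_c - 1]) if len(d2_sorted) >= n_c else float("inf")
        out[c] = (l_ratio, iso)
    return out
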