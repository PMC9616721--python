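"""Iterative-threshold place-field detection and field geometry.

A place field is a contiguous region of a ratemap in which firing decays
continuously from a single prominent peak and is stable across repeated
visits.  Detection thresholds the map at 1 Hz, labels 4-connected
components (diagonal neighbours are not connected), then re-thresholds
each candidate in 0.05-Hz steps, building a tree of nested candidates.
Candidates must span at least 10 bins, reach a 2-Hz peak, occupy no more
than half of the visited bins, and have an odd/even-minute stability
correlation (restricted to the candidate's bins) of at least 0.25.  The
tree is parsed from the highest thresholds down: in each chain of
overlapping valid candidates the lowest-threshold one is kept, except
that a candidate with two or more valid descendant fields is discarded
in favour of the descendants.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage

from .environments import EnvironmentSpec
from .ratemaps import Ratemap, spatial_correlation

__all__ = ["PlaceField", "detect_fields", "field_geometry", "field_maps"]

FOUR_CONNECTED = ndimage.generate_binary_structure(2, 1)

DEFAULT_BASE_HZ = 1.0
DEFAULT_STEP_HZ = 0.05
DEFAULT_MIN_BINS = 10
DEFAULT_MIN_PEAK_HZ = 2.0
DEFAULT_MAX_FRACTION = 0.5
DEFAULT_STABILITY_MIN = 0.25


@dataclass
class PlaceField:
    """A detected place field: 4-connected bin set with geometry."""

    bins: frozenset[tuple[int, int]]
    threshold_hz: float
    peak_bin: tuple[int, int]
    peak_rate: float
    area_cm2: float
    width_x_cm: float
    width_y_cm: float
    stability: float = float("nan")
    unit_id: str = ""
    env_id: str = ""

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        idx = np.array(sorted(self.bins))
        if len(idx):
            m[idx[:, 0], idx[:, 1]] = True
        return m


@dataclass
class _Candidate:
    threshold: float
    mask: np.ndarray
    valid: bool
    children: list["_Candidate"] = dc_field(default_factory=list)


def _components(rate: np.ndarray, threshold: float) -> list[np.ndarray]:
    above = np.isfinite(rate) & (rate >= threshold)
    labels, n = ndimage.label(above, structure=FOUR_CONNECTED)
    return [labels == k for k in range(1, n + 1)]


def _candidate_stability(
    mask: np.ndarray, odd: Ratemap, even: Ratemap, stability_min: float
) -> bool:
    r = spatial_correlation(
        np.where(mask, odd.rate, np.nan),
        np.where(mask, even.rate, np.nan),
        visited_a=odd.visited & mask,
        visited_b=even.visited & mask,
    )
    # fewer than 6 valid bins yields NaN: deemed unstable
    return bool(np.isfinite(r) and r >= stability_min)


def detect_fields(
    rm: Ratemap,
    split_maps: tuple[Ratemap, Ratemap],
    base_hz: float = DEFAULT_BASE_HZ,
    step_hz: float = DEFAULT_STEP_HZ,
    min_bins: int = DEFAULT_MIN_BINS,
    min_peak: float = DEFAULT_MIN_PEAK_HZ,
    max_fraction: float = DEFAULT_MAX_FRACTION,
    stability_min: float = DEFAULT_STABILITY_MIN,
) -> list[PlaceField]:
    """Detect place fields in a ratemap by iterative thresholding.

    ``split_maps`` is the odd/even-minute map pair used for the stability
    test.  Returns fields sorted by descending peak rate.
    """
    odd, even = split_maps
    if odd.shape != rm.shape or even.shape != rm.shape:
        raise ValueError("split maps must share the ratemap geometry")

    rate = np.where(rm.visited, rm.rate, np.nan)
    n_visited = int(rm.visited.sum())
    max_bins = max_fraction * n_visited

    def validate(mask: np.ndarray) -> bool:
        size = int(mask.sum())
        if size < min_bins or size > max_bins:
            return False
        if np.nanmax(np.where(mask, rate, np.nan)) < min_peak:
            return False
        return _candidate_stability(mask, odd, even, stability_min)

    # Build the candidate tree with an explicit stack (trees can be several
    # hundred threshold levels deep for high-rate cells).  Branches whose
    # peak falls below min_peak can never yield a valid candidate and are
    # pruned; components smaller than min_bins likewise.
    nodes: list[_Candidate] = []
    parent_of: list[int] = []
    stack: list[tuple[np.ndarray, float, int]] = [
        (comp, base_hz, -1)
        for comp in _components(rate, base_hz)
        if comp.sum() >= min_bins
    ]
    while stack:
        mask, threshold, parent = stack.pop()
        peak = np.nanmax(np.where(mask, rate, np.nan))
        if peak < min_peak:
            continue
        node = _Candidate(threshold, mask, validate(mask))
        idx = len(nodes)
        nodes.append(node)
        parent_of.append(parent)
        sub = np.where(mask, rate, np.nan)
        for comp in _components(sub, threshold + step_hz):
            if comp.sum() >= min_bins:
                stack.append((comp, threshold + step_hz, idx))

    # Parse from the highest thresholds down: children appear after their
    # parent in ``nodes``, so a reverse sweep aggregates descendant fields.
    results: list[list[_Candidate]] = [[] for _ in nodes]
    accepted: list[_Candidate] = []
    for i in range(len(nodes) - 1, -1, -1):
        sub_fields = results[i]
        if len(sub_fields) >= 2:
            chosen = sub_fields
        elif nodes[i].valid:
            chosen = [nodes[i]]
        else:
            chosen = sub_fields
        p = parent_of[i]
        if p < 0:
            accepted.extend(chosen)
        else:
            results[p].extend(chosen)

    fields = []
    for cand in accepted:
        f = _make_field(cand, rm)
        f.stability = _restricted_correlation(cand.mask, odd, even)
        fields.append(f)
    return sorted(fields, key=lambda f: -f.peak_rate)


def _restricted_correlation(mask: np.ndarray, odd: Ratemap, even: Ratemap) -> float:
    return spatial_correlation(
        np.where(mask, odd.rate, np.nan),
        np.where(mask, even.rate, np.nan),
        visited_a=odd.visited & mask,
        visited_b=even.visited & mask,
    )


def _make_field(cand: _Candidate, rm: Ratemap) -> PlaceField:
    idx = np.argwhere(cand.mask)
    rates = rm.rate[cand.mask]
    # deterministic peak tie-break: lowest row-major index among maxima
    flat = np.where(cand.mask, np.nan_to_num(rm.rate, nan=-np.inf), -np.inf)
    peak_flat = int(np.argmax(flat))
    peak_bin = np.unravel_index(peak_flat, rm.shape)
    area = rm.bin_cm**2 * len(idx)
    width_x = (idx[:, 0].max() - idx[:, 0].min() + 1) * rm.bin_cm
    width_y = (idx[:, 1].max() - idx[:, 1].min() + 1) * rm.bin_cm
    return PlaceField(
        bins=frozenset(map(tuple, idx)),
        threshold_hz=cand.threshold,
        peak_bin=(int(peak_bin[0]), int(peak_bin[1])),
        peak_rate=float(np.nanmax(rates)),
        area_cm2=float(area),
        width_x_cm=float(width_x),
        width_y_cm=float(width_y),
        unit_id=rm.unit_id,
        env_id=rm.env.env_id,
    )


def field_geometry(
    field: PlaceField, rm: Ratemap
) -> tuple[float, float, float, tuple[int, int]]:
    """(area_cm2, width_x_cm, width_y_cm, peak_bin) of a field.

    Area sums the 16-cm^2 bins; a width is the extent of the field's
    projection onto the corresponding axis.
    """
    if not field.bins:
        raise ValueError("empty field bin set")
    idx = np.array(sorted(field.bins))
    nx, ny = rm.shape
    if idx[:, 0].max() >= nx or idx[:, 1].max() >= ny or idx.min() < 0:
        raise ValueError("field bins fall outside the ratemap grid")
    area = rm.bin_cm**2 * len(idx)
    width_x = (idx[:, 0].max() - idx[:, 0].min() + 1) * rm.bin_cm
    width_y = (idx[:, 1].max() - idx[:, 1].min() + 1) * rm.bin_cm
    flat = np.full((nx, ny), -np.inf)
    flat[idx[:, 0], idx[:, 1]] = np.nan_to_num(rm.rate[idx[:, 0], idx[:, 1]], nan=-np.inf)
    peak = np.unravel_index(int(np.argmax(flat)), (nx, ny))
    return float(area), float(width_x), float(width_y), (int(peak[0]), int(peak[1]))


def field_maps(
    fields: list[PlaceField],
    env: EnvironmentSpec,
    bin_cm: float = 4.0,
    band_cm: float = 25.0,
) -> dict[str, object]:
    """Per-bin mean field area/width grids and peak density per band.

    Bins not overlapped by any field carry NaN.  Peak density for each
    25-cm wall-distance band is peaks per band area in m^2.
    """
    from .population_stats import band_partition  # local import, no cycle

    nx = int(np.ceil(env.width_cm / bin_cm))
    ny = int(np.ceil(env.height_cm / bin_cm))
    area_sum = np.zeros((nx, ny))
    wx_sum = np.zeros((nx, ny))
    wy_sum = np.zeros((nx, ny))
    count = np.zeros((nx, ny))
    part = band_partition(env, bin_cm=bin_cm, band_cm=band_cm)
    n_bands = int(part.band.max()) + 1
    peak_counts = np.zeros(n_bands)
    for f in fields:
        idx = np.array(sorted(f.bins))
        area_sum[idx[:, 0], idx[:, 1]] += f.area_cm2
        wx_sum[idx[:, 0], idx[:, 1]] += f.width_x_cm
        wy_sum[idx[:, 0], idx[:, 1]] += f.width_y_cm
        count[idx[:, 0], idx[:, 1]] += 1
        peak_counts[part.band[f.peak_bin]] += 1

    with np.errstate(invalid="ignore"):
        mean_area = np.where(count > 0, area_sum / np.maximum(count, 1), np.nan)
        mean_wx = np.where(count > 0, wx_sum / np.maximum(count, 1), np.nan)
        mean_wy = np.where(count > 0, wy_sum / np.maximum(count, 1), np.nan)

    band_area_m2 = np.array(
        [(part.band == b).sum() * bin_cm**2 / 1e4 for b in range(n_bands)]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(band_area_m2 > 0, peak_counts / band_area_m2, np.nan)
    return {
        "mean_area_cm2": mean_area,
        "mean_width_x_cm": mean_wx,
        "mean_width_y_cm": mean_wy,
        "n_overlapping": count,
        "peak_density_per_m2": density,
        "band_area_m2": band_area_m2,
        "peak_counts": peak_counts,
    }


def fields_table(fields: list[PlaceField]) -> pd.DataFrame:
    """One row per field, ready for delimited-text export."""
    rows = [
        {
            "env": f.env_id,
            "unit": f.unit_id,
            "threshold_hz": f.threshold_hz,
            "peak_ix": f.peak_bin[0],
            "peak_iy": f.peak_bin[1],
            "peak_rate_hz": f.peak_rate,
            "area_cm2": f.area_cm2,
            "width_x_cm": f.width_x_cm,
            "width_y_cm": f.width_y_cm,
            "stability": f.stability,
        }
        for f in fields
    ]
    return pd.DataFrame(rows)
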