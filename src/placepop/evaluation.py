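"""End-to-end evaluation benchmarks.

Each function runs one self-contained benchmark of the emulated
recording protocol on
synthetic data — from generation through the full analysis path — and
returns a flat dict of measured quantities.  The test suite asserts on
these quantities; ``scripts/acceptance.py`` reports them.

Problem sizes are scaled for a desk-class run: recording durations
follow the protocol's area scaling divided by four, populations are
tens to hundreds of cells, and replicate counts are 50-100.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import integrate, stats

from . import dynamics, gridsim, synthetic, vision
from .decoding import (
    ActivityWindow,
    count_windows,
    decode_position,
    decode_posterior,
    decode_session,
)
from .environments import PRESETS
from .field_models import (
    DensityRegression,
    adjusted_area,
    fit_models,
    fit_proportion_regression,
    gamma_poisson_pmf,
)
from .fields import detect_fields
from .population_stats import band_activity, band_partition, jensen_shannon
from .ratemaps import Ratemap, compute_ratemap, split_session

AREAS = {e: PRESETS[e].area_m2 for e in "ABCD"}
#: Protocol session durations (s), scaled down by four.
DURATIONS_S = {"A": 225.0, "B": 450.0, "C": 900.0, "D": 1800.0}


def _rel_range(v: np.ndarray) -> float:
    v = np.asarray(v, dtype=float)
    return float((v.max() - v.min()) / v.mean())


# ---------------------------------------------------------------- criterion 1
def pmf_quadrature_error() -> dict:
    """Max |PMF - quadrature of the Poisson-Gamma mixture| over a grid."""
    worst = 0.0
    for alpha in (0.5, 1.0, 2.0, 5.0):
        for theta_a in (0.5, 1.0, 2.0, 5.0):
            area = 2.0
            theta = theta_a / area
            scale = theta * area
            for x in range(31):
                val, _ = integrate.quad(
                    lambda tau: stats.poisson.pmf(x, tau)
                    * stats.gamma.pdf(tau, a=alpha, scale=scale),
                    0,
                    np.inf,
                    limit=200,
                )
                err = abs(float(gamma_poisson_pmf(x, alpha, theta, area)) - val)
                worst = max(worst, err)
    return {"pmf_quadrature_max_abs_error": worst}


# ---------------------------------------------------------------- criterion 2
def parameter_recovery(seed: int, n_recovery: int = 50, n_bic: int = 100) -> dict:
    """Gamma-Poisson parameter recovery and BIC model selection rates."""
    rng = np.random.default_rng(seed)
    area, alpha, theta = 2.0, 1.0, 1.0  # theta * A = 2, n = 627 cells
    rec_alpha, rec_theta = [], []
    gp_preferred = 0
    for i in range(max(n_recovery, n_bic)):
        taus = rng.gamma(alpha, theta * area, size=627)
        x = rng.poisson(taus)
        _, gp, preferred = fit_models(x, area)
        if i < n_recovery:
            rec_alpha.append(gp.alpha)
            rec_theta.append(gp.theta)
        if i < n_bic:
            gp_preferred += preferred == "gamma_poisson"
    eq_preferred = 0
    for _ in range(n_bic):
        x = rng.poisson(2.0, size=627)
        _, _, preferred = fit_models(x, area)
        eq_preferred += preferred == "equal_poisson"
    return {
        "alpha_median_rel_error": float(
            abs(np.median(rec_alpha) - alpha) / alpha
        ),
        "theta_median_rel_error": float(
            abs(np.median(rec_theta) - theta) / theta
        ),
        "bic_prefers_gamma_poisson_of_100": int(gp_preferred),
        "bic_prefers_equal_poisson_of_100": int(eq_preferred),
    }


# ---------------------------------------------------------------- criterion 3
def adjusted_area_checks(seed: int) -> dict:
    """A' - A = c/b identity, randomized and at the printed regression."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(200):
        a = rng.uniform(0.5, 20.0)
        b = rng.uniform(0.005, 1.0)
        c = rng.uniform(0.0, 0.5)
        off = adjusted_area(a, DensityRegression(b, c)) - a
        worst = max(worst, abs(off - c / b))
    reg = DensityRegression(0.038, 0.093)
    return {
        "identity_max_abs_error": worst,
        "study_regression_area_offset_m2": adjusted_area(5.0, reg) - 5.0,
        "study_regression_adjusted_area_D_m2": adjusted_area(8.75, reg),
    }


# ---------------------------------------------------------------- criterion 4
def _bump_map(env, centers, sigma=10.0, amp=8.0, bin_cm=4.0) -> Ratemap:
    nx = int(np.ceil(env.width_cm / bin_cm))
    ny = int(np.ceil(env.height_cm / bin_cm))
    xs = (np.arange(nx) + 0.5) * bin_cm
    ys = (np.arange(ny) + 0.5) * bin_cm
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    rate = np.zeros((nx, ny))
    for cx, cy in centers:
        rate += amp * np.exp(-((gx - cx) ** 2 + (gy - cy) ** 2) / (2 * sigma**2))
    return Ratemap(
        rate=rate,
        dwell_s=np.ones((nx, ny)),
        spike_count=rate.copy(),
        visited=np.ones((nx, ny), dtype=bool),
        bin_cm=bin_cm,
        env=env,
    )


def field_detection_recovery(seed: int, n_maps: int = 100) -> dict:
    """Fraction of seeded maps where exactly k bumps -> k fields, k=1..4."""
    env = PRESETS["C"]  # large enough to separate four bumps
    rng = np.random.default_rng(seed)
    exact = 0
    total = 0
    min_sep = 65.0
    for _ in range(n_maps):
        k = rng.integers(1, 5)
        centers = []
        while len(centers) < k:
            cand = rng.uniform([30, 30], [env.width_cm - 30, env.height_cm - 30])
            if all(np.hypot(*(cand - c)) > min_sep for c in centers):
                centers.append(cand)
        rm = _bump_map(env, centers, sigma=rng.uniform(9, 12), amp=rng.uniform(5, 9))
        fields = detect_fields(rm, (rm, rm))
        masks = [f.mask(rm.shape) for f in fields]
        for i, m in enumerate(masks):  # detected fields never overlap
            for m2 in masks[i + 1 :]:
                assert not (m & m2).any()
        exact += len(fields) == k
        total += 1

    # two bumps merged at 1 Hz but separable at a higher threshold
    env_a = PRESETS["A"]
    rm = _bump_map(env_a, [(24, 50), (52, 79)], sigma=9.0, amp=8.0)
    merged = detect_fields(rm, (rm, rm))
    return {
        "exact_recovery_fraction": exact / total,
        "merged_pair_field_count": len(merged),
    }


# ---------------------------------------------------------------- criterion 5
def _four_env_sessions(seed: int, n_cells: int):
    sessions = {}
    for i, env_id in enumerate("ABCD"):
        env = PRESETS[env_id]
        traj = synthetic.generate_trajectory(
            env, DURATIONS_S[env_id], seed=seed + 10 + i
        )
        cells = synthetic.generate_population(
            env, n_cells, alpha=1.5, theta=0.9, seed=seed + 20 + i
        )
        trains = synthetic.generate_spikes(cells, traj, seed=seed + 30 + i)
        sessions[env_id] = (traj, trains)
    return sessions


def decoding_benchmark(seed: int, n_cells: int = 50) -> dict:
    """Environment classification and position error, 1-s windows,
    3-minute leave-out cross-validated maps."""
    sessions = _four_env_sessions(seed, n_cells)
    full_maps = {
        e: [compute_ratemap(tr, st, PRESETS[e]) for st in sp]
        for e, (tr, sp) in sessions.items()
    }
    correct = total = 0
    errors = []
    for env_id, (traj, trains) in sessions.items():
        other = {k: v for k, v in full_maps.items() if k != env_id}
        df = decode_session(traj, trains, PRESETS[env_id], other_env_maps=other)
        correct += int((df.decoded_env == env_id).sum())
        total += len(df)
        errors.extend(df.error_cm)

    # population-size scaling on the smallest arena
    env = PRESETS["A"]
    traj = synthetic.generate_trajectory(env, 180.0, seed=seed + 50)
    cells = synthetic.generate_population(env, 200, alpha=1.5, theta=0.9, seed=seed + 51)
    trains = synthetic.generate_spikes(cells, traj, seed=seed + 52)
    maps = [compute_ratemap(traj, st, env) for st in trains]
    wins = count_windows(traj, trains, window_s=1.0)
    med_err = {}
    for n in (10, 50, 200):
        errs = []
        for w in wins:
            post = decode_posterior(
                ActivityWindow(w.start_s, w.duration_s, w.counts[:n]), maps[:n]
            )
            xy = decode_position(post)
            sel = (traj.timestamps >= w.start_s) & (traj.timestamps < w.start_s + 1.0)
            errs.append(float(np.hypot(*(xy - traj.xy[sel].mean(axis=0)))))
        med_err[n] = float(np.median(errs))
    return {
        "environment_decoding_accuracy_pct": 100.0 * correct / total,
        "median_position_error_cm": float(np.median(errors)),
        "median_error_cm_10_cells": med_err[10],
        "median_error_cm_50_cells": med_err[50],
        "median_error_cm_200_cells": med_err[200],
    }


# ---------------------------------------------------------------- criterion 6
def uniform_lattice_stats() -> dict:
    """Summed-rate and change constancy of the 1271-field lattice."""
    env = PRESETS["D"]
    pop = gridsim.build_uniform_population(env, 1271)
    xs = np.linspace(30.0, env.width_cm - 30.0, 40)
    ys = np.linspace(30.0, env.height_cm - 30.0, 30)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    summed = pop.summed_rate(pts)
    change_cv = []
    means = []
    for ang in np.radians([0.0, 45.0, 90.0, 135.0]):
        d = np.array([np.cos(ang), np.sin(ang)])
        _, _, ch = gridsim.evaluate_population(pop, pts, d, 1.0)
        change_cv.append(ch.std() / ch.mean())
        means.append(ch.mean())
    return {
        "uniform_summed_rate_cv_pct": 100.0 * float(summed.std() / summed.mean()),
        "uniform_change_cv_pct": 100.0 * float(max(change_cv)),
        "uniform_heading_spread_pct": 100.0
        * float((max(means) - min(means)) / np.mean(means)),
    }


# ---------------------------------------------------------------- criterion 7
def boundary_change_ratios() -> dict:
    """Band-0 / band-3 change ratios for orthogonal vs parallel motion."""
    env = PRESETS["D"]
    pop = gridsim.build_boundary_population(env)
    grid = gridsim._arena_grid(env)
    dx = np.minimum(grid[:, 0], env.width_cm - grid[:, 0])
    dy = np.minimum(grid[:, 1], env.height_cm - grid[:, 1])
    wall_axis = (dy < dx).astype(int)
    band = (np.minimum(dx, dy) // 25).astype(int)
    d_orth = np.where(wall_axis[:, None] == 0, [1.0, 0.0], [0.0, 1.0])
    d_par = np.where(wall_axis[:, None] == 0, [0.0, 1.0], [1.0, 0.0])
    _, _, ch_o = gridsim.evaluate_population(pop, grid, d_orth, 1.0)
    _, _, ch_p = gridsim.evaluate_population(pop, grid, d_par, 1.0)
    return {
        "boundary_orthogonal_band0_band3_ratio": float(
            ch_o[band == 0].mean() / ch_o[band == 3].mean()
        ),
        "boundary_parallel_band0_band3_ratio": float(
            ch_p[band == 0].mean() / ch_p[band == 3].mean()
        ),
    }


# ---------------------------------------------------------------- criterion 8
def homeostasis_benchmark(seed: int, duration_s: float = 900.0) -> dict:
    """Band statistics of spiking boundary populations, plus the
    total-field-area versus area regression across the four arenas."""
    env = PRESETS["D"]
    part = band_partition(env)
    traj = synthetic.generate_trajectory(env, duration_s, seed=seed + 5)
    out = {}
    for label, kwargs in (
        ("normalized", {}),
        ("control", {"density": "uniform", "normalize": False}),
    ):
        pop = gridsim.build_boundary_population(env, **kwargs)
        trains = synthetic.generate_spikes(
            pop.to_cells(baseline_hz=0.0), traj, seed=seed + 6
        )
        maps = [compute_ratemap(traj, st, env) for st in trains]
        tab = band_activity(maps, part)
        out[f"{label}_mean_rate_rel_range_pct"] = 100.0 * _rel_range(
            tab.mean_rate_hz.to_numpy()
        )
        out[f"{label}_coactive_rel_range_pct"] = 100.0 * _rel_range(
            tab.proportion_active.to_numpy()
        )

    # field-area scaling: animals x arenas, detection end to end; cell
    # yields match a realistic per-animal recording scale so each point
    # aggregates tens to hundreds of fields
    counts_by_env: dict[str, list] = {e: [] for e in "ABCD"}
    areas_by_env: dict[str, list] = {e: [] for e in "ABCD"}
    for animal in range(3):
        for i, env_id in enumerate("ABCD"):
            e = PRESETS[env_id]
            traj = synthetic.generate_trajectory(
                e, DURATIONS_S[env_id], seed=seed + 100 * animal + i
            )
            cells = synthetic.generate_population(
                e, 200, alpha=1.0, theta=0.28, seed=seed + 100 * animal + 10 + i
            )
            trains = synthetic.generate_spikes(
                cells, traj, seed=seed + 100 * animal + 20 + i
            )
            total_area = 0.0
            n_fields = 0
            for st in trains:
                rm = compute_ratemap(traj, st, e)
                (ta, sa), (tb, sb) = split_session(traj, st)
                splits = (compute_ratemap(ta, sa, e), compute_ratemap(tb, sb, e))
                for f in detect_fields(rm, splits):
                    total_area += f.area_cm2
                    n_fields += 1
            counts_by_env[env_id].append(n_fields)
            areas_by_env[env_id].append(total_area)

    # per-animal total-field-area proportions vs arena area
    area_mat = np.array([areas_by_env[e] for e in "ABCD"])  # env x animal
    props = area_mat / area_mat.sum(axis=0)
    xs = np.repeat([AREAS[e] for e in "ABCD"], props.shape[1])
    fit = stats.linregress(xs, props.ravel())
    out["field_area_vs_area_r"] = float(fit.rvalue)
    reg = fit_proportion_regression(
        {e: np.array(counts_by_env[e]) for e in "ABCD"}, AREAS
    )
    out["field_count_vs_area_r"] = float(reg.r)
    out["field_count_regression_slope"] = float(reg.slope)
    out["field_count_regression_intercept"] = float(reg.intercept)
    return out


# ---------------------------------------------------------------- criterion 9
def visual_benchmark(seed: int, duration_s: float = 600.0) -> dict:
    """Visual change near vs far from the cued wall, and the ordering of
    activity-change correlations on a full synthetic session."""
    env = PRESETS["D"]
    scene = vision.SceneModel(env)
    rig = vision.CameraRig()

    # straight approach to the cued north wall
    ys = np.arange(150.0, 248.0)
    poses = np.column_stack([np.full_like(ys, 160.0), ys])
    frames = vision.render_sequence(scene, rig, poses, np.full(len(ys), 90.0))
    vc = vision.visual_change_series(frames)
    dist = env.height_cm - ys
    near = float(np.nanmean(vc[(dist > 7.5) & (dist < 17.5)]))
    far = float(np.nanmean(vc[(dist > 82.5) & (dist < 92.5)]))

    # full session: boundary population rates along a foraging path
    pop = gridsim.build_boundary_population(env)
    traj = synthetic.generate_trajectory(env, duration_s, seed=seed + 7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pa = dynamics.resample_grid_along_path(pop, traj)
    change = dynamics.activity_change(pa)
    vc_path = vision.visual_change_for_path(
        scene, rig, pa.positions, pa.heading_deg, pa.segment
    )
    r_visual, _ = dynamics.covariate_correlation(change, vc_path)
    r_speed, _ = dynamics.covariate_correlation(change, pa.speed_cm_s)
    return {
        "visual_change_at_12p5_cm": near,
        "visual_change_at_87p5_cm": far,
        "corr_activity_visual": float(r_visual),
        "corr_activity_speed": float(r_speed),
    }


# --------------------------------------------------------------- criterion 10
def jsd_checks() -> dict:
    """Jensen-Shannon divergence properties and a hand-computed example."""
    p = np.array([0.5, 0.25, 0.25])
    q = np.array([0.25, 0.25, 0.5])
    m = (p + q) / 2
    hand = 0.5 * np.sum(p * np.log(p / m)) + 0.5 * np.sum(q * np.log(q / m))
    got = jensen_shannon(p, q)
    rng = np.random.default_rng(0)
    sym_err = bound_excess = 0.0
    for _ in range(100):
        a = rng.uniform(0.01, 1.0, size=6)
        b = rng.uniform(0.01, 1.0, size=6)
        d1, d2 = jensen_shannon(a, b), jensen_shannon(b, a)
        sym_err = max(sym_err, abs(d1 - d2))
        bound_excess = max(bound_excess, d1 - np.log(2))
    return {
        "jsd_identical_value": float(jensen_shannon(p, p)),
        "jsd_hand_example_abs_error": float(abs(got - hand)),
        "jsd_symmetry_max_abs_error": float(sym_err),
        "jsd_ln2_bound_excess": float(bound_excess),
    }
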