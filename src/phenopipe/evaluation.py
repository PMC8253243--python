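"""End-to-end validation benchmarks run against synthetic ground truth.

Each routine regenerates its inputs from a seed, runs the corresponding
pipeline stage, and reports summary metrics as a flat dict.  They back both
the test suite and ``scripts/acceptance.py``; oracles used here (step-up
false-discovery adjustment, per-sample occupancy recomputation) are written
as plain loops/closed forms, independent of the implementation paths they
check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from . import arena, cohort, mri, synthgen, thermo

__all__ = [
    "bh_stepup",
    "brute_force_occupancy",
    "thermography_recovery",
    "anticipation_detection",
    "ivim_recovery",
    "dsc_closed_forms",
    "fdr_oracle",
    "planted_effect_fdp",
    "zone_oracle",
    "ppi_and_gating",
]


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def bh_stepup(pvals: np.ndarray) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up adjusted p-values (plain loop)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        val = p[idx] / ((rank_from_top + 1) / m)
        running_min = min(running_min, val)
        q[idx] = running_min
    return q


def _point_in_zone(zone, x: float, y: float) -> bool:
    """Scalar membership test recomputed from raw geometry."""
    if isinstance(zone, arena.CircleZone):
        return (x - zone.cx) ** 2 + (y - zone.cy) ** 2 <= zone.r**2
    if isinstance(zone, arena.AnnulusZone):
        d2 = (x - zone.cx) ** 2 + (y - zone.cy) ** 2
        return zone.r_in**2 <= d2 < zone.r_out**2
    if isinstance(zone, arena.AnnulusSectorZone):
        dx, dy = x - zone.cx, y - zone.cy
        d2 = dx * dx + dy * dy
        if not (zone.r_in**2 <= d2 < zone.r_out**2):
            return False
        span = (zone.theta_end - zone.theta_start) % (2 * math.pi)
        ang = (math.atan2(dy, dx) - zone.theta_start) % (2 * math.pi)
        return ang < span
    raise TypeError(f"unknown zone type {type(zone)}")


def brute_force_occupancy(
    track: arena.Trajectory,
    zone,
    t_start: float,
    t_end: float,
    min_visit_duration: float = 0.5,
    merge_gap: float = 0.2,
) -> dict:
    """Occupancy metrics recomputed sample by sample with explicit loops."""
    dt = 1.0 / track.sampling_rate
    inside = []
    times = []
    for t, x, y in track.samples[["t", "x", "y"]].itertuples(index=False):
        if t_start <= t < t_end:
            inside.append(_point_in_zone(zone, x, y))
            times.append(t)
    total = sum(inside) * dt

    # maximal runs -> merge short gaps -> filter short visits
    runs = []
    start = None
    for i, flag in enumerate(inside):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(inside)))
    merged = []
    for r in runs:
        if merged and (r[0] - merged[-1][1]) * dt <= merge_gap:
            merged[-1] = (merged[-1][0], r[1])
        else:
            merged.append(list(r))
            merged[-1] = tuple(merged[-1])
    visits = [r for r in merged if (r[1] - r[0]) * dt >= min_visit_duration]

    if any(inside):
        latency = times[inside.index(True)] - t_start
        censored = False
    else:
        latency = t_end - t_start
        censored = True
    return {
        "total_time": total,
        "n_visits": len(visits),
        "latency": latency,
        "censored": censored,
    }


def _brute_force_path_length(track, t_start, t_end) -> float:
    pts = [
        (x, y)
        for t, x, y in track.samples[["t", "x", "y"]].itertuples(index=False)
        if t_start <= t < t_end
    ]
    total = 0.0
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        total += math.hypot(x1 - x0, y1 - y0)
    return total


# ---------------------------------------------------------------------------
# thermography
# ---------------------------------------------------------------------------

def _iou(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    return float(np.logical_and(a, b).sum() / union) if union else 1.0


def thermography_recovery(
    n_sessions: int = 100,
    seed: int = 0,
    noise_sd: float = 0.3,
    duration: float = 10.0,
) -> dict:
    """Segmentation and CI fidelity over many default-scene sessions.

    Per valid frame: IoU of the recovered whole-body mask against truth and
    the absolute CI error against the body/tail temperature ratio.
    """
    ious = []
    ci_errs = []
    n_invalid = 0
    for s in range(n_sessions):
        cfg = synthgen.ThermalSceneConfig(
            noise_sd=noise_sd, duration=duration, seed=seed * 100_003 + s
        )
        session, truth = synthgen.gen_thermal_session(cfg)
        series = thermo.extract_ci_series(session)
        for i in range(session.n_frames):
            masks = thermo.segment_mouse(session.frames[i], session.arena_mask)
            if not masks.valid:
                n_invalid += 1
                continue
            whole_true = truth.body_masks[i] | truth.tail_masks[i]
            ious.append(_iou(masks.whole_mask, whole_true))
            row = series.frame.iloc[i]
            if row["valid"]:
                ci_errs.append(abs(row["ci"] - truth.ci[i]))
            else:
                n_invalid += 1
    ious = np.asarray(ious)
    ci_errs = np.asarray(ci_errs)
    return {
        "n_frames": int(len(ious)),
        "n_invalid": n_invalid,
        "median_iou": float(np.median(ious)),
        "frac_iou_ge_0p95": float(np.mean(ious >= 0.95)),
        "median_ci_abs_err": float(np.median(ci_errs)),
        "frac_ci_err_le_0p02": float(np.mean(ci_errs <= 0.02)),
    }


def anticipation_detection(
    seed: int = 0,
    noise_sd: float = 0.3,
    frame_rate: float = 0.25,
    duration: float = 400.0,
    window: tuple[float, float] = (250.0, 350.0),
    cooling: float = 2.0,
) -> dict:
    """Scripted anticipatory tail cooling vs a flat scenario.

    The 'anticipation' session cools the tail linearly by ``cooling`` degC
    across the analysis window (stress-related vasoconstriction raises the
    CI); the control session keeps the tail flat at 30 degC.  Per-frame CI
    values inside the window are compared with Welch's t-test.
    """
    t0, t1 = window

    def cooling_tail(t: float) -> float:
        frac = min(max((t - t0) / (t1 - t0), 0.0), 1.0)
        return 30.0 - cooling * frac

    common = dict(
        noise_sd=noise_sd, frame_rate=frame_rate, duration=duration,
        phases=[("initiation", 0.0, t0), ("anticipation", t0, duration)],
    )
    ramp_cfg = synthgen.ThermalSceneConfig(
        tail_temp=cooling_tail, seed=seed * 7 + 1, **common
    )
    flat_cfg = synthgen.ThermalSceneConfig(tail_temp=30.0, seed=seed * 7 + 2, **common)

    out = {}
    window_ci = {}
    for name, cfg in (("ramp", ramp_cfg), ("flat", flat_cfg)):
        session, _ = synthgen.gen_thermal_session(cfg)
        series = thermo.extract_ci_series(session)
        mean, sd, n = thermo.window_stats(series, t0, t1)
        out[f"{name}_window_mean_ci"] = mean
        out[f"{name}_window_n"] = n
        df = series.frame
        sel = (df["time"] >= t0) & (df["time"] < t1) & df["valid"]
        window_ci[name] = df.loc[sel, "ci"].to_numpy(dtype=float)
    welch = stats.ttest_ind(window_ci["ramp"], window_ci["flat"], equal_var=False)
    out["welch_p"] = float(welch.pvalue)
    out["ci_increase"] = out["ramp_window_mean_ci"] - out["flat_window_mean_ci"]
    return out


# ---------------------------------------------------------------------------
# IVIM
# ---------------------------------------------------------------------------

def ivim_recovery(
    seed: int = 0,
    S0: float = 1.0,
    f: float = 0.10,
    dstar: float = 1e-2,
    adc: float = 7e-4,
    snr: float = 50.0,
    n_replicates: int = 200,
) -> dict:
    """Noiseless exactness and noisy precision of the diffusion fits.

    Noiseless: the tissue fit on a pure mono-exponential recovers the ADC,
    and the joint bi-exponential fit recovers (ADC, f, D*); relative errors
    reported.  Noisy: the segmented two-step pipeline (ADC on b > 200, then
    f and D* on all b) runs on replicates at the given SNR and the median
    absolute error of f is reported.
    """
    b = synthgen.DEFAULT_B_VALUES
    # tissue-only signal: closed-form check of the log-linear high-b fit
    mono = S0 * np.exp(-b * adc)
    adc_fit = mri.fit_adc(mono, b)
    adc_rel_err = abs(adc_fit.adc - adc) / adc

    _, clean = synthgen.gen_ivim_signals(S0, f, dstar, adc, noise_sd=0.0, seed=seed)
    joint = mri.fit_ivim(clean[0], b, free_adc=True)
    noiseless = {
        "adc": abs(joint.adc - adc) / adc,
        "f": abs(joint.f - f) / f,
        "dstar": abs(joint.dstar - dstar) / dstar,
    }

    _, noisy = synthgen.gen_ivim_signals(
        S0, f, dstar, adc, noise_sd=S0 / snr, seed=seed, n_replicates=n_replicates
    )
    f_errs = []
    for sig in noisy:
        fit = mri.fit_ivim_segmented(sig, b)
        if fit.valid:
            f_errs.append(abs(fit.f - f))
    return {
        "adc_monoexp_rel_err": float(adc_rel_err),
        "noiseless_max_rel_err": float(max(noiseless.values())),
        "noiseless_rel_err_f": float(noiseless["f"]),
        "f_median_abs_err_snr": float(np.median(f_errs)),
        "n_replicates": len(f_errs),
    }


# ---------------------------------------------------------------------------
# DSC perfusion
# ---------------------------------------------------------------------------

def dsc_closed_forms(seed: int = 0) -> dict:
    """Echo inversion and gamma-variate closed-form consistency.

    For several bolus shapes: generate noiseless multi-echo series, invert
    to R2*(t), subtract the pre-bolus baseline, fit the gamma variate, and
    check (a) the inversion reproduces the injected curve, (b) recovered
    (alpha, beta, t0) match truth, (c) CBV equals fine trapezoidal
    quadrature of the fitted curve, (d) MTT = beta*(alpha+1) and
    CBF*MTT = CBV identities.
    """
    shapes = [
        dict(K=0.01, alpha=2.0, beta=3.0, t0=10.0),
        dict(K=0.02, alpha=1.5, beta=4.0, t0=20.0),
        dict(K=0.005, alpha=3.0, beta=2.0, t0=15.0),
    ]
    inv_err = 0.0
    param_err = 0.0
    cbv_quad_err = 0.0
    identity_err = 0.0
    mtt_values = []
    for shape in shapes:
        series = synthgen.gen_dsc_series(
            R2star_baseline=0.05, n_frames=300, noise_sd=0.0, seed=seed, **shape
        )
        r2t = mri.fit_r2star_series(series.signals, series.tes)
        n_base = int(np.searchsorted(series.times, shape["t0"]))
        delta = mri.delta_r2star_series(r2t, (0, max(n_base, 2)))
        scale = series.true_delta_r2star.max()
        inv_err = max(inv_err, float(np.max(np.abs(delta - series.true_delta_r2star)) / scale))

        fit = mri.fit_gamma_variate(delta, series.times)
        for name in ("alpha", "beta", "t0"):
            truth = shape[name]
            param_err = max(param_err, abs(getattr(fit, name) - truth) / abs(truth))
        tq = np.linspace(fit.t0, fit.t0 + 40.0 * fit.beta * (fit.alpha + 1), 200_001)
        curve = mri._gamma_model(tq, fit.K, fit.alpha, fit.beta, fit.t0)
        quad = float(np.trapezoid(curve, tq))
        cbv_quad_err = max(cbv_quad_err, abs(fit.cbv - quad) / quad)
        identity_err = max(identity_err, abs(fit.cbf * fit.mtt - fit.cbv))
        mtt_values.append(fit.mtt)
    return {
        "inversion_max_rel_err": inv_err,
        "param_max_rel_err": float(param_err),
        "cbv_vs_quadrature_max_rel_err": float(cbv_quad_err),
        "cbf_mtt_identity_max_abs_err": float(identity_err),
        "mtt_first_shape_s": float(mtt_values[0]),
        "n_shapes": len(shapes),
    }


# ---------------------------------------------------------------------------
# FDR statistics
# ---------------------------------------------------------------------------

def fdr_oracle(seed: int = 0, n_vectors: int = 1000) -> dict:
    """Adjusted q-values vs the independent step-up oracle on random p-vectors."""
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(seed)
    max_diff = 0.0
    total = 0
    for _ in range(n_vectors):
        m = int(rng.integers(1, 200))
        p = rng.uniform(size=m)
        if rng.uniform() < 0.3:  # inject signal and ties
            p[: m // 3] = rng.uniform(0, 1e-3, size=m // 3)
            p = np.round(p, 3)
        q_impl = multipletests(p, method="fdr_bh")[1]
        q_oracle = bh_stepup(p)
        max_diff = max(max_diff, float(np.max(np.abs(q_impl - q_oracle))))
        total += m
    return {"max_abs_diff": max_diff, "n_pvalues": total}


def planted_effect_fdp(
    seed: int = 0,
    n_replicates: int = 20,
    shape: tuple[int, int, int] = (16, 16, 16),
    effect_sd_units: float = 3.0,
    sd: float = 0.05,
    n_per_group: int = 8,
) -> dict:
    """Realized false-discovery proportion on planted volume-reduction maps.

    Group A carries a ``-effect_sd_units * sd`` shift inside a central
    region; discoveries are voxels with z below -2.57 (q < 1%).  Because
    smoothing spreads true signal past the region edge, false positives are
    counted outside the truth mask dilated by two voxels.
    """
    from scipy import ndimage as ndi

    fdps = []
    sens = []
    for r in range(n_replicates):
        ga, gb, truth = synthgen.gen_jacobian_maps(
            shape=shape,
            n_a=n_per_group,
            n_b=n_per_group,
            effect=-effect_sd_units * sd,
            sd=sd,
            seed=seed * 50_021 + r,
        )
        res = mri.voxelwise_jacobian_stats(ga, gb, fwhm_mm=0.1, voxel_mm=0.1)
        disc = res.significant
        n_disc = int(disc.sum())
        dilated = ndi.binary_dilation(truth, iterations=2)
        fp = int((disc & ~dilated).sum())
        fdps.append(fp / n_disc if n_disc else 0.0)
        sens.append(float((disc & truth).sum() / truth.sum()))
    return {
        "mean_fdp": float(np.mean(fdps)),
        "mean_sensitivity": float(np.mean(sens)),
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# arena analytics
# ---------------------------------------------------------------------------

def zone_oracle(
    seed: int = 0,
    n_tracks: int = 100,
    duration: float = 30.0,
    sampling_rate: float = 10.0,
) -> dict:
    """Occupancy/visit/latency/distance agreement with the loop oracle,
    and time conservation over exhaustive disjoint zones."""
    zones = arena.open_field_zones(0.0, 0.0, 60.0)
    quadrants = arena.quadrant_zones(0.0, 0.0, 60.0)
    max_time = max_visits = max_latency = max_dist = 0.0
    max_conservation = 0.0
    for k in range(n_tracks):
        track = synthgen.gen_trajectory(
            zones, duration, speed=20.0, seed=seed * 99_991 + k,
            sampling_rate=sampling_rate,
        )
        t0, t1 = 0.0, duration
        for zs in (zones, quadrants):
            occ = arena.zone_occupancy(track, zs, t0, t1)
            for name, zone in zs.zones.items():
                ref = brute_force_occupancy(track, zone, t0, t1)
                rec = occ[name]
                max_time = max(max_time, abs(rec.total_time - ref["total_time"]))
                max_visits = max(max_visits, abs(rec.n_visits - ref["n_visits"]))
                max_latency = max(
                    max_latency, abs(rec.latency_first_entry - ref["latency"])
                )
                if rec.latency_censored != ref["censored"]:
                    max_latency = max(max_latency, float("inf"))
            total = sum(r.total_time for r in occ.values())
            window = len(track.samples) / sampling_rate
            max_conservation = max(max_conservation, abs(total - window))
        max_dist = max(
            max_dist,
            abs(arena.path_length(track, t0, t1) - _brute_force_path_length(track, t0, t1)),
        )
    return {
        "time_max_abs_diff_s": max_time,
        "visits_max_abs_diff": max_visits,
        "latency_max_abs_diff_s": max_latency,
        "distance_max_abs_diff": max_dist,
        "conservation_max_err_s": max_conservation,
        "n_tracks": n_tracks,
    }


# ---------------------------------------------------------------------------
# %PPI and gating
# ---------------------------------------------------------------------------

def ppi_and_gating(seed: int = 0, n_events: int = 10_000) -> dict:
    """Formula identities for %PPI and exact gate recovery on labelled events."""
    ppi_half = cohort.percent_ppi(50.0, 100.0)
    import pandas as pd

    table = pd.DataFrame(
        {
            "animal": [1] * 4 + [2] * 4,
            "intensity": [70, 75, 80, 120] * 2,
            "amplitude": [50, 60, 70, 100, 120, 90, 80, 100],
        }
    )
    records = cohort.process_startle_table(table)
    negative_excluded = records[1].excluded and not records[0].excluded

    blood_counts = {
        "t_helper": 3000,
        "t_cytotoxic": 2500,
        "b_cell": 2000,
        "myeloid": 1500,
        "ungated_double_positive": n_events - 9000,
    }
    events = synthgen.gen_flow_events("blood", blood_counts, seed=seed)
    gated = cohort.gate_cells(events, "blood")
    truth = events["true_label"].value_counts().to_dict()
    max_err = 0
    for name in ("t_helper", "t_cytotoxic", "b_cell", "myeloid"):
        max_err = max(max_err, abs(gated.counts[name] - truth.get(name, 0)))
    max_err = max(
        max_err,
        abs(gated.counts["ungated"] - truth.get("ungated_double_positive", 0)),
    )

    brain_counts = {
        "microglia": 4000,
        "macrophage": 1000,
        "cd4_t": 1500,
        "cd8_t": 1200,
        "b_cell": 800,
        "plasma_cell": 500,
        "leukocyte_other": 700,
        "ungated_negative": 300,
    }
    brain_events = synthgen.gen_flow_events("brain", brain_counts, seed=seed + 1)
    brain = cohort.gate_cells(brain_events, "brain")
    btruth = brain_events["true_label"].value_counts().to_dict()
    for sub in ("cd4_t", "cd8_t", "b_cell", "plasma_cell"):
        max_err = max(max_err, abs(brain.subgates[sub] - btruth.get(sub, 0)))
    for top, names in (
        ("microglia", ("microglia",)),
        ("macrophage", ("macrophage",)),
    ):
        max_err = max(max_err, abs(brain.counts[top] - sum(btruth.get(n, 0) for n in names)))
    leuko_truth = sum(
        btruth.get(n, 0)
        for n in ("cd4_t", "cd8_t", "b_cell", "plasma_cell", "leukocyte_other")
    )
    max_err = max(max_err, abs(brain.counts["leukocyte"] - leuko_truth))

    return {
        "ppi_half_pct": float(ppi_half),
        "negative_ppi_excluded": bool(negative_excluded),
        "gate_count_max_abs_err": int(max_err),
        "n_events": n_events + sum(brain_counts.values()),
    }
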