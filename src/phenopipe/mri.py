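"""Parametric MRI model fitting and voxelwise morphometry statistics.

Four analyses live here:

* **Segmented IVIM.** Tissue diffusion (ADC) is fitted log-linearly using
  only diffusion weightings above 200 s/mm^2, where the capillary
  pseudo-diffusion compartment has decayed away; the perfusion fraction f
  and pseudo-diffusion coefficient D* are then estimated from all b-values
  with the ADC held fixed:  S(b) = S0*[f*exp(-b*D*) + (1-f)*exp(-b*ADC)].
  A joint free-ADC fit is available behind a flag.
* **Multi-echo relaxometry.** R2* = 1/T2* per time point from a
  mono-exponential fit over echo time.
* **Gamma-variate perfusion.** The bolus-passage dR2*(t) curve is fitted
  with K*(t-t0)^alpha*exp(-(t-t0)/beta); cerebral blood volume is the curve
  area CBV = K*beta^(alpha+1)*Gamma(alpha+1), the mean transit time is the
  first moment MTT = beta*(alpha+1), and CBF = CBV/MTT (relative units, no
  arterial-input deconvolution).
* **Voxelwise volume-change statistics.** Two-sample t-tests on Gaussian-
  smoothed Jacobian-determinant maps, Benjamini-Hochberg q-values, and
  signed z-scores (z = sign of effect times the two-sided normal quantile of
  q); volume reductions are displayed at z < -2.57, the z magnitude
  corresponding to a false discovery rate below 1%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy import optimize, stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ADCFit",
    "IVIMParams",
    "DSCFit",
    "VoxelStatsMap",
    "fit_adc",
    "fit_ivim",
    "fit_ivim_segmented",
    "fit_r2star",
    "fit_r2star_series",
    "delta_r2star_series",
    "fit_gamma_variate",
    "voxelwise_jacobian_stats",
    "z_for_fdr",
    "roi_volume",
    "frame_rate_radial",
]

FWHM_TO_SIGMA = 1.0 / math.sqrt(8.0 * math.log(2.0))


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------

@dataclass
class ADCFit:
    S0: float          # intercept of the high-b mono-exponential, signal units
    adc: float         # mm^2/s
    n_points: int
    valid: bool


def fit_adc(signals, b_values, b_threshold: float = 200.0) -> ADCFit:
    """Log-linear tissue-diffusion fit restricted to b > ``b_threshold``.

    The least squares runs on ln S vs b with signal-proportional weights
    (delta method: additive signal noise of sd sigma becomes log-domain
    noise of sd sigma/S, so weighting residuals by S restores
    homoscedasticity); ADC = -slope.  Non-positive signals are dropped;
    fewer than two usable points make the fit invalid (NaN estimates),
    never an exception.
    """
    s = np.asarray(signals, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if s.shape != b.shape:
        raise ValueError("signals and b_values must have equal length")
    keep = (b > b_threshold) & (s > 0)
    n = int(keep.sum())
    if n < 2:
        return ADCFit(float("nan"), float("nan"), n, False)
    slope, intercept = np.polyfit(b[keep], np.log(s[keep]), 1, w=s[keep])
    return ADCFit(float(np.exp(intercept)), float(-slope), n, True)


@dataclass
class IVIMParams:
    """Intravoxel-incoherent-motion parameters with fit diagnostics."""

    S0: float
    adc: float         # mm^2/s (held fixed in the segmented fit)
    f: float           # perfusion fraction in [0, 1]
    dstar: float       # mm^2/s, pseudo-diffusion
    residual_norm: float
    n_iterations: int
    valid: bool
    message: str = ""


def _ivim_model(b, S0, f, dstar, adc):
    return S0 * (f * np.exp(-b * dstar) + (1.0 - f) * np.exp(-b * adc))


def fit_ivim(
    signals,
    b_values,
    adc_fixed: float | None = None,
    dstar_max: float = 0.1,
    free_adc: bool = False,
) -> IVIMParams:
    """Perfusion-fraction fit over all b-values.

    Segmented mode (default): ``adc_fixed`` comes from :func:`fit_adc` and
    (S0, f, D*) are estimated by bounded nonlinear least squares with
    f in [0, 1] and D* in (ADC, ``dstar_max``].  With ``free_adc=True`` the
    ADC is estimated jointly instead.  Non-convergence is reported via
    ``valid=False`` with diagnostics, never silently patched.
    """
    s = np.asarray(signals, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if s.shape != b.shape:
        raise ValueError("signals and b_values must have equal length")
    if not free_adc:
        if adc_fixed is None or not np.isfinite(adc_fixed) or adc_fixed <= 0:
            raise ValueError("segmented fit needs a positive adc_fixed from fit_adc")

    s0_init = float(np.max(s))
    adc_init = adc_fixed if not free_adc else max(fit_adc(s, b).adc, 1e-5)
    # extrapolate the tissue compartment to b=0: its intercept underestimates
    # the full signal by the perfusion fraction
    high = fit_adc(s, b)
    if high.valid and s0_init > 0:
        f_init = float(np.clip(1.0 - high.S0 / s0_init, 0.01, 0.5))
    else:
        f_init = 0.1
    dstar_init = float(np.clip(10.0 * adc_init, 1.05 * adc_init, dstar_max))

    if free_adc:
        x0 = np.array([s0_init, f_init, dstar_init, adc_init])
        lower = [1e-12, 0.0, 1e-6, 1e-8]
        upper = [np.inf, 1.0, dstar_max, dstar_max]

        def resid(x):
            return _ivim_model(b, x[0], x[1], x[2], x[3]) - s

    else:
        x0 = np.array([s0_init, f_init, dstar_init])
        lower = [1e-12, 0.0, adc_fixed * (1.0 + 1e-9)]
        upper = [np.inf, 1.0, dstar_max]

        def resid(x):
            return _ivim_model(b, x[0], x[1], x[2], adc_fixed) - s

    x0 = np.clip(x0, lower, upper)
    res = optimize.least_squares(
        resid, x0, bounds=(lower, upper), xtol=1e-15, ftol=1e-15, gtol=1e-15,
        max_nfev=2000,
    )
    adc_out = res.x[3] if free_adc else float(adc_fixed)
    return IVIMParams(
        S0=float(res.x[0]),
        adc=float(adc_out),
        f=float(res.x[1]),
        dstar=float(res.x[2]),
        residual_norm=float(np.linalg.norm(res.fun)),
        n_iterations=int(res.nfev),
        valid=bool(res.success),
        message=res.message,
    )


def fit_ivim_segmented(
    signals,
    b_values,
    b_threshold: float = 200.0,
    n_refine: int = 1,
    dstar_max: float = 0.1,
) -> IVIMParams:
    """The standard two-step diffusion-perfusion pipeline.

    Step 1 fits the tissue ADC on b > ``b_threshold``; step 2 fits
    (S0, f, D*) over all b with the ADC held fixed.  Because the capillary
    compartment has not fully decayed at the cutoff, the high-b ADC carries
    a small upward contamination bias; each refinement pass therefore
    subtracts the fitted perfusion compartment from the signal, refits the
    ADC on the corrected signal over the full b range, and repeats step 2.
    One pass (the default) reduces the noiseless f bias several-fold at
    essentially unchanged noise sensitivity.
    """
    s = np.asarray(signals, dtype=float)
    b = np.asarray(b_values, dtype=float)
    step = fit_adc(s, b, b_threshold=b_threshold)
    if not step.valid:
        return IVIMParams(
            float("nan"), float("nan"), float("nan"), float("nan"),
            float("nan"), 0, False, "high-b ADC fit failed",
        )
    fit = fit_ivim(s, b, adc_fixed=step.adc, dstar_max=dstar_max)
    for _ in range(n_refine):
        if not fit.valid:
            break
        corrected = s - fit.S0 * fit.f * np.exp(-b * fit.dstar)
        refit = fit_adc(corrected, b, b_threshold=-np.inf)
        if not refit.valid or refit.adc <= 0:
            break
        fit = fit_ivim(s, b, adc_fixed=refit.adc, dstar_max=dstar_max)
    return fit


# ---------------------------------------------------------------------------
# relaxometry
# ---------------------------------------------------------------------------

def fit_r2star(echo_signals, tes) -> tuple[float, float]:
    """Mono-exponential decay over echo time: returns (R2* per ms, S0).

    Non-positive echoes are dropped; fewer than two usable echoes yield NaN.
    """
    s = np.asarray(echo_signals, dtype=float)
    te = np.asarray(tes, dtype=float)
    keep = s > 0
    if keep.sum() < 2:
        return float("nan"), float("nan")
    slope, intercept = np.polyfit(te[keep], np.log(s[keep]), 1)
    return float(-slope), float(np.exp(intercept))


def fit_r2star_series(signals, tes) -> np.ndarray:
    """Vectorized R2* (1/ms) per time point for a (n_frames, n_echoes) stack."""
    s = np.asarray(signals, dtype=float)
    te = np.asarray(tes, dtype=float)
    if s.ndim != 2 or s.shape[1] != len(te):
        raise ValueError("signals must be (n_frames, n_echoes)")
    out = np.full(s.shape[0], np.nan)
    ok = np.all(s > 0, axis=1)
    if ok.any():
        logs = np.log(s[ok])
        A = np.vstack([te, np.ones_like(te)]).T
        coef, *_ = np.linalg.lstsq(A, logs.T, rcond=None)
        out[ok] = -coef[0]
    # rows with non-positive echoes: fall back to the per-row masked fit
    for i in np.flatnonzero(~ok):
        out[i] = fit_r2star(s[i], te)[0]
    return out


def delta_r2star_series(
    r2star_t: np.ndarray, baseline_window: tuple[int, int]
) -> np.ndarray:
    """Bolus-induced dR2*(t): R2*(t) minus the pre-bolus baseline median."""
    r2 = np.asarray(r2star_t, dtype=float)
    i0, i1 = baseline_window
    base = np.nanmedian(r2[i0:i1])
    return r2 - base


# ---------------------------------------------------------------------------
# gamma-variate perfusion
# ---------------------------------------------------------------------------

@dataclass
class DSCFit:
    """Gamma-variate bolus fit and the derived perfusion indices.

    CBV is the area under the fitted curve (closed form), MTT its first
    moment relative to t0, and CBF = CBV/MTT; the identity CBF*MTT = CBV is
    definitional.  Units are relative (no arterial input function).
    """

    K: float
    alpha: float
    beta: float       # s
    t0: float         # s
    cbv: float
    mtt: float        # s
    cbf: float
    residual_norm: float = float("nan")
    valid: bool = True
    message: str = ""


def _gamma_model(t, K, alpha, beta, t0):
    dtv = np.maximum(t - t0, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            dtv > 0,
            np.exp(np.log(K) + alpha * np.log(np.where(dtv > 0, dtv, 1.0)) - dtv / beta),
            0.0,
        )
    return out


def gamma_closed_forms(K: float, alpha: float, beta: float) -> tuple[float, float, float]:
    """(CBV, MTT, CBF) closed forms for a gamma-variate bolus curve."""
    cbv = float(K * np.exp((alpha + 1) * np.log(beta) + gammaln(alpha + 1)))
    mtt = float(beta * (alpha + 1))
    return cbv, mtt, cbv / mtt


def fit_gamma_variate(
    delta_r2star_t,
    times,
    peak_min_fraction: float = 0.05,
) -> DSCFit:
    """Fit the bolus curve dR2*(t) = K*(t-t0)^alpha*exp(-(t-t0)/beta).

    Initialization log-linearizes the curve around the detected peak; the
    four parameters are then refined by bounded least squares.  A flat curve
    (no detectable peak) or non-convergence returns ``valid=False`` with
    diagnostics.
    """
    y = np.asarray(delta_r2star_t, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.shape != t.shape:
        raise ValueError("curve and times must have equal length")
    finite = np.isfinite(y)
    y = np.where(finite, y, 0.0)

    ipeak = int(np.argmax(y))
    ymax = y[ipeak]
    if not np.isfinite(ymax) or ymax <= 0 or ipeak == 0:
        return DSCFit(*[float("nan")] * 7, valid=False, message="no bolus peak found")
    tpeak = t[ipeak]

    # arrival estimate: last pre-peak sample below a small fraction of the peak
    below = np.flatnonzero(y[:ipeak] < peak_min_fraction * ymax)
    t0_init = t[below[-1]] if len(below) else t[0]
    # log-linearize ln y = ln K + alpha*ln(dt) - dt/beta on the rising+falling lobe
    use = (t > t0_init) & (y > peak_min_fraction * ymax)
    if use.sum() >= 3:
        dtv = t[use] - t0_init
        A = np.vstack([np.log(dtv), -dtv, np.ones_like(dtv)]).T
        coef, *_ = np.linalg.lstsq(A, np.log(y[use]), rcond=None)
        alpha_init = float(np.clip(coef[0], 0.05, 50.0))
        beta_init = float(np.clip(1.0 / max(coef[1], 1e-6), 1e-3, 1e4))
        K_init = float(np.exp(np.clip(coef[2], -500, 500)))
    else:
        alpha_init, beta_init = 2.0, max((tpeak - t0_init) / 2.0, 1e-3)
        K_init = ymax / _gamma_model(np.array([tpeak]), 1.0, alpha_init, beta_init, t0_init)[0]

    x0 = np.array([K_init, alpha_init, beta_init, t0_init])
    lower = [1e-30, 1e-3, 1e-6, t[0] - (t[1] - t[0])]
    upper = [np.inf, 100.0, 1e6, tpeak]
    x0 = np.clip(x0, lower, upper)

    def resid(x):
        return _gamma_model(t, *x) - y

    res = optimize.least_squares(
        resid, x0, bounds=(lower, upper), xtol=1e-15, ftol=1e-15, gtol=1e-15,
        max_nfev=5000,
    )
    K, alpha, beta, t0 = (float(v) for v in res.x)
    cbv, mtt, cbf = gamma_closed_forms(K, alpha, beta)
    return DSCFit(
        K=K, alpha=alpha, beta=beta, t0=t0, cbv=cbv, mtt=mtt, cbf=cbf,
        residual_norm=float(np.linalg.norm(res.fun)),
        valid=bool(res.success),
        message=res.message,
    )


# ---------------------------------------------------------------------------
# voxelwise morphometry statistics
# ---------------------------------------------------------------------------

@dataclass
class VoxelStatsMap:
    """Per-voxel group-comparison maps.

    ``z`` carries the sign of the group-A-minus-group-B effect (negative =
    volume reduction in group A); ``significant`` marks voxels with
    z below ``z_threshold``.
    """

    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    z: np.ndarray
    significant: np.ndarray
    mask: np.ndarray
    z_threshold: float
    meta: dict = field(default_factory=dict)


def _smooth(volume: np.ndarray, sigma_vox: float, mask: np.ndarray) -> np.ndarray:
    """Gaussian smoothing with kernel renormalization at the mask boundary."""
    if sigma_vox <= 0:
        return volume
    v = np.where(mask, volume, 0.0)
    num = ndi.gaussian_filter(v, sigma_vox, mode="constant")
    den = ndi.gaussian_filter(mask.astype(float), sigma_vox, mode="constant")
    out = np.zeros_like(volume, dtype=float)
    np.divide(num, den, out=out, where=den > 1e-12)
    return out


def voxelwise_jacobian_stats(
    group_a,
    group_b,
    fwhm_mm: float = 0.1,
    voxel_mm: float = 0.1,
    mask: np.ndarray | None = None,
    z_threshold: float = -2.57,
    truncate_z: bool = False,
) -> VoxelStatsMap:
    """Voxelwise two-sample comparison of volume-change maps.

    Each map is Gaussian-smoothed at the stated FWHM (sigma =
    FWHM/sqrt(8 ln 2), renormalized at boundaries), a per-voxel Student
    t-test compares the groups, two-sided p-values are Benjamini-Hochberg
    adjusted across in-mask voxels, and signed z-scores are the two-sided
    normal quantile of q carrying the sign of the effect.  Negative z marks
    volume reduction in group A; ``significant`` applies ``z_threshold``.
    """
    a = np.asarray(group_a, dtype=float)
    bmaps = np.asarray(group_b, dtype=float)
    if a.ndim < 2 or bmaps.ndim < 2 or a.shape[1:] != bmaps.shape[1:]:
        raise ValueError("group maps must share one voxel grid")
    if a.shape[0] < 2 or bmaps.shape[0] < 2:
        raise ValueError("need at least 2 maps per group")
    grid = a.shape[1:]
    mask = np.ones(grid, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if mask.shape != grid:
        raise ValueError("mask grid mismatch")

    sigma_vox = (fwhm_mm * FWHM_TO_SIGMA) / voxel_mm
    a_s = np.stack([_smooth(m, sigma_vox, mask) for m in a])
    b_s = np.stack([_smooth(m, sigma_vox, mask) for m in bmaps])

    tstat, pval = stats.ttest_ind(a_s, b_s, axis=0, equal_var=True)
    tstat = np.asarray(tstat, dtype=float)
    pval = np.asarray(pval, dtype=float)
    pval = np.where(np.isfinite(pval), pval, 1.0)
    tstat = np.where(np.isfinite(tstat), tstat, 0.0)

    q = np.full(grid, np.nan)
    flat_p = pval[mask]
    if flat_p.size:
        q[mask] = multipletests(flat_p, method="fdr_bh")[1]

    z = np.full(grid, np.nan)
    qm = np.clip(q[mask], 1e-300, 1.0)
    zmag = np.abs(stats.norm.ppf(qm / 2.0))
    if truncate_z:
        zmag = np.trunc(zmag * 100.0) / 100.0
    z[mask] = np.sign(tstat[mask]) * zmag

    significant = np.zeros(grid, dtype=bool)
    significant[mask] = z[mask] < z_threshold
    return VoxelStatsMap(
        t=tstat,
        p=pval,
        q=q,
        z=z,
        significant=significant,
        mask=mask,
        z_threshold=z_threshold,
        meta={"fwhm_mm": fwhm_mm, "voxel_mm": voxel_mm, "sigma_vox": sigma_vox},
    )


def z_for_fdr(q_two_sided: float, truncate: bool = False) -> float:
    """z magnitude whose two-sided tail probability equals q.

    With ``truncate=True`` the value is cut (not rounded) to two decimals,
    matching the display convention under which a 1% false discovery rate
    corresponds to |z| = 2.57.
    """
    if not 0 < q_two_sided < 1:
        raise ValueError("q must lie strictly between 0 and 1")
    z = float(abs(stats.norm.ppf(q_two_sided / 2.0)))
    if truncate:
        z = math.trunc(z * 100.0) / 100.0
    return z


@dataclass
class RoiVolume:
    volume_mm3: float
    n_voxels: int
    empty: bool


def roi_volume(label_mask, voxel_mm) -> RoiVolume:
    """Region volume = voxel count x voxel volume (``voxel_mm`` scalar or per-axis)."""
    mask = np.asarray(label_mask, dtype=bool)
    vs = np.atleast_1d(np.asarray(voxel_mm, dtype=float))
    if np.any(vs <= 0):
        raise ValueError("voxel size must be positive")
    voxel_volume = float(np.prod(vs)) if vs.size > 1 else float(vs[0] ** mask.ndim)
    n = int(mask.sum())
    return RoiVolume(n * voxel_volume, n, n == 0)


def frame_rate_radial(tr_ms: float, spokes_per_image: int) -> float:
    """Temporal resolution of a radial acquisition: 1/(TR * spokes) in frames/s."""
    if tr_ms <= 0 or spokes_per_image <= 0:
        raise ValueError("TR and spoke count must be positive")
    return 1.0 / (tr_ms / 1000.0 * spokes_per_image)
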