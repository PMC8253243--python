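"""Synthetic MRI signals: bi-exponential diffusion decay, gamma-variate
bolus passage under multi-echo mono-exponential decay, and group-structured
volume-change (Jacobian-determinant) maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_B_VALUES",
    "DEFAULT_TES_MS",
    "ivim_signal",
    "gen_ivim_signals",
    "DSCSeries",
    "gen_dsc_series",
    "gen_jacobian_maps",
]

# diffusion-weighting grid of the acquisition protocol (s/mm^2); 7 values
# exceed the 200 s/mm^2 cutoff used for the tissue-diffusion fit
DEFAULT_B_VALUES = np.array(
    [10, 20, 30, 40, 50, 60, 70, 80, 110, 140, 170, 200,
     300, 400, 500, 600, 700, 800, 900],
    dtype=float,
)

# echo times of the multi-echo dynamic acquisition (ms)
DEFAULT_TES_MS = np.array([1.0, 2.15, 3.3])


def ivim_signal(b, S0: float, f: float, Dstar: float, ADC: float) -> np.ndarray:
    """Bi-exponential intravoxel-incoherent-motion decay.

    S(b) = S0 * [f * exp(-b*Dstar) + (1-f) * exp(-b*ADC)], separating
    capillary pseudo-diffusion (perfusion fraction f, pseudo-diffusion
    coefficient Dstar) from tissue diffusion (ADC), all in mm^2/s.
    """
    b = np.asarray(b, dtype=float)
    return S0 * (f * np.exp(-b * Dstar) + (1.0 - f) * np.exp(-b * ADC))


def gen_ivim_signals(
    S0: float,
    f: float,
    Dstar: float,
    ADC: float,
    b_values=None,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy diffusion signal replicates on a b-value grid.

    Returns ``(b_values, signals)`` with signals shaped
    (n_replicates, n_b).  Defaults to the 19-value acquisition grid.
    """
    if S0 <= 0:
        raise ValueError("S0 must be positive")
    if not 0 <= f <= 1:
        raise ValueError("perfusion fraction f must lie in [0, 1]")
    if not (Dstar > ADC > 0):
        raise ValueError("need Dstar > ADC > 0")
    b = np.asarray(b_values, dtype=float) if b_values is not None else DEFAULT_B_VALUES.copy()
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    clean = ivim_signal(b, S0, f, Dstar, ADC)
    signals = np.tile(clean, (n_replicates, 1))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signals = signals + rng.normal(0.0, noise_sd, size=signals.shape)
    return b, signals


@dataclass
class DSCSeries:
    """Multi-echo dynamic series with its injected truth channel."""

    times: np.ndarray            # s, frame times
    tes: np.ndarray              # ms
    signals: np.ndarray          # (n_frames, n_echoes)
    s0: float
    r2star_baseline: float       # 1/ms
    true_delta_r2star: np.ndarray  # 1/ms, the injected bolus curve
    params: dict                 # K, alpha, beta, t0 of the injected curve


def gamma_variate(t, K: float, alpha: float, beta: float, t0: float) -> np.ndarray:
    """Canonical bolus shape K*(t-t0)^alpha * exp(-(t-t0)/beta), 0 before t0."""
    t = np.asarray(t, dtype=float)
    dtv = t - t0
    out = np.zeros_like(dtv)
    pos = dtv > 0
    out[pos] = K * dtv[pos] ** alpha * np.exp(-dtv[pos] / beta)
    return out


def gen_dsc_series(
    R2star_baseline: float,
    K: float,
    alpha: float,
    beta: float,
    t0: float,
    TEs=None,
    frame_rate: float = 0.55,
    n_frames: int = 300,
    noise_sd: float = 0.0,
    seed: int = 0,
    S0: float = 100.0,
) -> DSCSeries:
    """Bolus-passage echo signals S(TE, t) = S0*exp(-TE*(R2*_base + dR2*(t))).

    dR2*(t) follows a gamma variate starting at ``t0`` (seconds); R2* values
    are per millisecond against the millisecond echo times.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    tes = np.asarray(TEs, dtype=float) if TEs is not None else DEFAULT_TES_MS.copy()
    if np.any(np.diff(tes) <= 0):
        raise ValueError("TEs must be strictly increasing")
    times = np.arange(n_frames) / frame_rate
    if not times[0] <= t0 <= times[-1]:
        raise ValueError("t0 must lie within the series")
    delta = gamma_variate(times, K, alpha, beta, t0)
    r2 = R2star_baseline + delta                    # 1/ms
    signals = S0 * np.exp(-np.outer(r2, tes))       # (n_frames, n_echoes)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signals = signals + rng.normal(0.0, noise_sd, size=signals.shape)
    return DSCSeries(
        times=times,
        tes=tes,
        signals=signals,
        s0=S0,
        r2star_baseline=R2star_baseline,
        true_delta_r2star=delta,
        params={"K": K, "alpha": alpha, "beta": beta, "t0": t0},
    )


def gen_jacobian_maps(
    shape: tuple[int, int, int] = (16, 16, 16),
    n_a: int = 8,
    n_b: int = 8,
    effect: float = 0.0,
    effect_mask: np.ndarray | None = None,
    sd: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two groups of volume-change maps with a planted effect region.

    Maps are Jacobian determinants around 1 (no volume change) with voxel
    noise ``sd``; group A additionally carries ``effect`` (e.g. a negative
    shift for atrophy) inside ``effect_mask`` (default: the central cube of
    half the grid extent).  Returns (groupA, groupB, effect_mask).
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 maps per group")
    rng = np.random.default_rng(seed)
    if effect_mask is None:
        effect_mask = np.zeros(shape, dtype=bool)
        sl = tuple(slice(s // 4, 3 * s // 4) for s in shape)
        effect_mask[sl] = True
    group_a = 1.0 + rng.normal(0.0, sd, size=(n_a, *shape))
    group_b = 1.0 + rng.normal(0.0, sd, size=(n_b, *shape))
    group_a[:, effect_mask] += effect
    return group_a, group_b, effect_mask.astype(bool)
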