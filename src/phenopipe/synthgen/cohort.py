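"""Synthetic cohort-level measurement tables (group effects, startle data)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SyntheticCohortConfig", "gen_cohort", "gen_startle_table"]


@dataclass
class SyntheticCohortConfig:
    """Two-group (or more) cohort with per-group effect distributions.

    ``family`` selects the sampling distribution: ``normal`` draws
    N(mean, sd); ``lognormal`` draws exp(N(mu, sigma)) with mu/sigma chosen
    so the samples have the requested mean and sd.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"control": 10, "dta": 10}
    )
    group_means: dict[str, float] = field(
        default_factory=lambda: {"control": 1.0, "dta": 1.0}
    )
    group_sds: dict[str, float] = field(
        default_factory=lambda: {"control": 0.2, "dta": 0.2}
    )
    family: str = "normal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("normal", "lognormal"):
            raise ValueError("family must be 'normal' or 'lognormal'")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError("group sizes must be at least 2")
            if self.group_sds.get(g, 1.0) <= 0:
                raise ValueError("group SDs must be positive")


def gen_cohort(cfg: SyntheticCohortConfig) -> pd.DataFrame:
    """Tidy table (group, value) with the configured group effects."""
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for group, n in cfg.group_sizes.items():
        mean = cfg.group_means[group]
        sd = cfg.group_sds[group]
        if cfg.family == "normal":
            vals = rng.normal(mean, sd, size=n)
        else:
            sigma2 = np.log1p((sd / mean) ** 2)
            mu = np.log(mean) - sigma2 / 2
            vals = rng.lognormal(mu, np.sqrt(sigma2), size=n)
        rows.append(pd.DataFrame({"group": group, "value": vals}))
    return pd.concat(rows, ignore_index=True)


def gen_startle_table(
    n_animals: int = 10,
    pulse_mean: float = 100.0,
    inhibition: dict[int, float] | None = None,
    trial_sd: float = 10.0,
    n_trials: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-trial startle amplitudes for a prepulse-inhibition session.

    ``inhibition`` maps prepulse intensity (dB) to the fractional reduction
    of the startle response (0.4 means the prepulse-preceded startle runs at
    60% of the pulse-only amplitude).  Columns: animal, intensity, amplitude;
    the 120 dB rows are the pulse-only trials.
    """
    inhibition = inhibition if inhibition is not None else {70: 0.2, 75: 0.35, 80: 0.5}
    rng = np.random.default_rng(seed)
    rows = []
    for animal in range(1, n_animals + 1):
        base = max(rng.normal(pulse_mean, pulse_mean / 10), 1.0)
        for intensity, inh in list(inhibition.items()) + [(120, 0.0)]:
            amps = rng.normal(base * (1 - inh), trial_sd, size=n_trials)
            amps = np.clip(amps, 0.0, None)
            for a in amps:
                rows.append(
                    {"animal": animal, "intensity": intensity, "amplitude": a}
                )
    return pd.DataFrame(rows)
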