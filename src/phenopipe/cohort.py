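"""Cohort-level readouts: prepulse inhibition, distribution-driven test
selection, blood-brain-barrier assay quantification, flow-cytometry gating
with counting-bead correction, and fold-change normalization."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "percent_ppi",
    "process_startle_table",
    "StartleRecord",
    "choose_two_sample_test",
    "TwoSampleResult",
    "water_content",
    "tracer_concentration",
    "TracerResult",
    "gate_cells",
    "GateResult",
    "bead_correct",
    "fold_change_to_control",
    "DEFAULT_THRESHOLDS",
]

PULSE_ONLY_DB = 120
PREPULSE_DB = (70, 75, 80)


# ---------------------------------------------------------------------------
# prepulse inhibition
# ---------------------------------------------------------------------------

def percent_ppi(startle_prepulse, startle_pulse_only):
    """%PPI = 100 - (startle after prepulse / startle after pulse only) x 100.

    Accepts scalars or arrays; the pulse-only amplitude must be positive.
    A prepulse response exceeding the pulse-only response yields a negative
    value (a non-performing animal by the exclusion rule).
    """
    pulse = np.asarray(startle_pulse_only, dtype=float)
    if np.any(pulse <= 0):
        raise ValueError("pulse-only startle amplitude must be positive")
    pre = np.asarray(startle_prepulse, dtype=float)
    out = 100.0 - (pre / pulse) * 100.0
    return float(out) if out.ndim == 0 else out


@dataclass
class StartleRecord:
    """Per-animal prepulse-inhibition outcome.

    Amplitudes are first averaged within each intensity, then the %PPI
    formula is applied per prepulse intensity.  Animals with any negative
    %PPI (non-performers) carry ``excluded=True``; a non-positive pulse-only
    response makes the record invalid.
    """

    animal: object
    mean_amplitudes: dict[int, float]
    ppi: dict[int, float]
    excluded: bool
    valid: bool


def process_startle_table(
    table: pd.DataFrame,
    pulse_intensity: int = PULSE_ONLY_DB,
) -> list[StartleRecord]:
    """Per-animal %PPI from a tidy trial table (animal, intensity, amplitude)."""
    required = {"animal", "intensity", "amplitude"}
    if not required.issubset(table.columns):
        raise ValueError(f"startle table needs columns {sorted(required)}")
    records = []
    for animal, grp in table.groupby("animal", sort=True):
        means = grp.groupby("intensity")["amplitude"].mean().to_dict()
        pulse = means.get(pulse_intensity)
        if pulse is None or pulse <= 0:
            records.append(StartleRecord(animal, means, {}, False, False))
            continue
        ppi = {
            int(i): percent_ppi(m, pulse)
            for i, m in means.items()
            if i != pulse_intensity
        }
        excluded = any(v < 0 for v in ppi.values())
        records.append(StartleRecord(animal, means, ppi, excluded, True))
    return records


# ---------------------------------------------------------------------------
# two-sample test selection
# ---------------------------------------------------------------------------

@dataclass
class TwoSampleResult:
    test_name: str      # "welch_t" or "mann_whitney_u"
    statistic: float
    p: float
    shapiro_p: tuple[float, float]
    note: str = ""


def choose_two_sample_test(group_a, group_b, alpha: float = 0.05) -> TwoSampleResult:
    """Normality-driven choice between Welch's t and the Mann-Whitney U test.

    Shapiro-Wilk is run on each group at the given alpha; only when both
    groups look normal (both p >= alpha) is the two-sided Welch t-test used,
    otherwise the two-sided Mann-Whitney U test.  The decision is a pure
    function of the two samples, recorded in the result.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per group")
    sw = []
    for g in (a, b):
        if np.ptp(g) == 0:
            sw.append(0.0)  # a constant sample is not plausibly normal
        else:
            sw.append(float(stats.shapiro(g).pvalue))
    note = ""
    if sw[0] >= alpha and sw[1] >= alpha:
        res = stats.ttest_ind(a, b, equal_var=False)
        name = "welch_t"
    else:
        name = "mann_whitney_u"
        if np.ptp(np.concatenate([a, b])) == 0:
            # all observations tied: U is its midpoint and the data carry
            # no ordering information
            return TwoSampleResult(
                name, len(a) * len(b) / 2.0, 1.0, (sw[0], sw[1]),
                note="degenerate: all values tied; p set to 1",
            )
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        if len(np.unique(np.concatenate([a, b]))) < len(a) + len(b):
            note = "ties present; normal approximation with tie correction"
    return TwoSampleResult(name, float(res.statistic), float(res.pvalue), (sw[0], sw[1]), note)


# ---------------------------------------------------------------------------
# blood-brain-barrier assays
# ---------------------------------------------------------------------------

def water_content(wet_g: float, dry_g: float) -> float:
    """Brain water content, percent: 100 * (wet - dry) / wet."""
    wet = np.asarray(wet_g, dtype=float)
    dry = np.asarray(dry_g, dtype=float)
    if np.any(dry <= 0) or np.any(wet <= 0):
        raise ValueError("masses must be positive")
    if np.any(dry > wet):
        raise ValueError("dry mass cannot exceed wet mass")
    out = 100.0 * (wet - dry) / wet
    return float(out) if out.ndim == 0 else out


@dataclass
class TracerResult:
    concentration: np.ndarray | float
    normalized: np.ndarray | float
    extrapolated: np.ndarray | bool


def tracer_concentration(
    fluorescence,
    standard_curve_points,
    control_mean: float | None = None,
) -> TracerResult:
    """Tracer concentration via a fluorescence standard curve.

    ``standard_curve_points`` is a sequence of (fluorescence, concentration)
    pairs; two points define the line exactly, more are fitted by least
    squares.  2-D input (samples x replicate measurements, e.g. triplicates)
    is averaged per sample first.  Readings outside the standard range are
    flagged as extrapolated.  With ``control_mean`` the concentrations are
    additionally normalized so the control group averages 1.
    """
    pts = np.asarray(standard_curve_points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("standard curve needs >= 2 (fluorescence, concentration) points")
    order = np.argsort(pts[:, 0])
    fl, conc = pts[order, 0], pts[order, 1]
    d = np.diff(conc)
    if not (np.all(d >= 0) or np.all(d <= 0)):
        raise ValueError("standard curve must be monotone")
    slope, intercept = np.polyfit(fl, conc, 1)

    x = np.asarray(fluorescence, dtype=float)
    scalar = x.ndim == 0
    if x.ndim == 2:
        x = x.mean(axis=1)  # replicate averaging
    c = slope * x + intercept
    extrap = (x < fl.min()) | (x > fl.max())
    norm = c / control_mean if control_mean is not None else c
    if control_mean is not None and control_mean <= 0:
        raise ValueError("control mean must be positive")
    if scalar:
        return TracerResult(float(c), float(norm), bool(extrap))
    return TracerResult(c, norm, extrap)


# ---------------------------------------------------------------------------
# flow-cytometry gating
# ---------------------------------------------------------------------------

# per-marker intensity cutoffs; markers with a "high" entry are banded into
# negative / low / high, others are boolean negative / positive
DEFAULT_THRESHOLDS: dict[str, dict[str, float]] = {
    "CD4": {"pos": 1.0},
    "CD8": {"pos": 1.0},
    "B220": {"pos": 1.0},
    "CD11b": {"pos": 1.0, "high": 3.0},
    "CD45": {"pos": 1.0, "high": 3.0},
    "CD19": {"pos": 1.0},
    "CD138": {"pos": 1.0},
}

BLOOD_PANEL_MARKERS = ("CD4", "CD8", "B220", "CD11b")
BRAIN_PANEL_MARKERS = ("CD45", "CD11b", "CD4", "CD8", "CD19", "CD138")


@dataclass
class GateResult:
    """Boolean-gating outcome for one sample.

    ``counts`` are mutually exclusive class counts within the parent gate
    (lymphocytes for blood, single cells for brain); events matching no
    class land in ``counts["ungated"]``, never silently dropped.
    ``frequencies`` are percentages of the parent gate.  For the brain panel
    the T/B/plasma sub-gates are also reported inside ``subgates`` with
    their parent (leukocyte) counts.
    """

    panel: str
    n_parent: int
    counts: dict[str, int]
    frequencies: dict[str, float]
    subgates: dict[str, int] = field(default_factory=dict)
    labels: pd.Series | None = None


def _level(values: np.ndarray, thr: dict[str, float]) -> np.ndarray:
    """Map intensities to 'neg' / 'pos' or 'neg' / 'low' / 'high' codes."""
    if "high" in thr:
        out = np.full(values.shape, "neg", dtype=object)
        out[(values >= thr["pos"]) & (values < thr["high"])] = "low"
        out[values >= thr["high"]] = "high"
        return out
    return np.where(values >= thr["pos"], "pos", "neg")


def gate_cells(
    events: pd.DataFrame,
    panel: str,
    thresholds: dict[str, dict[str, float]] | None = None,
) -> GateResult:
    """Classify events by boolean marker gates.

    Blood panel (within the scatter-defined lymphocyte gate): T-helper
    CD4+CD8-, cytotoxic T CD8+CD4-, B cells B220+CD11b-CD8-CD4-, myeloid
    CD11b+B220-CD8-CD4-; frequencies as percent of lymphocytes.  Brain
    panel (within the single-cell gate): leukocytes CD45-high CD11b-,
    microglia CD45-low CD11b-high, macrophages CD45-high CD11b-high; CD4+
    and CD8+ T cells within the leukocyte gate; CD19+ B cells and CD138+
    plasma cells within the CD4-CD8- leukocyte gate.
    """
    thresholds = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    if panel == "blood":
        markers, pregate = BLOOD_PANEL_MARKERS, "is_lymphocyte"
    elif panel == "brain":
        markers, pregate = BRAIN_PANEL_MARKERS, "is_single_cell"
    else:
        raise ValueError(f"unknown panel {panel!r}; expected 'blood' or 'brain'")
    missing = [m for m in markers if m not in events.columns]
    if missing:
        raise ValueError(f"event table lacks marker column(s) {missing}")

    if pregate in events.columns:
        ev = events[events[pregate].astype(bool)]
    else:
        ev = events
    n_parent = len(ev)
    lv = {m: _level(ev[m].to_numpy(dtype=float), thresholds[m]) for m in markers}

    labels = np.full(n_parent, "ungated", dtype=object)
    subgates: dict[str, int] = {}

    if panel == "blood":
        neg = {m: lv[m] == "neg" for m in markers}
        pos = {m: lv[m] != "neg" for m in markers}
        classes = {
            "t_helper": pos["CD4"] & neg["CD8"],
            "t_cytotoxic": pos["CD8"] & neg["CD4"],
            "b_cell": pos["B220"] & neg["CD11b"] & neg["CD8"] & neg["CD4"],
            "myeloid": pos["CD11b"] & neg["B220"] & neg["CD8"] & neg["CD4"],
        }
        # T-cell gates take precedence; remaining definitions are disjoint
        for name, sel in classes.items():
            labels[sel & (labels == "ungated")] = name
        class_names = list(classes)
    else:
        cd45, cd11b = lv["CD45"], lv["CD11b"]
        leuko = (cd45 == "high") & (cd11b == "neg")
        classes = {
            "microglia": (cd45 == "low") & (cd11b == "high"),
            "macrophage": (cd45 == "high") & (cd11b == "high"),
            "leukocyte": leuko,
        }
        for name, sel in classes.items():
            labels[sel & (labels == "ungated")] = name
        class_names = list(classes)

        pos = {m: lv[m] != "neg" for m in ("CD4", "CD8", "CD19", "CD138")}
        neg = {m: ~pos[m] for m in pos}
        dn = leuko & neg["CD4"] & neg["CD8"]  # double-negative leukocytes
        subgates = {
            "cd4_t": int((leuko & pos["CD4"] & neg["CD8"]).sum()),
            "cd8_t": int((leuko & pos["CD8"] & neg["CD4"]).sum()),
            "b_cell": int((dn & pos["CD19"]).sum()),
            "plasma_cell": int((dn & pos["CD138"] & neg["CD19"]).sum()),
            "leukocyte_parent": int(leuko.sum()),
            "dn_leukocyte_parent": int(dn.sum()),
        }

    counts = {name: int((labels == name).sum()) for name in class_names}
    counts["ungated"] = int((labels == "ungated").sum())
    freqs = {
        name: (100.0 * c / n_parent if n_parent else 0.0)
        for name, c in counts.items()
    }
    return GateResult(
        panel=panel,
        n_parent=n_parent,
        counts=counts,
        frequencies=freqs,
        subgates=subgates,
        labels=pd.Series(labels, index=ev.index, name="gate_label"),
    )


def bead_correct(count: float, beads_recorded: float, beads_added: float) -> float:
    """Absolute count from counting beads: count x beads_added / beads_recorded."""
    if beads_recorded <= 0:
        raise ValueError("recorded bead count must be positive")
    if beads_added < 0 or count < 0:
        raise ValueError("counts must be non-negative")
    return count * beads_added / beads_recorded


def fold_change_to_control(values, control_values):
    """Values divided by the control-group mean (controls average to 1)."""
    control = np.asarray(control_values, dtype=float)
    m = control.mean()
    if not np.isfinite(m) or m <= 0:
        raise ValueError("control mean must be positive")
    out = np.asarray(values, dtype=float) / m
    return float(out) if out.ndim == 0 else out
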