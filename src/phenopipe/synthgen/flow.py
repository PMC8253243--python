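"""Synthetic flow-cytometry event tables with known gate membership.

Marker intensities are drawn on a compensated log-like scale with three
well-separated levels — negative ~ N(0, 0.15), low ~ N(2, 0.15) and
positive/high ~ N(4, 0.15) — against default thresholds of 1 (negative vs
positive/low) and 3 (low vs high), so that thresholding reproduces the
intended boolean class exactly (levels sit >6 SD from the nearest cutoff)
and the true label can serve as an oracle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["BLOOD_CLASSES", "BRAIN_CLASSES", "gen_flow_events", "DEFAULT_LEVELS"]

# marker level -> mean intensity
DEFAULT_LEVELS = {"neg": 0.0, "low": 2.0, "pos": 4.0, "high": 4.0}

BLOOD_MARKERS = ["CD4", "CD8", "B220", "CD11b"]
# peripheral-blood classes within the lymphocyte gate
BLOOD_CLASSES: dict[str, dict[str, str]] = {
    "t_helper": {"CD4": "pos", "CD8": "neg", "B220": "neg", "CD11b": "neg"},
    "t_cytotoxic": {"CD8": "pos", "CD4": "neg", "B220": "neg", "CD11b": "neg"},
    "b_cell": {"B220": "pos", "CD11b": "neg", "CD8": "neg", "CD4": "neg"},
    "myeloid": {"CD11b": "pos", "B220": "neg", "CD8": "neg", "CD4": "neg"},
    # double positive: matches no defined class, must land in the ungated bucket
    "ungated_double_positive": {"CD4": "pos", "CD8": "pos", "B220": "neg", "CD11b": "neg"},
}

BRAIN_MARKERS = ["CD45", "CD11b", "CD4", "CD8", "CD19", "CD138"]
# brain classes within the single-cell gate; leukocytes are CD45-high CD11b-,
# microglia CD45-low CD11b-high, macrophages CD45-high CD11b-high
BRAIN_CLASSES: dict[str, dict[str, str]] = {
    "microglia": {"CD45": "low", "CD11b": "high", "CD4": "neg", "CD8": "neg",
                  "CD19": "neg", "CD138": "neg"},
    "macrophage": {"CD45": "high", "CD11b": "high", "CD4": "neg", "CD8": "neg",
                   "CD19": "neg", "CD138": "neg"},
    "cd4_t": {"CD45": "high", "CD11b": "neg", "CD4": "pos", "CD8": "neg",
              "CD19": "neg", "CD138": "neg"},
    "cd8_t": {"CD45": "high", "CD11b": "neg", "CD8": "pos", "CD4": "neg",
              "CD19": "neg", "CD138": "neg"},
    "b_cell": {"CD45": "high", "CD11b": "neg", "CD4": "neg", "CD8": "neg",
               "CD19": "pos", "CD138": "neg"},
    "plasma_cell": {"CD45": "high", "CD11b": "neg", "CD4": "neg", "CD8": "neg",
                    "CD19": "neg", "CD138": "pos"},
    "leukocyte_other": {"CD45": "high", "CD11b": "neg", "CD4": "neg", "CD8": "neg",
                        "CD19": "neg", "CD138": "neg"},
    "ungated_negative": {"CD45": "neg", "CD11b": "neg", "CD4": "neg", "CD8": "neg",
                         "CD19": "neg", "CD138": "neg"},
}

_PANELS = {
    "blood": (BLOOD_MARKERS, BLOOD_CLASSES, "is_lymphocyte"),
    "brain": (BRAIN_MARKERS, BRAIN_CLASSES, "is_single_cell"),
}


def gen_flow_events(
    panel: str,
    class_counts: dict[str, int],
    seed: int = 0,
    intensity_sd: float = 0.15,
    levels: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Event table for a staining panel with a truth-label column.

    ``class_counts`` maps class names (keys of :data:`BLOOD_CLASSES` or
    :data:`BRAIN_CLASSES`) to event counts.  The returned frame has one row
    per event with marker intensity columns, the upstream scatter pre-gate
    as a boolean column, and ``true_label``.
    """
    if panel not in _PANELS:
        raise ValueError(f"unknown panel {panel!r}; expected 'blood' or 'brain'")
    markers, classes, pregate = _PANELS[panel]
    levels = {**DEFAULT_LEVELS, **(levels or {})}
    rng = np.random.default_rng(seed)

    rows_per_class = []
    labels = []
    for name, count in class_counts.items():
        if name not in classes:
            raise ValueError(f"unknown class {name!r} for panel {panel!r}")
        if count < 0:
            raise ValueError("class counts must be non-negative")
        if count == 0:
            continue
        spec = classes[name]
        means = np.array([levels[spec[m]] for m in markers])
        rows_per_class.append(
            means + rng.normal(0.0, intensity_sd, size=(count, len(markers)))
        )
        labels += [name] * count

    if rows_per_class:
        data = np.vstack(rows_per_class)
    else:
        data = np.empty((0, len(markers)))
    df = pd.DataFrame(data, columns=markers)
    df[pregate] = True
    df["true_label"] = labels
    return df
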