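"""Infrared-thermography segmentation and the Centralization Index.

A calibrated thermal camera above a circular arena records temperature frames
(degrees Celsius).  The warm mouse is extracted per frame by intensity
thresholding inside the arena region of interest, cleaned of noise, and kept
as the single largest connected cluster.  Shape differences then split the
whole-body mask into a central body and a thin tail; the Centralization
Index (CI, also called T ratio) is the mean body temperature divided by the
mean tail temperature and rises under stress-related peripheral
vasoconstriction (the tail cools while the core stays warm).

Temperatures are always read from the raw calibrated frame; the 0-255
normalization exists solely to build masks.  Because the CI is a ratio of
Celsius values it is not unit-invariant, so the temperature unit is recorded
in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu, threshold_triangle
from skimage.morphology import disk

__all__ = [
    "ThermalSession",
    "SegmentationConfig",
    "SplitConfig",
    "BodyTailMasks",
    "CISeries",
    "normalize_frame",
    "segment_mouse",
    "split_body_tail",
    "extract_ci_series",
    "window_stats",
    "area_fraction",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ThermalSession:
    """Calibrated temperature frame stack plus arena geometry and trial phases.

    ``frames`` has shape (n_frames, H, W) in degrees Celsius; ``arena_mask``
    marks the region where the test mouse can move (the analysis ROI);
    ``phases`` is an ordered, non-overlapping list of (name, t_start, t_end)
    in seconds.
    """

    frames: np.ndarray
    frame_rate: float
    arena_mask: np.ndarray
    phases: list[tuple[str, float, float]] = field(default_factory=list)
    unit: str = "C"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) stack")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite temperatures")
        self.arena_mask = np.asarray(self.arena_mask, dtype=bool)
        if self.arena_mask.shape != self.frames.shape[1:]:
            raise ValueError("arena_mask shape does not match frames")
        if not self.arena_mask.any():
            raise ValueError("arena_mask is empty")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        prev_end = -np.inf
        for name, t0, t1 in self.phases:
            if t1 <= t0 or t0 < prev_end:
                raise ValueError("phases must be ordered and non-overlapping")
            prev_end = t1

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class SegmentationConfig:
    """Whole-body mask extraction parameters.

    ``threshold`` selects the binarization cutoff on the 0-255 normalized
    scale: ``"triangle"`` (default; the triangle method is built for
    histograms dominated by one background mode with a small warm tail, the
    regime of a mouse occupying ~1% of the arena), ``"otsu"``, or a fixed
    number.  All statistics are computed on the normalized arena pixels
    only.  Cleanup is
    opening-by-reconstruction with a disk of ``opening_radius`` (removes
    noise specks without nibbling the animal's outline) followed by a
    minimum component-size filter; the largest surviving connected component
    becomes the whole-body mask.
    """

    threshold: str | float = "triangle"
    opening_radius: int = 1
    min_size: int = 20


@dataclass
class SplitConfig:
    """Body/tail split parameters.

    ``body_opening_radius`` must exceed the tail half-width so that a plain
    morphological opening erases the tail; default 3 px suits a 3-px-wide
    tail at the default scene scale.  The opened body is dilated back inside
    the whole mask by the same radius (reclaiming the thin boundary rim the
    opening shaves off the body outline), and residual tail fragments
    smaller than ``min_tail_size`` px are treated as rim remnants and
    returned to the body.  A temperature plausibility check (tail cooler
    than body) only flags suspicious splits, it never redraws them.
    """

    body_opening_radius: int = 3
    min_tail_size: int = 15


@dataclass
class BodyTailMasks:
    """Per-frame segmentation result.

    ``body_mask`` and ``tail_mask`` partition ``whole_mask``; ``centroid``
    is the (x, y) centre of mass of the body mask (whole mask before the
    split).  ``valid`` is False when no animal was found, ``tail_valid``
    when additionally a tail could be separated.
    """

    whole_mask: np.ndarray
    body_mask: np.ndarray | None = None
    tail_mask: np.ndarray | None = None
    centroid: tuple[float, float] | None = None
    valid: bool = True
    tail_valid: bool = False
    touches_border: bool = False
    implausible_split: bool = False


# ---------------------------------------------------------------------------
# per-frame operations
# ---------------------------------------------------------------------------

def normalize_frame(frame: np.ndarray) -> tuple[np.ndarray, bool]:
    """Affine min-max map of a frame onto [0, 255].

    Returns ``(normalized, degenerate)``; a constant frame maps to all zeros
    with ``degenerate=True``.  Used only for mask generation — temperatures
    are always taken from the raw calibrated frame.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    lo = frame.min()
    rng = frame.max() - lo
    if rng == 0:
        return np.zeros_like(frame), True
    return (frame - lo) / rng * 255.0, False


def segment_mouse(
    frame: np.ndarray,
    arena_mask: np.ndarray,
    cfg: SegmentationConfig | None = None,
) -> BodyTailMasks:
    """Whole-body mask: threshold the normalized frame inside the arena ROI,
    clean noise, keep the single largest connected pixel cluster.

    Returns ``valid=False`` (never raises) when no supra-threshold component
    survives the cleanup.
    """
    cfg = cfg or SegmentationConfig()
    arena_mask = np.asarray(arena_mask, dtype=bool)
    if not arena_mask.any():
        raise ValueError("arena_mask is empty")
    norm, degenerate = normalize_frame(frame)
    if degenerate:
        return BodyTailMasks(np.zeros_like(arena_mask), valid=False)

    if isinstance(cfg.threshold, str):
        vals = norm[arena_mask]
        if np.ptp(vals) == 0:
            return BodyTailMasks(np.zeros_like(arena_mask), valid=False)
        if cfg.threshold == "triangle":
            thr = threshold_triangle(vals)
        elif cfg.threshold == "otsu":
            thr = threshold_otsu(vals)
        else:
            raise ValueError(f"unknown threshold method {cfg.threshold!r}")
    else:
        thr = float(cfg.threshold)
    binary = (norm > thr) & arena_mask
    if not binary.any():
        return BodyTailMasks(np.zeros_like(arena_mask), valid=False)

    labels, n = ndi.label(binary)
    sizes = np.bincount(labels.ravel())
    keep = np.ones(n + 1, dtype=bool)
    keep[0] = False
    if cfg.opening_radius > 0:
        # opening by reconstruction: keep only components that survive the
        # erosion somewhere, with their full original extent (removes noise
        # specks without nibbling the animal's outline)
        seed = ndi.binary_erosion(binary, structure=disk(cfg.opening_radius))
        surviving = np.zeros(n + 1, dtype=bool)
        surviving[np.unique(labels[seed])] = True
        keep &= surviving
    keep &= sizes >= cfg.min_size
    if not keep.any():
        return BodyTailMasks(np.zeros_like(arena_mask), valid=False)
    largest = int(np.argmax(np.where(keep, sizes, 0)))
    whole = labels == largest

    border = whole & ~ndi.binary_erosion(arena_mask, structure=disk(1))
    cy, cx = ndi.center_of_mass(whole)
    return BodyTailMasks(
        whole_mask=whole,
        centroid=(float(cx), float(cy)),
        valid=True,
        touches_border=bool(border.any()),
    )


def split_body_tail(
    frame: np.ndarray,
    masks: BodyTailMasks,
    cfg: SplitConfig | None = None,
) -> BodyTailMasks:
    """Split the whole-body mask into central body and thin tail.

    The body is the largest connected component of the whole mask opened
    with a disk wider than the tail; everything else in the whole mask is
    tail.  An empty tail leaves tail-dependent outputs flagged invalid.
    """
    cfg = cfg or SplitConfig()
    if not masks.valid:
        return masks
    whole = masks.whole_mask
    # crop to the animal's bounding box (plus margin) before the opening
    obj = ndi.find_objects(whole.astype(np.int8))[0]
    r = cfg.body_opening_radius
    sl = tuple(
        slice(max(s.start - r - 1, 0), min(s.stop + r + 1, dim))
        for s, dim in zip(obj, whole.shape)
    )
    whole_crop = whole[sl]
    opened = ndi.binary_opening(whole_crop, structure=disk(r))
    if opened.any():
        labels, n = ndi.label(opened)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        body_crop = labels == int(np.argmax(sizes))
        # regrow the rim the opening shaved off the body outline, staying
        # inside the whole mask; the thin tail only loses ~r root pixels
        body_crop = ndi.binary_dilation(
            body_crop, structure=disk(1), iterations=r, mask=whole_crop
        )
        tail_crop = whole_crop & ~body_crop
        # residual shards along the body outline are rim remnants, not tail
        tlabels, tn = ndi.label(tail_crop)
        if tn:
            tsizes = np.bincount(tlabels.ravel())
            for lab in range(1, tn + 1):
                if tsizes[lab] < cfg.min_tail_size:
                    body_crop |= tlabels == lab
            tail_crop = whole_crop & ~body_crop
        body = np.zeros_like(whole)
        body[sl] = body_crop
    else:
        body = whole.copy()  # animal thinner than the opening disk: no split
    tail = whole & ~body

    frame = np.asarray(frame, dtype=float)
    tail_valid = bool(tail.any())
    implausible = False
    if tail_valid and frame[tail].mean() >= frame[body].mean():
        implausible = True  # tail should be the cooler compartment
    cy, cx = ndi.center_of_mass(body)
    return BodyTailMasks(
        whole_mask=whole,
        body_mask=body,
        tail_mask=tail,
        centroid=(float(cx), float(cy)),
        valid=True,
        tail_valid=tail_valid,
        touches_border=masks.touches_border,
        implausible_split=implausible,
    )


# ---------------------------------------------------------------------------
# series-level operations
# ---------------------------------------------------------------------------

@dataclass
class CISeries:
    """Per-frame body/tail temperatures and Centralization Index.

    ``frame`` columns: time (s), body_temp, tail_temp (unit per metadata),
    ci (dimensionless), valid.  Invalid frames carry NaN readouts.
    """

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def valid(self) -> pd.DataFrame:
        return self.frame[self.frame["valid"]]


def extract_ci_series(
    session: ThermalSession,
    seg_cfg: SegmentationConfig | None = None,
    split_cfg: SplitConfig | None = None,
) -> CISeries:
    """Run segmentation and body/tail split on every frame of a session.

    Body and tail temperatures are means of the raw calibrated values over
    the respective masks; CI = body / tail where the split succeeded.  Any
    phase with more than half its frames invalid is listed in
    ``meta["warnings"]``.
    """
    times = session.times
    rows = []
    for i in range(session.n_frames):
        frame = session.frames[i]
        masks = split_body_tail(
            frame, segment_mouse(frame, session.arena_mask, seg_cfg), split_cfg
        )
        ok = masks.valid and masks.tail_valid
        if ok:
            body_t = float(frame[masks.body_mask].mean())
            tail_t = float(frame[masks.tail_mask].mean())
            ci = body_t / tail_t if tail_t > 0 else float("nan")
            ok = tail_t > 0
        else:
            body_t = tail_t = ci = float("nan")
        rows.append(
            {
                "time": times[i],
                "body_temp": body_t,
                "tail_temp": tail_t,
                "ci": ci,
                "valid": bool(ok),
            }
        )
    df = pd.DataFrame(rows, columns=["time", "body_temp", "tail_temp", "ci", "valid"])

    warnings = []
    for name, t0, t1 in session.phases:
        in_phase = (df["time"] >= t0) & (df["time"] < t1)
        n = int(in_phase.sum())
        if n and (~df.loc[in_phase, "valid"]).sum() > 0.5 * n:
            warnings.append(f"phase {name!r}: more than 50% invalid frames")
    meta = {
        "unit": session.unit,
        "frame_rate": session.frame_rate,
        "warnings": warnings,
    }
    return CISeries(df, meta)


def window_stats(series: CISeries, t0: float, t1: float) -> tuple[float, float, int]:
    """Mean, SD and valid-frame count of CI over frames with t0 <= t < t1.

    With no valid frames the mean and SD are NaN and ``n_valid`` is 0; the
    SD of a single frame is 0 by convention.
    """
    if not t0 < t1:
        raise ValueError("need t0 < t1")
    df = series.frame
    sel = (df["time"] >= t0) & (df["time"] < t1) & df["valid"]
    ci = df.loc[sel, "ci"].to_numpy(dtype=float)
    n = len(ci)
    if n == 0:
        return float("nan"), float("nan"), 0
    sd = float(np.std(ci, ddof=1)) if n > 1 else 0.0
    return float(np.mean(ci)), sd, n


# ---------------------------------------------------------------------------
# densitometry
# ---------------------------------------------------------------------------

def area_fraction(image: np.ndarray, roi_mask: np.ndarray, threshold: float) -> float:
    """Fraction of ROI pixels at or above a uniform intensity threshold.

    The densitometric area-fraction readout used for marker-positive area
    (e.g. astroglial stain coverage) within a region of interest.
    """
    image = np.asarray(image, dtype=float)
    roi = np.asarray(roi_mask, dtype=bool)
    if roi.shape != image.shape:
        raise ValueError("roi_mask shape does not match image")
    n = int(roi.sum())
    if n == 0:
        raise ValueError("roi_mask is empty")
    return float((image[roi] >= threshold).sum()) / n
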