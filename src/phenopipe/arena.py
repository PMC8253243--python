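"""Arena geometry and trajectory analytics.

Turns tracked (t, x, y) positions into the behavioural readouts reported for
circular test arenas: zone occupancy (interaction zones in front of the five
social-recognition inserts, open-field annuli, water-maze quadrants), visit
counts and latencies, path lengths, per-day learning curves and
social-recognition discrimination metrics.

Conventions
-----------
* Coordinates are arena pixels (or cm — any consistent unit), ``x`` to the
  right, ``y`` downward (image convention).
* A sample at time ``t`` represents the interval ``[t, t + 1/rate)``; zone
  times are therefore multiples of the sample period and exhaustive disjoint
  zones partition the trial duration exactly.
* A *visit* is a maximal run of consecutive in-zone samples, after merging
  runs separated by gaps of at most ``merge_gap`` seconds, kept only if it
  lasts at least ``min_visit_duration`` seconds.  Total zone time counts all
  in-zone samples regardless of visit qualification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CircleZone",
    "AnnulusZone",
    "AnnulusSectorZone",
    "ZoneSet",
    "Trajectory",
    "OccupancyRecord",
    "RecognitionMetrics",
    "Trial",
    "zone_occupancy",
    "path_length",
    "recognition_metrics",
    "trial_schedule",
    "learning_curve",
    "probe_metrics",
    "open_field_zones",
    "quadrant_zones",
    "sociobox_zones",
]


# ---------------------------------------------------------------------------
# zone geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CircleZone:
    """Disk of radius ``r`` centred at (cx, cy)."""

    cx: float
    cy: float
    r: float

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("circle zone radius must be positive")

    def contains(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x - self.cx) ** 2 + (y - self.cy) ** 2 <= self.r**2

    def representative_point(self) -> tuple[float, float]:
        return self.cx, self.cy

    def min_radius_from(self, cx: float, cy: float) -> float:
        return math.hypot(self.cx - cx, self.cy - cy) - self.r


@dataclass(frozen=True)
class AnnulusZone:
    """Ring between radii ``r_in`` (exclusive lower bound 0 allowed) and ``r_out``."""

    cx: float
    cy: float
    r_in: float
    r_out: float

    def __post_init__(self) -> None:
        if not 0 <= self.r_in < self.r_out:
            raise ValueError("annulus requires 0 <= r_in < r_out")

    def contains(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        d2 = (x - self.cx) ** 2 + (y - self.cy) ** 2
        return (d2 >= self.r_in**2) & (d2 < self.r_out**2)

    def representative_point(self) -> tuple[float, float]:
        r = 0.5 * (self.r_in + self.r_out)
        return self.cx + r, self.cy

    def min_radius_from(self, cx: float, cy: float) -> float:
        return self.r_in - math.hypot(self.cx - cx, self.cy - cy)


@dataclass(frozen=True)
class AnnulusSectorZone:
    """Angular sector of an annulus; angles in radians, measured from +x.

    ``theta_start``/``theta_end`` wrap modulo 2*pi; a quadrant is the special
    case ``r_in = 0`` with a 90-degree span.
    """

    cx: float
    cy: float
    r_in: float
    r_out: float
    theta_start: float
    theta_end: float

    def __post_init__(self) -> None:
        if not 0 <= self.r_in < self.r_out:
            raise ValueError("sector requires 0 <= r_in < r_out")
        span = (self.theta_end - self.theta_start) % (2 * math.pi)
        if span == 0:
            raise ValueError("sector angular span must be non-zero")

    def contains(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        dx = x - self.cx
        dy = y - self.cy
        d2 = dx**2 + dy**2
        radial = (d2 >= self.r_in**2) & (d2 < self.r_out**2)
        theta = np.mod(np.arctan2(dy, dx) - self.theta_start, 2 * math.pi)
        span = (self.theta_end - self.theta_start) % (2 * math.pi)
        return radial & (theta < span)

    def representative_point(self) -> tuple[float, float]:
        span = (self.theta_end - self.theta_start) % (2 * math.pi)
        mid = self.theta_start + 0.5 * span
        r = 0.5 * (self.r_in + self.r_out) if self.r_in > 0 else 0.5 * self.r_out
        return self.cx + r * math.cos(mid), self.cy + r * math.sin(mid)

    def min_radius_from(self, cx: float, cy: float) -> float:
        # conservative: distance to the sector's inner rim, assuming the
        # reference point is the sector's own centre
        return self.r_in - math.hypot(self.cx - cx, self.cy - cy)


Zone = CircleZone | AnnulusZone | AnnulusSectorZone


@dataclass
class ZoneSet:
    """Named zones over a circular arena, with role labels.

    Roles identify a zone's function (``stimulus_1``..``stimulus_4``,
    ``stranger``, ``center``/``mid``/``periphery``, ``target_quadrant``);
    they are free-form strings keyed by zone name.
    """

    zones: dict[str, Zone]
    roles: dict[str, str] = field(default_factory=dict)
    arena_center: tuple[float, float] = (0.0, 0.0)
    arena_radius: float = 1.0

    def __post_init__(self) -> None:
        if len(self.zones) == 0:
            raise ValueError("ZoneSet needs at least one zone")
        if self.arena_radius <= 0:
            raise ValueError("arena radius must be positive")

    def membership(self, x, y) -> dict[str, np.ndarray]:
        return {name: z.contains(x, y) for name, z in self.zones.items()}


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Timestamped 2-D positions at a fixed sampling rate."""

    samples: pd.DataFrame  # columns t, x, y
    sampling_rate: float

    def __post_init__(self) -> None:
        required = {"t", "x", "y"}
        if not required.issubset(self.samples.columns):
            raise ValueError(f"trajectory table needs columns {sorted(required)}")
        t = self.samples["t"].to_numpy(dtype=float)
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValueError("trajectory timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.samples[["t", "x", "y"]].to_numpy(dtype=float))):
            raise ValueError("trajectory contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def t(self) -> np.ndarray:
        return self.samples["t"].to_numpy(dtype=float)

    @property
    def xy(self) -> np.ndarray:
        return self.samples[["x", "y"]].to_numpy(dtype=float)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate


@dataclass
class OccupancyRecord:
    """Per-zone occupancy summary over one analysis window."""

    zone: str
    total_time: float          # s, all in-zone samples
    n_visits: int              # qualified visits (>= min duration, gap-merged)
    latency_first_entry: float  # s from window start; window length if censored
    latency_censored: bool
    time_per_visit: float      # nan when n_visits == 0

    def as_dict(self) -> dict:
        return {
            "zone": self.zone,
            "total_time": self.total_time,
            "n_visits": self.n_visits,
            "latency_first_entry": self.latency_first_entry,
            "latency_censored": self.latency_censored,
            "time_per_visit": self.time_per_visit,
        }


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs, stop exclusive."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def zone_occupancy(
    track: Trajectory,
    zones: ZoneSet,
    t_start: float,
    t_end: float,
    min_visit_duration: float = 0.5,
    merge_gap: float = 0.2,
) -> dict[str, OccupancyRecord]:
    """Per-sample occupancy of every zone within ``[t_start, t_end)``.

    Latency to first entry is measured from ``t_start`` and censored at the
    window length (with ``latency_censored=True``) when the zone is never
    entered.
    """
    if len(track.samples) < 2:
        raise ValueError("trajectory must contain at least 2 samples")
    if not t_start < t_end:
        raise ValueError("need t_start < t_end")
    t = track.t
    dt = 1.0 / track.sampling_rate
    sel = (t >= t_start) & (t < t_end)
    x = track.samples["x"].to_numpy(dtype=float)[sel]
    y = track.samples["y"].to_numpy(dtype=float)[sel]
    tw = t[sel]
    window = t_end - t_start

    out: dict[str, OccupancyRecord] = {}
    for name, zone in zones.zones.items():
        inside = np.asarray(zone.contains(x, y), dtype=bool)
        total = float(inside.sum()) * dt

        runs = _runs(inside)
        # merge runs separated by short gaps
        merged: list[tuple[int, int]] = []
        for start, stop in runs:
            if merged and (start - merged[-1][1]) * dt <= merge_gap:
                merged[-1] = (merged[-1][0], stop)
            else:
                merged.append((start, stop))
        visits = [r for r in merged if (r[1] - r[0]) * dt >= min_visit_duration]

        if inside.any():
            latency = float(tw[np.argmax(inside)] - t_start)
            censored = False
        else:
            latency = window
            censored = True
        n_visits = len(visits)
        out[name] = OccupancyRecord(
            zone=name,
            total_time=total,
            n_visits=n_visits,
            latency_first_entry=latency,
            latency_censored=censored,
            time_per_visit=total / n_visits if n_visits else float("nan"),
        )
    return out


def path_length(track: Trajectory, t_start: float, t_end: float) -> float:
    """Summed Euclidean segment length over samples with t in [t_start, t_end)."""
    t = track.t
    sel = (t >= t_start) & (t < t_end)
    xy = track.xy[sel]
    if len(xy) < 2:
        return 0.0
    return float(np.sum(np.hypot(*np.diff(xy, axis=0).T)))


# ---------------------------------------------------------------------------
# social recognition
# ---------------------------------------------------------------------------

@dataclass
class RecognitionMetrics:
    """Stranger-vs-acquainted discrimination readout for the five-insert test."""

    stranger_pct_time: float
    mean_stimulus_pct_time: float
    stranger_visits: int
    mean_stimulus_visits: float
    latency_to_stranger: float
    latency_censored: bool
    stranger_time_per_visit: float
    mean_stimulus_time_per_visit: float
    total_interaction_time: float
    undefined: bool  # True when total interaction time is zero


def recognition_metrics(
    occupancy: dict[str, OccupancyRecord], roles: dict[str, str]
) -> RecognitionMetrics:
    """Stranger vs mean-of-4-acquainted-stimuli comparison.

    Percentages are of the *total interaction time* summed over the five
    insert zones; the acquainted side is averaged over exactly four stimulus
    zones.
    """
    stranger = [z for z, r in roles.items() if r == "stranger"]
    stimuli = sorted(z for z, r in roles.items() if r.startswith("stimulus"))
    if len(stranger) != 1 or len(stimuli) != 4:
        raise ValueError("need exactly 1 stranger zone and 4 stimulus zones")
    for z in stranger + stimuli:
        if z not in occupancy:
            raise KeyError(f"occupancy record missing zone {z!r}")

    s = occupancy[stranger[0]]
    stim = [occupancy[z] for z in stimuli]
    total = s.total_time + sum(r.total_time for r in stim)
    undefined = total <= 0
    pct = (lambda v: 100.0 * v / total) if not undefined else (lambda v: float("nan"))

    return RecognitionMetrics(
        stranger_pct_time=pct(s.total_time),
        mean_stimulus_pct_time=pct(float(np.mean([r.total_time for r in stim]))),
        stranger_visits=s.n_visits,
        mean_stimulus_visits=float(np.mean([r.n_visits for r in stim])),
        latency_to_stranger=s.latency_first_entry,
        latency_censored=s.latency_censored,
        stranger_time_per_visit=s.time_per_visit,
        mean_stimulus_time_per_visit=float(
            np.nanmean([r.time_per_visit for r in stim])
        )
        if any(r.n_visits for r in stim)
        else float("nan"),
        total_interaction_time=total,
        undefined=undefined,
    )


# ---------------------------------------------------------------------------
# trial structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trial:
    name: str
    phases: tuple[tuple[str, float, float], ...]
    insert_roles: dict[str, str]


def trial_schedule(paradigm: str) -> list[Trial]:
    """Canonical trial sequence for a paradigm.

    The social-recognition box runs six 600-s trials: three habituations
    (empty inserts), two exposures (five acquainted stimulus mice) and one
    recognition trial in which one acquainted mouse is replaced by a
    stranger.  Each trial starts with 300 s confined initiation and ends
    with 300 s free interaction after the partition is lifted.
    """
    if paradigm != "sociobox":
        raise ValueError(f"unknown paradigm {paradigm!r}")
    phases = (("initiation", 0.0, 300.0), ("interaction", 300.0, 600.0))
    inserts = [f"insert_{i}" for i in range(1, 6)]
    exposure_roles = {z: f"stimulus_{i}" for i, z in enumerate(inserts, start=1)}
    memory_roles = {z: f"stimulus_{i}" for i, z in enumerate(inserts[:-1], start=1)}
    memory_roles[inserts[-1]] = "stranger"
    trials = [Trial(f"habituation_{i}", phases, {}) for i in range(1, 4)]
    trials += [Trial(f"exposure_{i}", phases, exposure_roles) for i in range(1, 3)]
    trials += [Trial("memory", phases, memory_roles)]
    return trials


def learning_curve(
    latencies, per_day: int = 4, cap: float = 90.0, allow_partial: bool = False
) -> np.ndarray:
    """Per-day mean escape latency from a flat list of per-trial latencies.

    Trials run ``per_day`` to a day; failures are recorded at the ``cap``
    (90 s by convention).  A trailing partial day is rejected unless
    ``allow_partial``.
    """
    lat = np.asarray(latencies, dtype=float)
    if np.any((lat < 0) | (lat > cap)):
        raise ValueError(f"latencies must lie in [0, {cap}] s")
    n = len(lat)
    if n % per_day and not allow_partial:
        raise ValueError(f"{n} trials do not divide into days of {per_day}")
    means = []
    for start in range(0, n, per_day):
        means.append(float(np.mean(lat[start : start + per_day])))
    return np.asarray(means)


@dataclass
class ProbeMetrics:
    time_in_target: float
    visits_target: int
    latency_target: float
    latency_censored: bool
    distance: float


def probe_metrics(
    track: Trajectory,
    quadrants: ZoneSet,
    target: str,
    duration: float = 90.0,
    min_visit_duration: float = 0.5,
    merge_gap: float = 0.2,
) -> ProbeMetrics:
    """Probe-trial readout: target-quadrant occupancy plus swim distance."""
    if target not in quadrants.zones:
        raise KeyError(f"unknown target quadrant {target!r}")
    t0 = float(track.t[0])
    occ = zone_occupancy(
        track,
        quadrants,
        t0,
        t0 + duration,
        min_visit_duration=min_visit_duration,
        merge_gap=merge_gap,
    )[target]
    return ProbeMetrics(
        time_in_target=occ.total_time,
        visits_target=occ.n_visits,
        latency_target=occ.latency_first_entry,
        latency_censored=occ.latency_censored,
        distance=path_length(track, t0, t0 + duration),
    )


# ---------------------------------------------------------------------------
# standard zone layouts
# ---------------------------------------------------------------------------

def open_field_zones(cx: float, cy: float, radius: float) -> ZoneSet:
    """Center / mid / periphery as equal-width annulus thirds of the arena."""
    r1, r2 = radius / 3.0, 2.0 * radius / 3.0
    zones = {
        "center": AnnulusZone(cx, cy, 0.0, r1),
        "mid": AnnulusZone(cx, cy, r1, r2),
        "periphery": AnnulusZone(cx, cy, r2, radius),
    }
    roles = {name: name for name in zones}
    return ZoneSet(zones, roles, (cx, cy), radius)


def quadrant_zones(
    cx: float, cy: float, radius: float, target: str = "NE"
) -> ZoneSet:
    """Four 90-degree quadrants of a circular pool; one carries the target role."""
    names = ["NE", "NW", "SW", "SE"]
    if target not in names:
        raise ValueError(f"target must be one of {names}")
    zones = {
        name: AnnulusSectorZone(
            cx, cy, 0.0, radius, k * math.pi / 2, (k + 1) * math.pi / 2
        )
        for k, name in enumerate(names)
    }
    roles = {name: ("target_quadrant" if name == target else "quadrant") for name in names}
    return ZoneSet(zones, roles, (cx, cy), radius)


def sociobox_zones(
    cx: float,
    cy: float,
    arena_radius: float,
    zone_depth: float,
    roles: dict[str, str] | None = None,
    n_inserts: int = 5,
    angular_width: float = 2 * math.pi / 10,
) -> ZoneSet:
    """Interaction zones: annular sectors of ``zone_depth`` hugging the outer wall,
    one in front of each insert, evenly spaced around the arena."""
    zones: dict[str, Zone] = {}
    for i in range(n_inserts):
        mid = 2 * math.pi * i / n_inserts
        zones[f"insert_{i + 1}"] = AnnulusSectorZone(
            cx,
            cy,
            arena_radius - zone_depth,
            arena_radius,
            mid - angular_width / 2,
            mid + angular_width / 2,
        )
    return ZoneSet(zones, roles or {}, (cx, cy), arena_radius)
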