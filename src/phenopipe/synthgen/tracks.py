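"""Synthetic arena trajectories, optionally with scripted zone visits."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from ..arena import Trajectory, ZoneSet

__all__ = ["gen_trajectory"]


def gen_trajectory(
    arena: ZoneSet,
    duration: float,
    speed: float,
    seed: int = 0,
    sampling_rate: float = 10.0,
    scripted_visits: list[tuple[str, float, float]] | None = None,
    ou_tau: float = 2.0,
) -> Trajectory:
    """Smooth random path inside the arena with optional exact zone visits.

    The free path is an Ornstein-Uhlenbeck velocity walk (stationary speed
    scale ``speed``) reflected at a confinement radius.  Each scripted visit
    ``(zone_name, t_in, t_out)`` parks the animal at an interior point of
    that zone for exactly ``[t_in, t_out)``; outside its window the free
    path is confined to a disk that stays clear of every scripted zone, so
    the occupancy oracle sees exactly the scripted visits.  ``speed = 0``
    with no scripts yields a stationary track at the start point.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if speed < 0:
        raise ValueError("speed must be non-negative")
    visits = sorted(scripted_visits or [], key=lambda v: v[1])
    for i, (name, t_in, t_out) in enumerate(visits):
        if name not in arena.zones:
            raise KeyError(f"unknown zone {name!r} in scripted visit")
        if not 0 <= t_in < t_out:
            raise ValueError("scripted visit needs 0 <= t_in < t_out")
        if i and t_in < visits[i - 1][2]:
            raise ValueError("scripted visits overlap in time")

    cx, cy = arena.arena_center
    max_r = 0.95 * arena.arena_radius
    if visits:
        clearances = [
            arena.zones[name].min_radius_from(cx, cy) for name, _, _ in visits
        ]
        max_r = min([max_r] + [c - 2.0 for c in clearances])
        if max_r <= 1.0:
            raise ValueError(
                "scripted zones must be peripheral so a clear confinement "
                "region exists for the free path"
            )

    rng = np.random.default_rng(seed)
    n = int(math.floor(sampling_rate * duration))
    dt = 1.0 / sampling_rate
    t = np.arange(n) * dt

    pos = np.empty((n, 2))
    p = np.array([cx, cy], dtype=float)
    v = rng.normal(0.0, speed, size=2) if speed > 0 else np.zeros(2)
    theta = dt / ou_tau
    diff = speed * math.sqrt(2 * theta)
    center = np.array([cx, cy])
    for i in range(n):
        pos[i] = p
        if speed > 0:
            v = v * (1 - theta) + rng.normal(0.0, diff, size=2)
            p = p + v * dt
            d = np.linalg.norm(p - center)
            if d > max_r:
                u = (p - center) / d
                p = center + (2 * max_r - d) * u
                v = v - 2 * np.dot(v, u) * u

    for name, t_in, t_out in visits:
        inside = (t >= t_in) & (t < t_out)
        px, py = arena.zones[name].representative_point()
        pos[inside] = (px, py)

    df = pd.DataFrame({"t": t, "x": pos[:, 0], "y": pos[:, 1]})
    return Trajectory(df, sampling_rate)
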