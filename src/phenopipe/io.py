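"""Reading and writing the pipeline's on-disk formats.

Thermal sessions travel as multi-page float32 TIFF stacks with a JSON
sidecar carrying the arena geometry, frame rate, temperature unit and trial
phases; trajectories and event/signal tables as headered CSV; zone layouts
as a JSON geometry spec.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .arena import (
    AnnulusSectorZone,
    AnnulusZone,
    CircleZone,
    Trajectory,
    ZoneSet,
)
from .thermo import ThermalSession

__all__ = [
    "write_thermal_session",
    "read_thermal_session",
    "write_trajectory",
    "read_trajectory",
    "write_zoneset",
    "read_zoneset",
]


def write_thermal_session(
    session: ThermalSession,
    frames_path: str | Path,
    sidecar_path: str | Path,
    arena_center: tuple[float, float] | None = None,
    arena_radius: float | None = None,
) -> None:
    """Frames as multi-page float32 TIFF + JSON sidecar.

    The sidecar stores the arena as a circle (centre, radius) when given,
    otherwise the full boolean mask is encoded run-length-free as a packed
    bitmask; circular geometry is by far the common case.
    """
    tifffile.imwrite(
        str(frames_path),
        session.frames.astype(np.float32),
        photometric="minisblack",
    )
    sidecar = {
        "frame_rate": session.frame_rate,
        "unit": session.unit,
        "phases": [list(p) for p in session.phases],
        "shape": list(session.frames.shape[1:]),
    }
    if arena_center is not None and arena_radius is not None:
        sidecar["arena"] = {
            "type": "circle",
            "center": list(arena_center),
            "radius": arena_radius,
        }
    else:
        sidecar["arena"] = {
            "type": "bitmask",
            "packed": np.packbits(session.arena_mask).tolist(),
        }
    Path(sidecar_path).write_text(json.dumps(sidecar))


def read_thermal_session(
    frames_path: str | Path, sidecar_path: str | Path
) -> ThermalSession:
    frames = tifffile.imread(str(frames_path)).astype(np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    meta = json.loads(Path(sidecar_path).read_text())
    h, w = meta["shape"]
    arena = meta["arena"]
    if arena["type"] == "circle":
        cx, cy = arena["center"]
        ys, xs = np.ogrid[:h, :w]
        mask = (xs - cx) ** 2 + (ys - cy) ** 2 <= arena["radius"] ** 2
    else:
        packed = np.asarray(arena["packed"], dtype=np.uint8)
        mask = np.unpackbits(packed)[: h * w].reshape(h, w).astype(bool)
    return ThermalSession(
        frames=frames,
        frame_rate=meta["frame_rate"],
        arena_mask=mask,
        phases=[tuple(p) for p in meta.get("phases", [])],
        unit=meta.get("unit", "C"),
    )


def write_trajectory(track: Trajectory, path: str | Path) -> None:
    df = track.samples[["t", "x", "y"]].copy()
    df.attrs = {}
    df.to_csv(path, index=False)


def read_trajectory(path: str | Path, sampling_rate: float | None = None) -> Trajectory:
    df = pd.read_csv(path)
    if sampling_rate is None:
        t = df["t"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError("cannot infer sampling rate from fewer than 2 samples")
        sampling_rate = 1.0 / float(np.median(np.diff(t)))
    return Trajectory(df, sampling_rate)


_ZONE_TAGS = {CircleZone: "circle", AnnulusZone: "annulus", AnnulusSectorZone: "annulus_sector"}


def write_zoneset(zones: ZoneSet, path: str | Path) -> None:
    spec = {
        "arena_center": list(zones.arena_center),
        "arena_radius": zones.arena_radius,
        "roles": zones.roles,
        "zones": {
            name: {"type": _ZONE_TAGS[type(z)], **z.__dict__}
            for name, z in zones.zones.items()
        },
    }
    Path(path).write_text(json.dumps(spec))


def read_zoneset(path: str | Path) -> ZoneSet:
    spec = json.loads(Path(path).read_text())
    ctor = {"circle": CircleZone, "annulus": AnnulusZone, "annulus_sector": AnnulusSectorZone}
    zones = {}
    for name, z in spec["zones"].items():
        kind = z.pop("type")
        zones[name] = ctor[kind](**z)
    return ZoneSet(
        zones=zones,
        roles=spec.get("roles", {}),
        arena_center=tuple(spec.get("arena_center", (0.0, 0.0))),
        arena_radius=spec.get("arena_radius", 1.0),
    )
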