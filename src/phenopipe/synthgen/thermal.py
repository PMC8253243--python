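"""Synthetic thermal arena scenes with per-frame ground truth.

Renders a warm ellipse (body) with a thin, cooler, constant-width tail
attached to its posterior pole, moving along a smooth Ornstein-Uhlenbeck
random walk reflected at the arena wall, over a uniform room-temperature
background, plus i.i.d. Gaussian pixel noise.  Default geometry matches a
thermal camera above a social-recognition arena: 640 x 480 px frames, 2 Hz,
36 degC body, 30 degC tail, ~22 degC background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ..thermo import ThermalSession

__all__ = ["ThermalSceneConfig", "GroundTruth", "gen_thermal_session"]

TempSpec = float | Callable[[float], float]


@dataclass
class ThermalSceneConfig:
    """Scene description for one synthetic thermography session.

    Temperatures may be constants or callables of time (seconds) to script
    scenarios such as anticipatory tail cooling.  ``noise_sd`` is the i.i.d.
    Gaussian pixel noise in degrees Celsius.
    """

    frame_size: tuple[int, int] = (480, 640)  # (height, width) px
    frame_rate: float = 2.0                   # Hz (2 or 5 in practice)
    duration: float = 10.0                    # s
    arena_center: tuple[float, float] | None = None  # (x, y); default frame centre
    arena_radius: float = 200.0               # px
    background_temp: TempSpec = 22.0          # degC
    body_temp: TempSpec = 36.0                # degC
    tail_temp: TempSpec = 30.0                # degC
    body_axes: tuple[float, float] = (30.0, 15.0)  # semi-major, semi-minor px
    tail_length: float = 40.0                 # px
    tail_width: float = 3.0                   # px
    noise_sd: float = 0.1                     # degC
    seed: int = 0
    ou_tau: float = 2.0                       # s, velocity relaxation time
    speed_sd: float = 40.0                    # px/s, stationary speed scale
    phases: list[tuple[str, float, float]] | None = None
    render_tail: bool = True

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.tail_width >= min(self.body_axes):
            raise ValueError("tail_width must be smaller than both body axes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.arena_radius <= self.body_axes[0] + self.tail_length:
            raise ValueError("arena too small for the animal")

    def temp_at(self, which: str, t: float) -> float:
        spec = getattr(self, which)
        return float(spec(t)) if callable(spec) else float(spec)


@dataclass
class GroundTruth:
    """Per-frame truth channel for a generated session."""

    body_masks: np.ndarray      # (n, H, W) bool
    tail_masks: np.ndarray      # (n, H, W) bool
    body_temp: np.ndarray       # (n,) degC
    tail_temp: np.ndarray       # (n,) degC
    centroid: np.ndarray        # (n, 2) px (x, y) body-ellipse centre
    ci: np.ndarray = field(init=False)  # body/tail ratio

    def __post_init__(self) -> None:
        self.ci = self.body_temp / self.tail_temp


def _ou_path(
    n: int,
    dt: float,
    center: np.ndarray,
    max_r: float,
    tau: float,
    speed_sd: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Ornstein-Uhlenbeck velocity walk; positions reflected at radius max_r.

    The walk is integrated at sub-steps of at most 0.1 s regardless of the
    frame interval, so wall reflections stay well-posed at low frame rates.
    Returns positions (n, 2) and headings (n,) in radians.
    """
    pos = np.empty((n, 2))
    headings = np.empty(n)
    p = center + rng.uniform(-0.3, 0.3, size=2) * max_r
    v = rng.normal(0.0, speed_sd, size=2)
    heading = math.atan2(v[1], v[0])
    substeps = max(1, int(math.ceil(dt / 0.1)))
    h = dt / substeps
    theta = h / tau
    diff = speed_sd * math.sqrt(2 * theta) if tau > 0 else 0.0
    for i in range(n):
        pos[i] = p
        headings[i] = heading
        for _ in range(substeps):
            v = v * (1 - theta) + rng.normal(0.0, diff, size=2)
            p = p + v * h
            d = np.linalg.norm(p - center)
            if d > max_r:  # reflect at the wall, never error
                u = (p - center) / d
                p = center + max(2 * max_r - d, 0.0) * u
                v = v - 2 * np.dot(v, u) * u
        speed = np.linalg.norm(v)
        if speed > 1e-9:
            heading = math.atan2(v[1], v[0])
    return pos, headings


def _render_mouse(
    shape: tuple[int, int],
    center: np.ndarray,
    heading: float,
    axes: tuple[float, float],
    tail_length: float,
    tail_width: float,
    render_tail: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean body and tail masks for one pose (tail excluded from body)."""
    h, w = shape
    a, b = axes
    cx, cy = center
    ux, uy = math.cos(heading), math.sin(heading)

    pad = a + tail_length + tail_width + 2
    x0, x1 = max(0, int(cx - pad)), min(w, int(cx + pad) + 1)
    y0, y1 = max(0, int(cy - pad)), min(h, int(cy + pad) + 1)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx = xs - cx
    dy = ys - cy

    lon = dx * ux + dy * uy     # along heading
    lat = -dx * uy + dy * ux    # across heading
    body_box = (lon / a) ** 2 + (lat / b) ** 2 <= 1.0

    body = np.zeros(shape, dtype=bool)
    body[y0:y1, x0:x1] = body_box
    tail = np.zeros(shape, dtype=bool)
    if render_tail and tail_length > 0:
        # constant-width segment from the posterior pole, pointing backward
        s = -(lon + a)                      # distance behind the pole
        on_seg = (s >= 0) & (s <= tail_length)
        near = np.abs(lat) <= tail_width / 2.0
        tip = (s > tail_length) & (
            (s - tail_length) ** 2 + lat**2 <= (tail_width / 2.0) ** 2
        )
        tail_box = ((on_seg & near) | tip) & ~body_box
        tail[y0:y1, x0:x1] = tail_box
    return body, tail


def gen_thermal_session(
    cfg: ThermalSceneConfig,
) -> tuple[ThermalSession, GroundTruth]:
    """Generate a calibrated thermal frame stack plus its truth channel.

    Frame count is exactly ``floor(frame_rate * duration)``.  Identical
    configuration and seed reproduce the stack bitwise.  The animal's path
    is confined so body and tail always stay inside the arena (reflection at
    the wall, never an error).
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.frame_size
    n = int(math.floor(cfg.frame_rate * cfg.duration))
    dt = 1.0 / cfg.frame_rate
    center = (
        np.asarray(cfg.arena_center, dtype=float)
        if cfg.arena_center is not None
        else np.array([w / 2.0, h / 2.0])
    )
    # keep the whole animal inside the arena
    max_r = cfg.arena_radius - (cfg.body_axes[0] + cfg.tail_length) - 2.0
    pos, headings = _ou_path(n, dt, center, max_r, cfg.ou_tau, cfg.speed_sd, rng)

    frames = np.empty((n, h, w), dtype=np.float64)
    body_masks = np.empty((n, h, w), dtype=bool)
    tail_masks = np.empty((n, h, w), dtype=bool)
    body_t = np.empty(n)
    tail_t = np.empty(n)
    times = np.arange(n) * dt
    for i, t in enumerate(times):
        bg = cfg.temp_at("background_temp", t)
        bt = cfg.temp_at("body_temp", t)
        tt = cfg.temp_at("tail_temp", t)
        if bt <= bg:
            raise ValueError("body_temp must exceed background_temp at all times")
        body, tail = _render_mouse(
            (h, w),
            pos[i],
            headings[i],
            cfg.body_axes,
            cfg.tail_length,
            cfg.tail_width,
            cfg.render_tail,
        )
        frame = frames[i]
        frame.fill(bg)
        frame[body] = bt
        frame[tail] = tt
        body_masks[i] = body
        tail_masks[i] = tail
        body_t[i] = bt
        tail_t[i] = tt
    if cfg.noise_sd > 0:
        frames += cfg.noise_sd * rng.standard_normal(frames.shape, dtype=np.float32)

    ys, xs = np.ogrid[:h, :w]
    arena = (xs - center[0]) ** 2 + (ys - center[1]) ** 2 <= cfg.arena_radius**2
    phases = cfg.phases if cfg.phases is not None else [("trial", 0.0, cfg.duration)]
    session = ThermalSession(
        frames=frames, frame_rate=cfg.frame_rate, arena_mask=arena, phases=phases
    )
    truth = GroundTruth(
        body_masks=body_masks,
        tail_masks=tail_masks,
        body_temp=body_t,
        tail_temp=tail_t,
        centroid=pos.copy(),
    )
    return session, truth
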