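"""Synthetic fish images, swim videos and kinematic traces with ground truth.

Every downstream stage (tracker, error correction, gait segmentation,
statistics) is validated against this generator, so it encodes the physical
situation the real recordings present:

* a dark, elongated fish silhouette on a light backlit arena.  The body is
  a disc sweep along the midline; the bend is a rigid cranial segment plus
  a uniformly curved distal segment starting at the bend position;
* pectoral fins as two lateral lobes near 0.6 body length.  Real pectoral
  fins are translucent, so on a backlit arena their gray sits close to the
  background -- which is precisely why maximum-entropy binarization drops
  them while keeping the pigmented body (the default fin gray here is 226
  on a 230 background; see docs/methods.md);
* burst-and-coast locomotion: each step is a short series of tail bends (a
  damped oscillation of the bend angle) that produces an acceleration
  and/or a turn, followed by a passive coast in which speed decays;
* injectable single/few-frame midline misplacements that mimic caudal-fin
  and pectoral-fin tracking errors.

Angles follow the package convention (viewer counter-clockwise positive,
y-down image coordinates); a positive bend amplitude bends the tail to the
fish's left.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from skimage import draw as skdraw

from .geometry import arc_lengths, resample_polyline, wrap_angle
from .tracker import FrameMidline, TrackSeries

__all__ = [
    "FishShapeSpec",
    "PoseSpec",
    "StepEvent",
    "SwimScript",
    "GroundTruth",
    "RenderResult",
    "default_width_profile",
    "midline_polyline",
    "render_fish_mask",
    "render_swim_video",
    "simulate_kinematics",
    "SimulatedKinematics",
    "inject_point_errors",
    "random_swim_script",
    "track_from_truth",
    "synthetic_track",
]


def default_width_profile(body_length: float) -> Callable[[np.ndarray], np.ndarray]:
    """Half-width (px) as a function of normalized arc position s in [0, 1]
    (0 = tail tip, 1 = snout): tapers to ~0 at the tail, stays blunt at the
    head, widest near two-thirds of the body."""

    wmax = 0.08 * body_length

    def profile(s):
        s = np.clip(np.asarray(s, dtype=float), 0, 1)
        # pigmented body ends caudally at a finite-width peduncle (the
        # translucent caudal fin beyond it is not part of the silhouette)
        base = (0.14 + 0.86 * s**0.8) * (1.0 - 0.52 * s)
        u = np.clip((s - 0.75) / 0.25, 0.0, 1.0)
        snout = 1.0 - 0.2 * u * u * (3.0 - 2.0 * u)  # slight narrowing at the nose
        return wmax * base * snout / 0.52

    return profile


@dataclass
class FishShapeSpec:
    """Geometry and gray levels of the rendered fish."""

    body_length: float = 80.0
    width_profile: Callable[[np.ndarray], np.ndarray] | None = None
    body_gray: int = 30
    fin_gray: int = 226
    fins_enabled: bool = False
    background_gray: int = 230

    def __post_init__(self) -> None:
        if self.body_length < 20:
            raise ValueError("body_length must be >= 20 px")
        if not (self.body_gray < self.fin_gray < self.background_gray):
            raise ValueError("need body_gray < fin_gray < background_gray")
        if self.width_profile is None:
            self.width_profile = default_width_profile(self.body_length)


@dataclass
class PoseSpec:
    """Instantaneous pose: position of the body midpoint, heading and bend.

    ``bend_amplitude`` is the signed angle (rad, left-positive) between the
    cranial and caudal midline tangents; ``bend_onset`` is the fraction of
    body length from the tail at which flexion begins (the bend position k).
    """

    position: tuple[float, float] = (0.0, 0.0)
    heading: float = 0.0
    bend_amplitude: float = 0.0
    bend_onset: float = 0.6

    def __post_init__(self) -> None:
        if not (0.0 < self.bend_onset <= 1.0):
            raise ValueError("bend_onset must be in (0, 1]")
        if not abs(self.bend_amplitude) < np.pi / 2:
            raise ValueError("|bend_amplitude| must be < pi/2")


@dataclass
class StepEvent:
    """One scripted burst-and-coast step.

    ``n_bends`` monotone tail sweeps at ``frequency`` Hz (the bend-angle
    zero-crossing frequency), peak amplitude ``peak_bend`` rad, net heading
    change ``turn_angle`` rad, a speed gain of ``speed_gain`` mm/s during
    the burst, and a coast occupying ``coast_frac`` of the step duration.
    """

    start: float
    n_bends: int = 2
    frequency: float = 20.0
    peak_bend: float = np.deg2rad(25.0)
    turn_angle: float = 0.0
    speed_gain: float = 60.0
    coast_frac: float = 0.5
    bend_onset: float = 0.6

    def __post_init__(self) -> None:
        if self.n_bends < 2:
            raise ValueError("a step needs at least two tail bends")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if not (0.0 < self.coast_frac < 1.0):
            raise ValueError("coast_frac must be in (0, 1)")
        if self.speed_gain < 0:
            raise ValueError("speed_gain must be >= 0")

    @property
    def burst_duration(self) -> float:
        # n monotone sweeps span (n - 1) half-periods of the oscillation
        return (self.n_bends - 1) / (2.0 * self.frequency)

    @property
    def coast_duration(self) -> float:
        return self.burst_duration * self.coast_frac / (1.0 - self.coast_frac)

    @property
    def end(self) -> float:
        return self.start + self.burst_duration + self.coast_duration


@dataclass
class SwimScript:
    """A deterministic swim program: step events on a time axis."""

    duration: float = 10.0
    fps: float = 100.0
    events: list[StepEvent] = field(default_factory=list)
    seed: int = 0
    initial_speed: float = 0.0
    damping: float = 0.8  # amplitude ratio of successive bend lobes

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        ev = sorted(self.events, key=lambda e: e.start)
        for a, b in zip(ev, ev[1:]):
            if b.start < a.end:
                raise ValueError("step events overlap in time")
        if ev and (ev[0].start < 0 or ev[-1].end > self.duration):
            raise ValueError("step events outside script duration")
        self.events = ev

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))


# ---------------------------------------------------------------------------
# still-image rendering


def midline_polyline(
    shape: FishShapeSpec, pose: PoseSpec, n_samples: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Exact midline of the posed fish.

    Returns ``(points, s)``: an (m, 2) polyline ordered tail -> head in
    image coordinates and the normalized arc positions s in [0, 1].  The
    cranial part (s >= bend_onset) is straight along the heading; the
    distal part is a circular arc whose tangent at the tail deviates from
    the heading by the bend amplitude.
    """
    L = shape.body_length
    if n_samples is None:
        n_samples = max(64, int(round(2 * L)))
    s = np.linspace(1.0, 0.0, n_samples)  # head -> tail
    b = pose.bend_onset
    amp = pose.bend_amplitude
    # tangent angle pointing tail-ward, per sample
    psi = np.full(n_samples, pose.heading + np.pi)
    bent = s < b
    psi[bent] -= amp * (b - s[bent]) / b
    # integrate positions head -> tail (viewer angles: y flipped)
    step = L / (n_samples - 1)
    dx = np.cos(psi) * step
    dy = -np.sin(psi) * step
    x = np.concatenate([[0.0], np.cumsum(dx[:-1])])
    y = np.concatenate([[0.0], np.cumsum(dy[:-1])])
    pts = np.column_stack([x, y])
    # anchor: the midline midpoint (s = 0.5 by arc length) sits at position
    mid = resample_polyline(pts, [0.5])[0]
    pts += np.asarray(pose.position, float) - mid
    return pts[::-1].copy(), s[::-1].copy()


def _silhouette_midline(spine: np.ndarray, w_tail: float, w_head: float) -> np.ndarray:
    """Extend the spine to the tips of the silhouette's rounded end caps:
    the disc sweep reaches one cap radius beyond each spine endpoint, and
    the silhouette's medial axis runs tip to tip."""
    d_tail = spine[0] - spine[1]
    d_tail = d_tail / np.hypot(*d_tail)
    d_head = spine[-1] - spine[-2]
    d_head = d_head / np.hypot(*d_head)
    return np.vstack(
        [spine[0] + d_tail * w_tail, spine, spine[-1] + d_head * w_head]
    )


@dataclass
class RenderResult:
    """A rendered frame: grayscale image, exact silhouette midline (tail
    tip -> snout tip, i.e. including the rounded end caps) and the exact
    body silhouette mask."""

    image: np.ndarray
    midline: np.ndarray
    body_mask: np.ndarray


def _paint_fish(
    canvas: np.ndarray,
    shape: FishShapeSpec,
    pose: PoseSpec,
    scale: int = 1,
) -> np.ndarray:
    """Paint fins then body onto ``canvas`` (modified in place) at an
    integer supersampling scale; returns the body mask at that scale."""
    h, w = canvas.shape
    midline, s = midline_polyline(shape, pose)
    pts = midline * scale
    radii = np.maximum(shape.width_profile(s) * scale, 0.0)

    body = np.zeros_like(canvas, dtype=bool)
    for (x, y), r in zip(pts, radii):
        if r <= 0:
            continue
        rr, cc = skdraw.disk((y, x), r, shape=canvas.shape)
        body[rr, cc] = True

    if shape.fins_enabled:
        fin = np.zeros_like(body)
        # pectoral lobes attach at the body edge near 0.625 body length from
        # the tail and sweep backward, overlapping the silhouette so no gap
        # opens between fin base and body
        anchor = resample_polyline(midline, [0.60, 0.65]) * scale
        p = anchor[0]
        tangent = anchor[1] - anchor[0]
        tangent = tangent / np.hypot(*tangent)
        normal = np.array([-tangent[1], tangent[0]])
        half_w = float(shape.width_profile(np.array([0.625]))[0]) * scale
        fin_len = 0.13 * shape.body_length * scale   # lobe major diameter
        fin_wid = 0.05 * shape.body_length * scale   # lobe minor diameter
        for side in (+1, -1):
            base = p + side * normal * (0.8 * half_w)
            d = -tangent * 0.55 + side * normal * 0.84  # backward-outward sweep
            d = d / np.hypot(*d)
            center = base + d * 0.38 * fin_len
            rot = -np.arctan2(d[1], d[0])
            rr, cc = skdraw.ellipse(
                center[1], center[0], 0.5 * fin_wid, 0.5 * fin_len,
                shape=canvas.shape, rotation=rot,
            )
            fin[rr, cc] = True
        canvas[fin & ~body] = shape.fin_gray
    canvas[body] = shape.body_gray
    return body


def render_fish_mask(
    shape: FishShapeSpec,
    pose: PoseSpec,
    canvas: tuple[int, int],
    antialias: bool = False,
    noise_sigma: float = 0.0,
    illumination: float = 0.0,
    rng: np.random.Generator | None = None,
) -> RenderResult:
    """Render one posed fish on a light canvas ``(width, height)``.

    With ``antialias=False`` the image holds exact gray levels (for exact
    assertions); with ``antialias=True`` it is rendered at 2x and averaged
    down, producing soft edges.  ``noise_sigma`` adds Gaussian pixel noise
    and ``illumination`` a vertical illumination gradient of that amplitude
    (both in gray levels), emulating a real backlit recording.  Raises
    ``ValueError`` if the fish does not fit in the canvas.
    """
    w, h = canvas
    midline, s = midline_polyline(shape, pose)
    radii = shape.width_profile(s)
    margin_x = midline[:, 0].min() - radii.max(), midline[:, 0].max() + radii.max()
    margin_y = midline[:, 1].min() - radii.max(), midline[:, 1].max() + radii.max()
    if margin_x[0] < 0 or margin_y[0] < 0 or margin_x[1] > w - 1 or margin_y[1] > h - 1:
        raise ValueError("fish does not fit in the canvas at this pose")

    scale = 2 if antialias else 1
    hi = np.full((h * scale, w * scale), float(shape.background_gray))
    body_hi = _paint_fish(hi, shape, pose, scale=scale)
    if antialias:
        img = hi.reshape(h, scale, w, scale).mean(axis=(1, 3))
        body = body_hi.reshape(h, scale, w, scale).mean(axis=(1, 3)) >= 0.5
    else:
        img, body = hi, body_hi
    if illumination:
        img = img + illumination * np.linspace(-1.0, 1.0, h)[:, None]
    if noise_sigma:
        if rng is None:
            rng = np.random.default_rng(0)
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    w_tail = float(shape.width_profile(np.array([0.0]))[0])
    w_head = float(shape.width_profile(np.array([1.0]))[0])
    full_midline = _silhouette_midline(midline, w_tail, w_head)
    return RenderResult(image=img, midline=full_midline, body_mask=body)


# ---------------------------------------------------------------------------
# kinematic simulation


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


@dataclass
class SimulatedKinematics:
    """Ground-truth kinematic traces plus the true episode/step tables."""

    t: np.ndarray
    v: np.ndarray
    theta: np.ndarray
    alpha: np.ndarray
    k: np.ndarray
    fps: float
    bends: pd.DataFrame = field(default_factory=pd.DataFrame)
    turns: pd.DataFrame = field(default_factory=pd.DataFrame)
    accels: pd.DataFrame = field(default_factory=pd.DataFrame)
    steps: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_kinematics(script: SwimScript) -> SimulatedKinematics:
    """Generate per-frame v, theta, alpha, k for a swim script.

    Per step: the bend angle is a half-period-wise damped sinusoid at the
    scripted frequency (n monotone sweeps, first lobe reaching the scripted
    peak exactly); speed rises smoothly by the scripted gain during the
    burst and decays exponentially through the coast; heading ramps by the
    scripted turn angle during the burst; the bend position k is constant
    within the step and undefined (NaN) outside bends.
    """
    n = script.n_frames
    t = np.arange(n) / script.fps
    v = np.zeros(n)
    theta = np.zeros(n)
    alpha = np.zeros(n)
    k = np.full(n, np.nan)

    bends_rows, turns_rows, accels_rows, steps_rows = [], [], [], []

    v_level = script.initial_speed  # speed at the end of the previous segment
    seg_start_t, seg_tau = 0.0, 0.25  # exponential decay of current segment
    for ev in script.events:
        bd, cd = ev.burst_duration, ev.coast_duration
        # speed decays up to the burst start
        pre = (t >= seg_start_t) & (t < ev.start)
        v[pre] = v_level * np.exp(-(t[pre] - seg_start_t) / seg_tau)
        v_trough = v_level * np.exp(-(ev.start - seg_start_t) / seg_tau)

        burst = (t >= ev.start) & (t < ev.start + bd)
        tau = t[burst] - ev.start
        # bend angle: damped oscillation, lobe j scaled by damping^j
        j = np.floor(2.0 * ev.frequency * tau).astype(int)
        alpha[burst] = (
            ev.peak_bend * script.damping**j * np.sin(2 * np.pi * ev.frequency * tau)
        )
        k[burst] = ev.bend_onset
        # heading ramp and speed rise over the burst
        theta[t >= ev.start] += ev.turn_angle * 1.0
        theta[burst] += ev.turn_angle * (_smoothstep(tau / bd) - 1.0)
        v[burst] = v_trough + ev.speed_gain * _smoothstep(tau / bd)
        v_peak = v_trough + ev.speed_gain

        # coast (and beyond): exponential decay from the peak
        seg_start_t = ev.start + bd
        seg_tau = max(cd / 3.0, 1.0 / script.fps)
        v_level = v_peak

        # --- ground-truth tables -----------------------------------------
        T = 1.0 / ev.frequency
        extrema_tau = T / 4.0 + np.arange(ev.n_bends - 1) * T / 2.0
        jj = np.floor(2.0 * ev.frequency * extrema_tau).astype(int)
        extrema_val = (
            ev.peak_bend * script.damping**jj * np.sin(2 * np.pi * ev.frequency * extrema_tau)
        )
        knots_tau = np.concatenate([[0.0], extrema_tau, [bd]])
        knots_val = np.concatenate([[0.0], extrema_val, [0.0]])
        for i in range(len(knots_tau) - 1):
            d_alpha = knots_val[i + 1] - knots_val[i]
            bends_rows.append(
                dict(
                    start_t=ev.start + knots_tau[i],
                    end_t=ev.start + knots_tau[i + 1],
                    delta_alpha=d_alpha,
                    direction="left" if d_alpha > 0 else "right",
                    bend_position=ev.bend_onset,
                    step=len(steps_rows),
                )
            )
        if ev.turn_angle != 0.0:
            turns_rows.append(
                dict(
                    start_t=ev.start,
                    end_t=ev.start + bd,
                    turn_angle=ev.turn_angle,
                    direction="left" if ev.turn_angle > 0 else "right",
                    step=len(steps_rows),
                )
            )
        if ev.speed_gain > 0.0:
            accels_rows.append(
                dict(
                    start_t=ev.start,
                    end_t=ev.start + bd,
                    speed_change=ev.speed_gain,
                    step=len(steps_rows),
                )
            )
        traveled = float(np.abs(np.diff(knots_val)).sum())
        steps_rows.append(
            dict(
                start_t=ev.start,
                burst_end_t=ev.start + bd,
                end_t=ev.end,
                n_bends=ev.n_bends,
                speed_change=ev.speed_gain,
                turn_angle=ev.turn_angle,
                bend_angle_reached=abs(ev.peak_bend),
                bend_angle_traveled=traveled,
                bend_duration_total=bd,
                bend_wave_frequency=ev.n_bends / bd,
                coast_duration=cd,
                step_duration=bd + cd,
                coast_percent=cd / (bd + cd),
                bend_position=ev.bend_onset,
            )
        )

    # tail of the trace after the last event
    post = t >= seg_start_t
    v[post] = v_level * np.exp(-(t[post] - seg_start_t) / seg_tau)
    if not script.events:
        v[:] = script.initial_speed

    # step length needs the realized speed trace
    for row in steps_rows:
        sel = (t >= row["start_t"]) & (t <= row["end_t"])
        if sel.sum() >= 2:
            row["step_length"] = float(np.trapezoid(v[sel], t[sel]))
        else:
            row["step_length"] = 0.0

    return SimulatedKinematics(
        t=t,
        v=v,
        theta=theta,
        alpha=alpha,
        k=k,
        fps=script.fps,
        bends=pd.DataFrame(bends_rows),
        turns=pd.DataFrame(turns_rows),
        accels=pd.DataFrame(accels_rows),
        steps=pd.DataFrame(steps_rows),
    )


def random_swim_script(
    seed: int,
    duration: float = 10.0,
    fps: float = 100.0,
    n_steps: int = 8,
    turn_prob: float = 0.6,
) -> SwimScript:
    """A randomized but reproducible burst-and-coast script.

    Event parameters are drawn from ranges typical of adult zebrafish
    exploratory swimming: 2-4 bends per step, 10-18 Hz bend wave, peak bend
    15-40 deg, turns up to +/-60 deg, speed gains 30-120 mm/s.
    """
    rng = np.random.default_rng(seed)
    events = []
    t_cursor = 0.3
    for _ in range(n_steps):
        freq = rng.uniform(10.0, 18.0)
        n_bends = int(rng.integers(2, 5))
        cf = rng.uniform(0.35, 0.65)
        turn = rng.uniform(np.deg2rad(12), np.deg2rad(60)) * rng.choice([-1, 1]) \
            if rng.random() < turn_prob else 0.0
        ev = StepEvent(
            start=round(t_cursor, 3),
            n_bends=n_bends,
            frequency=freq,
            peak_bend=rng.uniform(np.deg2rad(15), np.deg2rad(40)),
            turn_angle=turn,
            speed_gain=rng.uniform(30.0, 120.0),
            coast_frac=cf,
            bend_onset=rng.uniform(0.45, 0.8),
        )
        events.append(ev)
        t_cursor = ev.end + rng.uniform(0.35, 0.8)
        if t_cursor > duration - 0.4:
            break
    return SwimScript(duration=duration, fps=fps, events=events, seed=seed)


# ---------------------------------------------------------------------------
# video rendering


@dataclass
class GroundTruth:
    """Frame-aligned truth for a rendered swim video."""

    frames: pd.DataFrame            # frame, t, c_x, c_y, theta, alpha, k
    midlines: list[np.ndarray]      # exact midline polyline per frame
    bends: pd.DataFrame
    turns: pd.DataFrame
    accels: pd.DataFrame
    steps: pd.DataFrame
    manifest: dict


def _integrate_path(
    sim: SimulatedKinematics,
    shape: FishShapeSpec,
    arena: tuple[int, int],
    mm_per_px: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the centroid path from the simulated speed and heading,
    reflecting specularly off a wall margin so the fish stays inside the
    arena.  Returns (positions px, realized heading per frame)."""
    w, h = arena
    margin = 0.62 * shape.body_length
    if w - 2 * margin <= 0 or h - 2 * margin <= 0:
        raise ValueError("arena too small for the fish")
    n = len(sim.t)
    theta = sim.theta.copy()
    pos = np.zeros((n, 2))
    pos[0] = (w / 2.0, h / 2.0)
    for i in range(1, n):
        step_px = sim.v[i] / mm_per_px / sim.fps
        d = np.array([np.cos(theta[i]), -np.sin(theta[i])])
        nxt = pos[i - 1] + d * step_px
        if nxt[0] < margin or nxt[0] > w - margin:
            theta[i:] = np.pi - theta[i:]  # mirror on x
            d = np.array([np.cos(theta[i]), -np.sin(theta[i])])
            nxt = pos[i - 1] + d * step_px
        if nxt[1] < margin or nxt[1] > h - margin:
            theta[i:] = -theta[i:]
            d = np.array([np.cos(theta[i]), -np.sin(theta[i])])
            nxt = pos[i - 1] + d * step_px
        pos[i] = np.clip(nxt, margin, (w - margin, h - margin))
    return pos, theta


def synthetic_track(
    script: SwimScript,
    n_midline: int = 10,
    shape: FishShapeSpec | None = None,
    arena: tuple[int, int] = (400, 300),
    mm_per_px: float = 0.5,
) -> tuple[TrackSeries, SimulatedKinematics]:
    """An idealized tracker output computed directly from the scripted
    poses, with no rasterization: exact midline geometry resampled at the
    tracker's point fractions.  Fast ground truth for testing the error
    corrector and the gait analysis in isolation from the imaging stages.
    """
    shape = shape or FishShapeSpec()
    sim = simulate_kinematics(script)
    pos, theta = _integrate_path(sim, shape, arena, mm_per_px)
    records = []
    fracs = np.arange(0, n_midline) / n_midline
    for i in range(len(sim.t)):
        pose = PoseSpec(
            position=tuple(pos[i]),
            heading=float(wrap_angle(theta[i])),
            bend_amplitude=float(sim.alpha[i]),
            bend_onset=float(sim.k[i]) if np.isfinite(sim.k[i]) else 0.6,
        )
        ml, _ = midline_polyline(shape, pose)
        S = resample_polyline(ml, fracs)
        records.append(
            FrameMidline(
                frame_index=i, C=pos[i].copy(), S=S, head=ml[-1].copy(), flag="ok"
            )
        )
    sim.theta = theta  # realized heading (after wall reflections)
    return TrackSeries(fps=script.fps, mm_per_px=mm_per_px, frames=records), sim


def render_swim_video(
    shape: FishShapeSpec,
    script: SwimScript,
    arena: tuple[int, int] = (400, 300),
    mm_per_px: float = 0.5,
    antialias: bool = True,
    noise_sigma: float = 2.0,
    illumination: float = 6.0,
) -> tuple[list[np.ndarray], GroundTruth]:
    """Render a whole swim video plus frame-aligned ground truth.

    The trajectory integrates the simulated speed along the simulated
    heading; specular reflection at a wall margin keeps the fish inside the
    arena (the reflected heading is what the ground truth records).
    Deterministic for a fixed script seed.
    """
    sim = simulate_kinematics(script)
    w, h = arena
    rng = np.random.default_rng(script.seed)
    n = script.n_frames
    pos, theta = _integrate_path(sim, shape, arena, mm_per_px)

    frames: list[np.ndarray] = []
    midlines: list[np.ndarray] = []
    rows = []
    for i in range(n):
        pose = PoseSpec(
            position=tuple(pos[i]),
            heading=float(wrap_angle(theta[i])),
            bend_amplitude=float(sim.alpha[i]),
            bend_onset=float(sim.k[i]) if np.isfinite(sim.k[i]) else 0.6,
        )
        res = render_fish_mask(
            shape,
            pose,
            (w, h),
            antialias=antialias,
            noise_sigma=noise_sigma,
            illumination=illumination,
            rng=rng,
        )
        frames.append(res.image)
        midlines.append(res.midline)
        ys, xs = np.nonzero(res.body_mask)
        rows.append(
            dict(
                frame=i,
                t=sim.t[i],
                c_x=xs.mean(),
                c_y=ys.mean(),
                theta=theta[i],
                alpha=sim.alpha[i],
                k=sim.k[i],
            )
        )

    manifest = dict(
        seed=script.seed,
        fps=script.fps,
        duration=script.duration,
        mm_per_px=mm_per_px,
        arena=list(arena),
        body_length=shape.body_length,
        fins_enabled=shape.fins_enabled,
        body_gray=shape.body_gray,
        fin_gray=shape.fin_gray,
        background_gray=shape.background_gray,
        noise_sigma=noise_sigma,
        illumination=illumination,
        antialias=antialias,
        events=[dataclasses.asdict(e) for e in script.events],
    )
    truth = GroundTruth(
        frames=pd.DataFrame(rows),
        midlines=midlines,
        bends=sim.bends,
        turns=sim.turns,
        accels=sim.accels,
        steps=sim.steps,
        manifest=manifest,
    )
    return frames, truth


def track_from_truth(
    truth: GroundTruth,
    n_midline: int,
    fps: float,
    mm_per_px: float,
    include_head: bool = True,
) -> TrackSeries:
    """Build an idealized TrackSeries directly from ground-truth midlines
    (a perfect tracker), used to test error injection and correction in
    isolation from the imaging pipeline."""
    records = []
    for i, ml in enumerate(truth.midlines):
        fracs = np.arange(0, n_midline) / n_midline
        S = resample_polyline(ml, fracs)
        head = ml[-1].copy()
        row = truth.frames.iloc[i]
        records.append(
            FrameMidline(
                frame_index=i,
                C=np.array([row.c_x, row.c_y]),
                S=S,
                head=head,
                foreground_area=np.nan,
                flag="ok",
            )
        )
    return TrackSeries(fps=fps, mm_per_px=mm_per_px, frames=records)


# ---------------------------------------------------------------------------
# error injection


def inject_point_errors(
    track: TrackSeries,
    frames: Sequence[int],
    mode: str = "pectoral-fin",
) -> tuple[TrackSeries, list[int]]:
    """Corrupt midline points in the given frames, mimicking fin errors.

    ``tail-fin``: S1 is reflected past S2 (caudal-fin interference: S1 and
    S2 converge and the caudal tangent flips) -- only the caudal segment is
    disturbed, the cranial segment stays sound.

    ``pectoral-fin``: S1 jumps to a pectoral-fin locus lateral of the
    mid-trunk and the midline points are re-derived from that wrong anchor,
    disrupting both the caudal and cranial tangents.

    Unlisted frames are untouched; returns the corrupted copy and the
    sorted list of corrupted frame indices.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    if mode not in ("tail-fin", "pectoral-fin"):
        raise ValueError(f"unknown mode {mode!r}")
    frames = sorted(set(int(f) for f in frames))
    valid = {f.frame_index for f in track.frames}
    if not set(frames) <= valid:
        raise ValueError("frames to corrupt are not all in the track")

    out = track.copy()
    offset = track.frames[0].frame_index
    for f in frames:
        fm = out.frames[f - offset]
        if mode == "tail-fin":
            s1, s2 = fm.S[0], fm.S[1]
            fm.S[0] = s2 + 0.6 * (s2 - s1)
        else:
            chain = np.vstack([fm.S, fm.head])
            s = arc_lengths(chain)
            total = s[-1]
            axis_pts = resample_polyline(chain, [0.15, 0.55, 0.65])
            u = axis_pts[2] - axis_pts[1]
            u = u / np.hypot(*u)
            perp = np.array([-u[1], u[0]])
            pectoral = axis_pts[1] + perp * 0.4 * total
            # midline re-derived from the wrong caudal anchor: it now runs
            # from the fin locus back toward the caudal trunk
            target = axis_pts[0]
            n = fm.S.shape[0]
            line = np.vstack([pectoral, target])
            fm.S = resample_polyline(line, np.arange(n) / max(n - 1, 1))
    return out, frames
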