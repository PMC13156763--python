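"""Per-frame kinematics, episode detection, burst-and-coast steps and
whole-recording (macro) summaries.

From a corrected, calibrated track the module derives four per-frame
quantities:

* speed ``v`` (mm/s) from the centroid displacement;
* orientation ``theta`` (rad, unwrapped) of the cranial segment Sn-1 -> Sn;
* signed bend angle ``alpha`` (rad, left-positive) between the cranial
  tangent (Sn-1 -> Sn) and the caudal tangent (S1 -> S2);
* bend position ``k`` in [0, 1]: the fraction of body length from the tail
  at which lateral flexion begins (NaN for a straight body).

Swimming is episodic: speed peaks are accelerations, orientation ramps are
turns, bend-angle sweeps are tail bends.  Consecutive tail bends group into
the burst of a *step* (one burst + the following coast), the unit of
micro-parameter analysis, in analogy with a stride.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .geometry import arc_lengths, segment_orientation, wrap_angle
from .tracker import TrackSeries

__all__ = [
    "KinematicSeries",
    "BendEpisode",
    "TurnEpisode",
    "AccelEpisode",
    "Step",
    "GaitParams",
    "derive_series",
    "bend_position",
    "detect_bends",
    "detect_turns",
    "detect_accels",
    "assemble_steps",
    "macro_summary",
    "episodes_frame",
    "steps_frame",
    "STEP_METRICS",
]

#: the step micro-parameter columns, in reporting order
STEP_METRICS = [
    "speed_change",
    "acceleration",
    "turn_angle",
    "turn_angular_velocity",
    "turn_duration",
    "bend_angle_reached",
    "bend_angle_traveled",
    "bend_angular_velocity",
    "bend_duration_total",
    "bend_wave_frequency",
    "coast_duration",
    "step_duration",
    "coast_percent",
    "step_length",
]


@dataclass
class GaitParams:
    """Episode-detection thresholds (all configurable).

    Defaults are small relative to normal adult dynamics (per-frame cranial
    orientation changes reach ~40 deg during rapid turns), so genuine
    episodes are kept while derivative noise is not segmented.
    """

    min_bend_amplitude: float = np.deg2rad(5.0)   # rad, |delta alpha| per sweep
    turn_rate_threshold: float = np.deg2rad(30.0)  # rad/s
    min_turn_angle: float = np.deg2rad(10.0)       # rad
    turn_merge_gap: int = 2                        # frames
    min_speed_change: float = 5.0                  # mm/s
    inter_bend_gap: float = 0.15                   # s, bends closer than this share a step
    freeze_speed: float = 1.0                      # mm/s
    freeze_min_duration: float = 1.0               # s
    speed_smooth_frames: int = 5                   # centered moving average for v
    k_tangent_tolerance: float = np.deg2rad(10.0)  # flexion-onset tolerance


@dataclass
class KinematicSeries:
    """Per-frame kinematic quantities of one recording."""

    t: np.ndarray
    v: np.ndarray          # smoothed speed, mm/s
    v_raw: np.ndarray      # unsmoothed speed (for max speed)
    theta: np.ndarray      # unwrapped orientation, rad
    alpha: np.ndarray      # signed bend angle, rad (left positive)
    k: np.ndarray          # bend position in [0, 1], NaN when straight
    fps: float
    mm_per_px: float
    quality: np.ndarray | None = None  # True where the frame is usable

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class BendEpisode:
    start: int
    end: int
    delta_alpha: float
    angular_velocity: float
    duration: float
    bend_position: float
    direction: str = ""

    def __post_init__(self) -> None:
        if not self.direction:
            self.direction = "left" if self.delta_alpha > 0 else "right"


@dataclass
class TurnEpisode:
    start: int
    end: int
    turn_angle: float
    angular_velocity: float
    duration: float
    direction: str = ""

    def __post_init__(self) -> None:
        if not self.direction:
            self.direction = "left" if self.turn_angle > 0 else "right"


@dataclass
class AccelEpisode:
    start: int
    end: int
    speed_change: float
    acceleration: float


@dataclass
class Step:
    bends: list[BendEpisode]
    turn: TurnEpisode | None
    accel: AccelEpisode | None
    burst_start: int
    burst_end: int
    end: int
    metrics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# per-frame series


def _unwrap_with_nan(raw: np.ndarray) -> np.ndarray:
    """Unwrap a wrapped angle series, stepping over NaN entries."""
    out = np.full_like(raw, np.nan)
    last_val, last_unwrapped = None, None
    for i, a in enumerate(raw):
        if not np.isfinite(a):
            continue
        if last_val is None:
            out[i] = a
        else:
            out[i] = last_unwrapped + wrap_angle(a - last_val)
        last_val, last_unwrapped = a, out[i]
    return out


def bend_position(points: np.ndarray, tolerance: float = np.deg2rad(10.0)) -> float:
    """Bend position k of one midline (points ordered tail -> head).

    Walking from the head toward the tail, the first segment whose tangent
    deviates from the cranial axis by more than ``tolerance`` marks where
    flexion begins; k is the arc length from the tail to that point divided
    by the whole midline arc length.  A straight midline returns NaN.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("bend position needs at least 3 midline points")
    s = arc_lengths(pts)
    axis = segment_orientation(pts[-2], pts[-1])
    for j in range(pts.shape[0] - 2, 0, -1):  # segments head-ward -> tail-ward
        tangent = segment_orientation(pts[j - 1], pts[j])
        if abs(wrap_angle(tangent - axis)) > tolerance:
            return float(s[j] / s[-1])
    return float("nan")


def derive_series(
    track: TrackSeries,
    params: GaitParams | None = None,
) -> KinematicSeries:
    """Per-frame v, theta, alpha, k from a (corrected) track.

    Speed is |delta C| x fps x mm_per_px, smoothed with a short centered
    moving average (the raw trace is kept for the maximum speed).  Frames
    flagged unusable propagate into the quality mask and carry NaN.
    """
    params = params or GaitParams()
    n = len(track)
    pts = track.point_array()  # (n, n_midline + 2, 2): C, S1..Sn, head
    C = pts[:, 0]
    S = pts[:, 1:-1]
    quality = np.array([f.flag != "no_fish" and np.all(np.isfinite(f.S)) for f in track.frames])

    t = np.arange(n) / track.fps
    dC = np.hypot(*np.diff(C, axis=0).T)
    v_raw = np.empty(n)
    v_raw[1:] = dC * track.fps * track.mm_per_px
    v_raw[0] = v_raw[1] if n > 1 else 0.0
    v_raw[~quality] = np.nan

    w = max(1, params.speed_smooth_frames)
    if w > 1 and n >= w:
        kernel = np.ones(w) / w
        filled = np.where(np.isfinite(v_raw), v_raw, np.nanmean(v_raw) if np.any(quality) else 0.0)
        v = np.convolve(filled, kernel, mode="same")
        v[~quality] = np.nan
    else:
        v = v_raw.copy()

    theta_raw = np.full(n, np.nan)
    alpha = np.full(n, np.nan)
    k = np.full(n, np.nan)
    for i in range(n):
        if not quality[i]:
            continue
        try:
            th_cr = segment_orientation(S[i, -2], S[i, -1])
            th_cd = segment_orientation(S[i, 0], S[i, 1])
        except ValueError:
            quality[i] = False
            continue
        theta_raw[i] = th_cr
        alpha[i] = wrap_angle(th_cr - th_cd)
        k[i] = bend_position(S[i], tolerance=params.k_tangent_tolerance)
    theta = _unwrap_with_nan(theta_raw)
    return KinematicSeries(
        t=t,
        v=v,
        v_raw=v_raw,
        theta=theta,
        alpha=alpha,
        k=k,
        fps=track.fps,
        mm_per_px=track.mm_per_px,
        quality=quality,
    )


# ---------------------------------------------------------------------------
# episode detection


def detect_bends(
    series: KinematicSeries,
    params: GaitParams | None = None,
) -> list[BendEpisode]:
    """Tail bends: maximal monotone sweeps of alpha between successive
    significant extrema (or neutral crossings) with |delta alpha| at least
    the minimum amplitude.  Direction follows the sign of delta alpha
    (positive = left); the bend position is the maximum k in the sweep."""
    params = params or GaitParams()
    alpha = np.where(np.isfinite(series.alpha), series.alpha, 0.0)
    n = len(alpha)
    min_amp = params.min_bend_amplitude
    peaks_hi, _ = find_peaks(alpha, prominence=min_amp)
    peaks_lo, _ = find_peaks(-alpha, prominence=min_amp)
    extrema = np.sort(np.concatenate([peaks_hi, peaks_lo]))
    if extrema.size == 0:
        return []

    eps = min_amp / 4.0
    # sweeps run extremum to extremum, but a near-neutral plateau between
    # two extrema separates them into a return-to-neutral sweep and the
    # next episode's departure-from-neutral sweep; the first sweep starts
    # at the last neutral frame before the first extremum and the last one
    # ends at the first neutral frame after the last extremum
    neutral = np.abs(alpha) <= eps
    before = np.nonzero(neutral[: extrema[0]])[0]
    knots = [int(before[-1]) if before.size else 0]
    min_plateau = 3  # frames; a mere zero transit must not split a sweep
    for e, e_next in zip(extrema[:-1], extrema[1:]):
        knots.append(int(e))
        between = np.nonzero(neutral[e + 1 : e_next])[0]
        if between.size >= min_plateau and between[-1] - between[0] >= min_plateau - 1:
            knots.append(int(e + 1 + between[0]))
            knots.append(int(e + 1 + between[-1]))
    knots.append(int(extrema[-1]))
    after = np.nonzero(neutral[extrema[-1] :])[0]
    knots.append(int(extrema[-1] + after[0]) if after.size else n - 1)
    knots = np.asarray(knots)

    extrema_set = set(int(e) for e in extrema)
    times = _refine_knot_times(alpha, knots, extrema_set, eps)

    bends: list[BendEpisode] = []
    for (a, b), (ta, tb) in zip(zip(knots[:-1], knots[1:]), zip(times[:-1], times[1:])):
        if b <= a:
            continue
        d_alpha = alpha[b] - alpha[a]
        if abs(d_alpha) < min_amp:
            continue
        dadt = np.abs(np.diff(alpha[a : b + 1])) * series.fps
        seg_k = series.k[a : b + 1]
        k_max = float(np.nanmax(seg_k)) if np.any(np.isfinite(seg_k)) else float("nan")
        bends.append(
            BendEpisode(
                start=int(a),
                end=int(b),
                delta_alpha=float(d_alpha),
                angular_velocity=float(dadt.max()) if dadt.size else 0.0,
                duration=max(tb - ta, 1.0) / series.fps,
                bend_position=k_max,
            )
        )
    return bends


def _refine_knot_times(
    alpha: np.ndarray, knots: np.ndarray, extrema: set, eps: float
) -> np.ndarray:
    """Sub-frame times (in frame units) for sweep boundaries.

    Frame-quantized durations are too coarse for tail-beat rates near the
    Nyquist regime of a 100 fps recording, so extrema are refined by
    parabolic interpolation and neutral boundaries by linear extrapolation
    of the departing/arriving limb of the oscillation to zero.
    """
    n = len(alpha)
    times = np.asarray(knots, dtype=float).copy()
    for i, k in enumerate(knots):
        k = int(k)
        if k in extrema and 1 <= k <= n - 2:
            den = alpha[k - 1] - 2 * alpha[k] + alpha[k + 1]
            if den != 0:
                dt = 0.5 * (alpha[k - 1] - alpha[k + 1]) / den
                times[i] = k + float(np.clip(dt, -0.5, 0.5))
        elif abs(alpha[k]) <= eps:
            # departing boundary: extrapolate the rising limb back to zero
            if (
                i < len(knots) - 1
                and knots[i + 1] in extrema
                and k + 3 < n
                and abs(alpha[k + 1]) > eps
            ):
                t0 = _root_toward(alpha, k + 1, k + 2, k + 3)
                if t0 is not None:
                    times[i] = float(np.clip(t0, k, k + 1))
            # arriving boundary: extrapolate the falling limb forward to zero
            if (
                i > 0
                and knots[i - 1] in extrema
                and k - 3 >= 0
                and abs(alpha[k - 1]) > eps
            ):
                t1 = _root_toward(alpha, k - 1, k - 2, k - 3)
                if t1 is not None:
                    times[i] = float(np.clip(t1, k - 1, k))
    return times


def _root_toward(alpha: np.ndarray, i0: int, i1: int, i2: int) -> float | None:
    """Zero of the quadratic through samples i0, i1, i2, taken on the side
    of i0 away from i1 (i.e. extrapolating the limb back/forward to zero)."""
    x = np.array([i0, i1, i2], dtype=float)
    y = alpha[[i0, i1, i2]].astype(float)
    try:
        coef = np.polyfit(x, y, 2)
    except np.linalg.LinAlgError:  # pragma: no cover
        return None
    roots = np.roots(coef)
    roots = roots[np.isreal(roots)].real
    if roots.size == 0:
        # fall back to the secant through the first two samples
        slope = (y[1] - y[0]) / (x[1] - x[0])
        return x[0] - y[0] / slope if slope != 0 else None
    # pick the root nearest i0 on the far side from i1
    side = np.sign(i0 - i1)
    cand = roots[np.sign(roots - i0) * side >= 0] if np.any(
        np.sign(roots - i0) * side >= 0
    ) else roots
    return float(cand[np.argmin(np.abs(cand - i0))])


def detect_turns(
    series: KinematicSeries,
    params: GaitParams | None = None,
) -> list[TurnEpisode]:
    """Turns: maximal intervals where |d theta / dt| exceeds the rate
    threshold (gaps up to ``turn_merge_gap`` frames merged), kept when the
    net angle change reaches the minimum turn angle."""
    params = params or GaitParams()
    theta = series.theta
    n = len(theta)
    if n < 2:
        return []
    dth = np.diff(theta)
    with np.errstate(invalid="ignore"):
        active = np.abs(dth) * series.fps > params.turn_rate_threshold
    active = np.where(np.isfinite(dth), active, False)

    # merge short gaps
    idx = np.nonzero(active)[0]
    if idx.size == 0:
        return []
    turns: list[TurnEpisode] = []
    run_start = idx[0]
    prev = idx[0]
    segments = []
    for i in idx[1:]:
        if i - prev <= params.turn_merge_gap + 1:
            prev = i
            continue
        segments.append((run_start, prev))
        run_start, prev = i, i
    segments.append((run_start, prev))

    for s0, s1 in segments:
        a, b = int(s0), int(s1) + 1  # frame span of the episode
        angle = theta[b] - theta[a]
        if not np.isfinite(angle) or abs(angle) < params.min_turn_angle:
            continue
        seg = np.abs(dth[s0 : s1 + 1]) * series.fps
        turns.append(
            TurnEpisode(
                start=a,
                end=b,
                turn_angle=float(angle),
                angular_velocity=float(np.nanmax(seg)),
                duration=(b - a) / series.fps,
            )
        )
    return turns


def detect_accels(
    series: KinematicSeries,
    params: GaitParams | None = None,
) -> list[AccelEpisode]:
    """Accelerations: trough-to-peak upslopes of the (smoothed) speed with
    a speed change of at least the minimum; the acceleration value is the
    maximum discrete dv/dt within the upslope."""
    params = params or GaitParams()
    v = np.where(np.isfinite(series.v), series.v, 0.0)
    peaks, _ = find_peaks(v, prominence=params.min_speed_change)
    out: list[AccelEpisode] = []
    prev_peak = 0
    for p in peaks:
        trough = int(prev_peak + np.argmin(v[prev_peak : p + 1]))
        change = v[p] - v[trough]
        if change >= params.min_speed_change and p > trough:
            dv = np.diff(v[trough : p + 1]) * series.fps
            out.append(
                AccelEpisode(
                    start=trough,
                    end=int(p),
                    speed_change=float(change),
                    acceleration=float(dv.max()),
                )
            )
        prev_peak = int(p)
    return out


# ---------------------------------------------------------------------------
# steps


def _freeze_runs(series: KinematicSeries, params: GaitParams) -> list[tuple[int, int]]:
    """Inclusive frame runs where v stays below the freeze speed for at
    least the minimum freeze duration."""
    v = series.v
    below = np.where(np.isfinite(v), v < params.freeze_speed, False)
    runs = []
    i = 0
    n = len(v)
    min_frames = int(np.ceil(params.freeze_min_duration * series.fps))
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and below[j + 1]:
            j += 1
        if j - i + 1 >= min_frames:
            runs.append((i, j))
        i = j + 1
    return runs


def assemble_steps(
    bends: list[BendEpisode],
    turns: list[TurnEpisode],
    accels: list[AccelEpisode],
    series: KinematicSeries,
    params: GaitParams | None = None,
) -> list[Step]:
    """Group tail bends into burst-and-coast steps and compute the step
    micro-parameters.

    Consecutive bends separated by at most the inter-bend gap form one bend
    series -- the burst.  Turns and accelerations overlapping the burst are
    attached.  The coast runs from the burst end to the next step's start
    (the final step coasts until speed bottoms out or the series ends); a
    freezing onset inside the coast ends the step there.  Obligatory return
    bends are part of the series by construction and never start a step.
    """
    params = params or GaitParams()
    if not bends:
        return []
    gap_frames = params.inter_bend_gap * series.fps
    groups: list[list[BendEpisode]] = [[bends[0]]]
    for b in bends[1:]:
        if b.start - groups[-1][-1].end <= gap_frames:
            groups[-1].append(b)
        else:
            groups.append([b])

    freeze_starts = [a for a, _ in _freeze_runs(series, params)]
    n = len(series)
    steps: list[Step] = []
    for gi, grp in enumerate(groups):
        burst_start = grp[0].start
        burst_end = grp[-1].end
        if gi + 1 < len(groups):
            end = groups[gi + 1][0].start
        else:
            v_after = np.where(np.isfinite(series.v), series.v, np.inf)[burst_end:]
            rel = np.nonzero(np.diff(v_after) > 0)[0]
            end = int(burst_end + rel[0]) if rel.size else n - 1
            end = max(end, burst_end)
        for fs in freeze_starts:
            if burst_end < fs < end:
                end = fs
                break

        turn = None
        for tu in turns:
            if tu.start <= burst_end and tu.end >= burst_start:
                if turn is None or abs(tu.turn_angle) > abs(turn.turn_angle):
                    turn = tu
        accel = None
        for ac in accels:
            if ac.start <= burst_end and ac.end >= burst_start:
                if accel is None or ac.speed_change > accel.speed_change:
                    accel = ac

        bend_duration_total = sum(b.duration for b in grp)
        seg_alpha = series.alpha[burst_start : burst_end + 1]
        seg_t = series.t[burst_start : end + 1]
        seg_v = series.v[burst_start : end + 1]
        good = np.isfinite(seg_v)
        step_length = float(np.trapezoid(seg_v[good], seg_t[good])) if good.sum() >= 2 else 0.0
        step_duration = (end - burst_start) / series.fps
        coast_duration = max(0.0, (end - burst_end) / series.fps)
        seg_k = [b.bend_position for b in grp if np.isfinite(b.bend_position)]
        metrics = dict(
            speed_change=accel.speed_change if accel else np.nan,
            acceleration=accel.acceleration if accel else np.nan,
            turn_angle=turn.turn_angle if turn else np.nan,
            turn_angular_velocity=turn.angular_velocity if turn else np.nan,
            turn_duration=turn.duration if turn else np.nan,
            bend_angle_reached=float(np.nanmax(np.abs(seg_alpha)))
            if np.any(np.isfinite(seg_alpha))
            else np.nan,
            bend_angle_traveled=float(sum(abs(b.delta_alpha) for b in grp)),
            bend_angular_velocity=float(max(b.angular_velocity for b in grp)),
            bend_duration_total=bend_duration_total,
            bend_wave_frequency=len(grp) / bend_duration_total
            if bend_duration_total > 0
            else np.nan,
            coast_duration=coast_duration,
            step_duration=step_duration,
            coast_percent=coast_duration / step_duration if step_duration > 0 else np.nan,
            step_length=step_length,
            n_bends=len(grp),
            bend_position=float(max(seg_k)) if seg_k else np.nan,
        )
        steps.append(
            Step(
                bends=grp,
                turn=turn,
                accel=accel,
                burst_start=burst_start,
                burst_end=burst_end,
                end=int(end),
                metrics=metrics,
            )
        )
    return steps


# ---------------------------------------------------------------------------
# macro summary


def macro_summary(
    series: KinematicSeries,
    bends: list[BendEpisode],
    turns: list[TurnEpisode],
    steps: list[Step],
    arena_polygon: np.ndarray | None = None,
    wall_band_mm: float | None = None,
    centroid_px: np.ndarray | None = None,
    params: GaitParams | None = None,
) -> dict:
    """Whole-recording macro-parameters.

    distance traveled, freezing time, active (non-freezing) mean speed,
    maximum speed, thigmotaxis duration (time spent within the wall band of
    the arena polygon), meandering (total |turn angle| per active second),
    counts/totals of turns and bends with their left/right splits, and the
    step count.
    """
    params = params or GaitParams()
    if series.mm_per_px <= 0 or series.fps <= 0:
        raise ValueError("series must be calibrated")
    dt = 1.0 / series.fps
    v = series.v
    good = np.isfinite(v)
    distance = float(np.nansum(v[good]) * dt)

    freeze = _freeze_runs(series, params)
    freeze_mask = np.zeros(len(series), dtype=bool)
    for a, b in freeze:
        freeze_mask[a : b + 1] = True
    freezing_s = float(freeze_mask.sum() * dt)
    active_mask = good & ~freeze_mask
    active_time = float(active_mask.sum() * dt)
    active_speed = float(np.nanmean(v[active_mask])) if active_mask.any() else 0.0
    max_speed = float(np.nanmax(series.v_raw)) if np.any(np.isfinite(series.v_raw)) else 0.0

    thigmotaxis = float("nan")
    if arena_polygon is not None and centroid_px is not None:
        from shapely.geometry import Point, Polygon

        band_px = (wall_band_mm if wall_band_mm is not None else 25.0) / series.mm_per_px
        poly = Polygon(np.asarray(arena_polygon, dtype=float))
        near = 0
        for p in centroid_px:
            if not np.all(np.isfinite(p)):
                continue
            if poly.exterior.distance(Point(p)) <= band_px:
                near += 1
        thigmotaxis = near * dt

    total_turn_angle = float(sum(abs(t.turn_angle) for t in turns))
    meandering = total_turn_angle / active_time if active_time > 0 else float("nan")

    def _split(items, value, side):
        return float(sum(abs(value(i)) for i in items if i.direction == side))

    summary = dict(
        distance_mm=distance,
        freezing_s=freezing_s,
        active_speed_mm_s=active_speed,
        max_speed_mm_s=max_speed,
        thigmotaxis_s=thigmotaxis,
        meandering_rad_s=meandering,
        turn_count=len(turns),
        total_turn_angle_rad=total_turn_angle,
        total_turn_duration_s=float(sum(t.duration for t in turns)),
        bend_count=len(bends),
        total_bend_angle_rad=float(sum(abs(b.delta_alpha) for b in bends)),
        total_bend_duration_s=float(sum(b.duration for b in bends)),
        step_count=len(steps),
        turn_count_left=sum(1 for t in turns if t.direction == "left"),
        turn_count_right=sum(1 for t in turns if t.direction == "right"),
        total_turn_angle_left=_split(turns, lambda t: t.turn_angle, "left"),
        total_turn_angle_right=_split(turns, lambda t: t.turn_angle, "right"),
        total_turn_duration_left=float(
            sum(t.duration for t in turns if t.direction == "left")
        ),
        total_turn_duration_right=float(
            sum(t.duration for t in turns if t.direction == "right")
        ),
        bend_count_left=sum(1 for b in bends if b.direction == "left"),
        bend_count_right=sum(1 for b in bends if b.direction == "right"),
        total_bend_angle_left=_split(bends, lambda b: b.delta_alpha, "left"),
        total_bend_angle_right=_split(bends, lambda b: b.delta_alpha, "right"),
        total_bend_duration_left=float(
            sum(b.duration for b in bends if b.direction == "left")
        ),
        total_bend_duration_right=float(
            sum(b.duration for b in bends if b.direction == "right")
        ),
    )
    return summary


# ---------------------------------------------------------------------------
# tabular exports


def episodes_frame(
    bends: list[BendEpisode],
    turns: list[TurnEpisode],
    accels: list[AccelEpisode],
    fps: float,
) -> pd.DataFrame:
    """Long-format episode table (one row per episode, typed)."""
    rows = []
    for b in bends:
        rows.append(
            dict(
                type="bend",
                start=b.start,
                end=b.end,
                start_t=b.start / fps,
                end_t=b.end / fps,
                value=b.delta_alpha,
                angular_velocity=b.angular_velocity,
                duration=b.duration,
                bend_position=b.bend_position,
                direction=b.direction,
            )
        )
    for t in turns:
        rows.append(
            dict(
                type="turn",
                start=t.start,
                end=t.end,
                start_t=t.start / fps,
                end_t=t.end / fps,
                value=t.turn_angle,
                angular_velocity=t.angular_velocity,
                duration=t.duration,
                bend_position=np.nan,
                direction=t.direction,
            )
        )
    for a in accels:
        rows.append(
            dict(
                type="accel",
                start=a.start,
                end=a.end,
                start_t=a.start / fps,
                end_t=a.end / fps,
                value=a.speed_change,
                angular_velocity=np.nan,
                duration=(a.end - a.start) / fps,
                bend_position=np.nan,
                direction="",
            )
        )
    return pd.DataFrame(rows)


def steps_frame(steps: list[Step], fps: float) -> pd.DataFrame:
    """One row per step: frame bounds plus all step micro-parameters."""
    rows = []
    for i, s in enumerate(steps):
        row = dict(
            step=i,
            burst_start=s.burst_start,
            burst_end=s.burst_end,
            end=s.end,
            start_t=s.burst_start / fps,
        )
        row.update(s.metrics)
        rows.append(row)
    return pd.DataFrame(rows)
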