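"""Detection and repair of midline-point misplacements.

Fin interference occasionally drops the tail anchor S1 onto the caudal or
pectoral fin for one or a few frames.  Such a misplacement flips the caudal
tangent S1->S2 (and, for pectoral errors, the cranial tangent Sn-1->Sn)
essentially instantaneously, producing frame-to-frame orientation jumps far
beyond anything a real fish does: rapid turns reach per-frame changes of
~18 deg (caudal) and ~40 deg (cranial), while the appearance or resolution
of a misplacement produces jumps above ~117 deg.  A threshold of 57 deg --
17 deg above the quickest genuine movement -- separates the two regimes.

An error run is opened by one super-threshold jump (the appearance) and
closed by the next one within a 5-frame window (the resolution); the frames
strictly between are replaced by linear interpolation from the flanking
clean frames.  An appearance with no resolution inside the window is left
uncorrected (only warned about) to avoid overcorrecting: errors that long
are obvious on the annotated video.

The accuracy index of a segment is the fraction of frames tracked without
detected misplacement, (N - E) / N.  (Stated the other way around as E / N
in some descriptions, but only (N - E) / N is consistent with values like
0.9240 for 456.2 error frames out of 6000, or 1.0 for error-free tracking;
see docs/methods.md.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import segment_orientation, wrap_angle
from .tracker import TrackSeries

__all__ = [
    "ErrorFlags",
    "DEFAULT_JUMP_THRESHOLD_DEG",
    "DEFAULT_MAX_GAP",
    "orientation_series",
    "detect_misplacements",
    "interpolate_midlines",
    "accuracy_index",
    "correct",
]

#: per-frame orientation jump (deg) above which a transition marks the
#: appearance or resolution of a point misplacement
DEFAULT_JUMP_THRESHOLD_DEG = 57.0
#: a resolution must follow the appearance within this many frames
DEFAULT_MAX_GAP = 5


@dataclass
class ErrorFlags:
    """Per-frame error labels and the runs they form.

    ``runs`` holds ``(start, end, corrected)`` with inclusive frame bounds;
    only corrected runs contribute to ``error_frames``.  ``warnings`` lists
    appearances that found no resolution within the gap window.
    """

    error_frames: np.ndarray
    runs: list[tuple[int, int, bool]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_error_frames(self) -> int:
        return int(self.error_frames.sum())


def orientation_series(track: TrackSeries) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame orientations (rad) of the caudal segment S1->S2
    (theta_1->2) and the cranial segment Sn-1->Sn (theta).  NaN where a
    frame is missing or degenerate."""
    th12 = np.full(len(track), np.nan)
    th = np.full(len(track), np.nan)
    for i, fm in enumerate(track.frames):
        if fm.flag == "no_fish" or not np.all(np.isfinite(fm.S)):
            continue
        try:
            th12[i] = segment_orientation(fm.S[0], fm.S[1])
            th[i] = segment_orientation(fm.S[-2], fm.S[-1])
        except ValueError:
            pass
    return th12, th


def detect_misplacements(
    track: TrackSeries,
    threshold_deg: float = DEFAULT_JUMP_THRESHOLD_DEG,
    max_gap: int = DEFAULT_MAX_GAP,
) -> ErrorFlags:
    """Flag frames whose midline points are misplaced.

    A frame transition with |delta theta_1->2| or |delta theta| above the
    threshold marks an error appearance; the next such transition within
    ``max_gap`` frames marks its resolution, and the frames strictly
    between the two transitions are flagged.  Jumps nested inside the
    window extend the run.  An appearance without resolution in the window
    is recorded as a warning only.
    """
    n = len(track)
    if n < 2:
        raise ValueError("need at least 2 frames")
    th12, th = orientation_series(track)
    d12 = wrap_angle(np.diff(th12))
    d = wrap_angle(np.diff(th))
    thr = np.deg2rad(threshold_deg)
    with np.errstate(invalid="ignore"):
        jump = (np.abs(d12) > thr) | (np.abs(d) > thr)
    jump = np.where(np.isfinite(d12) & np.isfinite(d), jump, False)

    flags = np.zeros(n, dtype=bool)
    runs: list[tuple[int, int, bool]] = []
    warnings: list[str] = []
    i = 0
    n_trans = n - 1
    while i < n_trans:
        if not jump[i]:
            i += 1
            continue
        # appearance at transition i -> find the last jump in the window
        window = np.nonzero(jump[i + 1 : min(i + 1 + max_gap, n_trans)])[0]
        if window.size == 0:
            warnings.append(
                f"orientation jump at frame {i}->{i + 1} with no resolution "
                f"within {max_gap} frames; left uncorrected"
            )
            i += 1
            continue
        b = i + 1 + window[-1]  # resolution transition
        flags[i + 1 : b + 1] = True
        runs.append((i + 1, b, True))
        i = b + 1
    return ErrorFlags(error_frames=flags, runs=runs, warnings=warnings)


def interpolate_midlines(track: TrackSeries, flags: ErrorFlags) -> TrackSeries:
    """Replace every point of flagged frames by linear interpolation in
    time between the flanking clean frames.  Runs touching the series
    boundary hold the nearest clean frame instead of extrapolating.
    Unflagged frames are returned bit-identical."""
    out = track.copy()
    n = len(track)
    for start, end, corrected in flags.runs:
        if not corrected:
            continue
        before = start - 1
        after = end + 1
        if before < 0 and after >= n:
            continue  # nothing clean to anchor on
        for f in range(start, end + 1):
            if before < 0:
                src = track.frames[after]
                wa, wb = 0.0, 1.0
            elif after >= n:
                src = track.frames[before]
                wa, wb = 1.0, 0.0
            else:
                wb = (f - before) / (after - before)
                wa = 1.0 - wb
            fm = out.frames[f]
            if before >= 0 and after < n:
                a, b = track.frames[before], track.frames[after]
                fm.C = wa * a.C + wb * b.C
                fm.S = wa * a.S + wb * b.S
                fm.head = wa * a.head + wb * b.head
            else:
                fm.C = src.C.copy()
                fm.S = src.S.copy()
                fm.head = src.head.copy()
            fm.flag = "ok"
    return out


def accuracy_index(error_frame_count: float, total_frames: int) -> float:
    """Fraction of frames tracked without detected misplacement:
    (total - errors) / total."""
    if total_frames <= 0:
        raise ValueError("total_frames must be positive")
    if not (0 <= error_frame_count <= total_frames):
        raise ValueError("error_frame_count must be within [0, total]")
    return (total_frames - error_frame_count) / total_frames


def correct(
    track: TrackSeries,
    threshold_deg: float = DEFAULT_JUMP_THRESHOLD_DEG,
    max_gap: int = DEFAULT_MAX_GAP,
):
    """Detect + interpolate in one call.

    Returns ``(corrected_track, flags, accuracy)`` where ``accuracy`` is
    the pre-correction accuracy index of the segment.
    """
    flags = detect_misplacements(track, threshold_deg=threshold_deg, max_gap=max_gap)
    fixed = interpolate_midlines(track, flags)
    return fixed, flags, accuracy_index(flags.n_error_frames, len(track))
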