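"""Posture tracking: frame -> centroid + midline points + head.

The pipeline mirrors classical silhouette tracking of a dark fish on a
backlit (light) arena:

1. grayscale frame, Gaussian blur for noise reduction;
2. maximum-entropy (Kapur) histogram threshold -- the dark side of the split
   is the fish.  Background subtraction is deliberately *not* performed for
   adults: the translucent pectoral fins then stay with the background class
   and never perturb the midline.  Larvae are too light for this, so their
   channel is a background-subtracted difference image; juveniles run both
   channels in parallel and refine the tail from the subtraction channel;
3. largest connected component -> outer contour;
4. the tail S1 is the "sharpest" contour pixel: the one whose surrounding
   square window contains the fewest foreground pixels.  The head is the
   sharpest point of the proximal half (arc distance from S1 > perimeter/4);
5. the contour is cut at tail and head into two arcs, each arc is sampled at
   equal fractions of its arc length, and matched pairs are averaged into the
   midline points S2..Sn.  S1..Sn are ordered caudal -> cranial.

Coordinates are (x, y) pixels, x right / y down, 0-based frame indices.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

from .geometry import arc_lengths, resample_polyline

__all__ = [
    "TrackerParams",
    "FrameMidline",
    "TrackSeries",
    "NoFishError",
    "max_entropy_threshold",
    "estimate_background",
    "binarize_frame",
    "centroid",
    "largest_contour",
    "window_counts",
    "locate_tail",
    "locate_head",
    "midline_points",
    "refine_tail_juvenile",
    "track",
    "annotate_frame",
]

#: default midline point counts by fish size class
DEFAULT_N_MIDLINE = {
    "large_adult": 10,
    "small_adult": 7,
    "juvenile": 6,
    "larva": 5,
}

_SIZE_CLASS_MODE = {
    "large_adult": "adult",
    "small_adult": "adult",
    "juvenile": "juvenile",
    "larva": "larva",
}


class NoFishError(ValueError):
    """Raised when a frame contains no usable foreground."""


@dataclass
class TrackerParams:
    """Configuration of the posture tracker.

    Parameters
    ----------
    mode:
        ``"adult"`` (threshold only), ``"juvenile"`` (dual channel) or
        ``"larva"`` (background subtraction).
    n_midline:
        Number of midline points S1..Sn.  Defaults by mode: 10 (adult),
        6 (juvenile), 5 (larva); use :meth:`for_size_class` to get the
        7-point small-adult preset.  Any value >= 4 is accepted.
    blur_radius:
        Gaussian blur sigma in px applied before thresholding.
    tail_window:
        Side of the square window (px, odd) used for the sharpness
        statistic; ``None`` selects an area-adaptive default
        ``max(5, 0.15 * sqrt(foreground_area))`` rounded to odd.
    threshold_override:
        Fixed gray level to use instead of the maximum-entropy threshold.
    min_area:
        Foreground components smaller than this (px^2) are treated as
        debris; a frame whose largest component is below it is ``no_fish``.
    background_samples:
        Number of evenly spaced frames sampled for the median background
        (juvenile/larva modes).
    """

    mode: str = "adult"
    n_midline: int | None = None
    blur_radius: float = 1.0
    tail_window: int | None = None
    threshold_override: int | None = None
    min_area: int = 30
    background_samples: int = 21

    def __post_init__(self) -> None:
        if self.mode not in ("adult", "juvenile", "larva"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_midline is None:
            self.n_midline = {"adult": 10, "juvenile": 6, "larva": 5}[self.mode]
        if self.n_midline < 4:
            raise ValueError("n_midline must be >= 4")
        if self.tail_window is not None:
            if self.tail_window < 3 or self.tail_window % 2 == 0:
                raise ValueError("tail_window must be odd and >= 3")

    @classmethod
    def for_size_class(cls, size_class: str, **kwargs) -> "TrackerParams":
        """Preset for ``large_adult`` / ``small_adult`` / ``juvenile`` / ``larva``."""
        if size_class not in DEFAULT_N_MIDLINE:
            raise ValueError(f"unknown size class {size_class!r}")
        kwargs.setdefault("n_midline", DEFAULT_N_MIDLINE[size_class])
        return cls(mode=_SIZE_CLASS_MODE[size_class], **kwargs)


@dataclass
class FrameMidline:
    """Tracked geometry of one frame.

    ``S`` holds the midline points S1..Sn ordered caudal -> cranial
    (``S[0]`` is the tail anchor S1); ``head`` is the extra cranial point
    S_{n+1}.  Failed frames carry NaN coordinates and a non-``ok`` flag.
    """

    frame_index: int
    C: np.ndarray
    S: np.ndarray
    head: np.ndarray
    foreground_area: float = np.nan
    flag: str = "ok"

    @classmethod
    def missing(cls, frame_index: int, n_midline: int, flag: str = "no_fish"):
        nan2 = np.full(2, np.nan)
        return cls(
            frame_index=frame_index,
            C=nan2.copy(),
            S=np.full((n_midline, 2), np.nan),
            head=nan2.copy(),
            foreground_area=0.0,
            flag=flag,
        )

    def copy(self) -> "FrameMidline":
        return FrameMidline(
            frame_index=self.frame_index,
            C=self.C.copy(),
            S=self.S.copy(),
            head=self.head.copy(),
            foreground_area=self.foreground_area,
            flag=self.flag,
        )


@dataclass
class TrackSeries:
    """Time-ordered :class:`FrameMidline` records with calibration."""

    fps: float
    mm_per_px: float
    frames: list[FrameMidline] = field(default_factory=list)
    params: TrackerParams | None = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        idx = [f.frame_index for f in self.frames]
        if idx and list(idx) != list(range(idx[0], idx[0] + len(idx))):
            raise ValueError("frame indices must increase by 1")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_midline(self) -> int:
        return self.frames[0].S.shape[0] if self.frames else 0

    def copy(self) -> "TrackSeries":
        return TrackSeries(
            fps=self.fps,
            mm_per_px=self.mm_per_px,
            frames=[f.copy() for f in self.frames],
            params=dataclasses.replace(self.params) if self.params else None,
        )

    def point_array(self) -> np.ndarray:
        """Stack all tracked points as (n_frames, n_midline + 2, 2):
        columns are C, S1..Sn, head."""
        return np.stack(
            [np.vstack([f.C, f.S, f.head]) for f in self.frames], axis=0
        )


# ---------------------------------------------------------------------------
# thresholding and masks


def max_entropy_threshold(histogram: np.ndarray) -> int:
    """Kapur maximum-entropy threshold of a 256-bin histogram.

    Returns the level T maximizing the sum of Shannon entropies of the two
    classes [0..T] and (T..255] (the ImageJ ``MaxEntropy`` formulation).
    The dark class (values <= T) is the foreground for a dark fish on a
    light background.  Ties break to the smallest level; a histogram with
    fewer than two nonzero bins raises ``ValueError``.
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    if np.count_nonzero(hist) < 2:
        raise ValueError("histogram needs >= 2 nonzero bins to split")
    p = hist / hist.sum()

    plogp = np.where(p > 0, p * np.log(p, where=p > 0, out=np.zeros_like(p)), 0.0)
    w1 = np.cumsum(p)                  # mass of [0..T]
    h1 = np.cumsum(plogp)              # sum p log p over [0..T]
    total_h = h1[-1]

    best_t, best_val = -1, -np.inf
    for t in range(256):
        m1, m2 = w1[t], 1.0 - w1[t]
        if m1 <= 0 or m2 <= 0:
            continue
        ent1 = np.log(m1) - h1[t] / m1
        ent2 = np.log(m2) - (total_h - h1[t]) / m2
        val = ent1 + ent2
        if val > best_val + 1e-12:
            best_val, best_t = val, t
    return best_t


def estimate_background(frames: Sequence[np.ndarray]) -> np.ndarray:
    """Per-pixel median over sampled frames (empty-arena estimate)."""
    frames = [np.asarray(f) for f in frames]
    if len(frames) < 3:
        raise ValueError("need at least 3 sampled frames")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("inconsistent frame sizes")
    stack = np.stack(frames).astype(np.float64)
    return np.median(stack, axis=0).round().astype(frames[0].dtype)


def _threshold_channel(img: np.ndarray, params: TrackerParams, dark: bool):
    """Blur + maximum-entropy threshold; returns (mask, blurred image).

    A 3x3 binary closing + opening smooths the mask boundary: pixels of the
    faint halo around the fish sit exactly at the threshold, so sensor
    noise otherwise flips them frame to frame and jitters the contour.
    """
    blurred = ndimage.gaussian_filter(img.astype(float), params.blur_radius)
    blurred = np.clip(np.round(blurred), 0, 255).astype(np.uint8)
    if params.threshold_override is not None:
        level = int(params.threshold_override)
    else:
        hist = np.bincount(blurred.ravel(), minlength=256)
        level = max_entropy_threshold(hist)
    mask = blurred <= level if dark else blurred > level
    structure = np.ones((3, 3), dtype=bool)
    mask = ndimage.binary_opening(ndimage.binary_closing(mask, structure), structure)
    return mask, blurred


def _threshold_mask(img: np.ndarray, params: TrackerParams, dark: bool) -> np.ndarray:
    return _threshold_channel(img, params, dark)[0]


def binarize_frame(
    gray: np.ndarray,
    params: TrackerParams,
    background: np.ndarray | None = None,
):
    """Foreground mask(s) of one frame.

    adult -> single mask (blur + threshold, dark side).
    larva -> single mask from the background-subtracted difference image.
    juvenile -> ``(mask_main, mask_subtracted)`` tuple: the direct channel
    plus the subtraction channel used for tail refinement.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("binarize_frame expects a single-channel image")
    if params.mode == "adult":
        return _threshold_mask(gray, params, dark=True)
    if background is None:
        raise ValueError(f"mode {params.mode!r} requires a background image")
    diff = np.clip(background.astype(int) - gray.astype(int), 0, 255).astype(np.uint8)
    mask_sub = _threshold_mask(diff, params, dark=False)
    if params.mode == "larva":
        return mask_sub
    mask_main = _threshold_mask(gray, params, dark=True)
    return mask_main, mask_sub


def centroid(mask: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Center of mass (x, y) of the foreground.

    Without ``weights``: the arithmetic mean of foreground pixel
    coordinates.  With a per-pixel weight image (the tracking pipeline
    passes pigment darkness, background level minus gray): the weighted
    mean, which discounts the faint threshold halo around the body and
    lands on the silhouette's true center of mass.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise NoFishError("empty mask has no centroid")
    if weights is None:
        return np.array([cols.mean(), rows.mean()])
    w = np.clip(weights[rows, cols].astype(float), 0.0, None)
    total = w.sum()
    if total <= 0:
        return np.array([cols.mean(), rows.mean()])
    return np.array([(cols * w).sum() / total, (rows * w).sum() / total])


def largest_contour(mask: np.ndarray, min_area: int = 1):
    """Outer contour of the largest connected foreground component.

    Returns ``(contour, component_mask)`` where ``contour`` is an ordered
    (m, 2) array of (x, y) points tracing the component outline (closed
    implicitly; the duplicate endpoint is dropped).  Smaller components are
    discarded as debris.
    """
    labels, n = ndimage.label(mask)
    if n == 0:
        raise NoFishError("empty mask")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1
    if sizes[biggest - 1] < min_area:
        raise NoFishError("largest component below min_area")
    comp = labels == biggest
    contours = measure.find_contours(comp.astype(float), 0.5)
    if not contours:  # pragma: no cover - comp is nonempty
        raise NoFishError("no contour found")
    contour_rc = max(contours, key=lambda c: arc_lengths(c)[-1])
    if np.allclose(contour_rc[0], contour_rc[-1]):
        contour_rc = contour_rc[:-1]
    if contour_rc.shape[0] < 8:
        raise NoFishError("degenerate contour (< 8 points)")
    contour_xy = contour_rc[:, ::-1].copy()
    return contour_xy, comp


def window_counts(mask: np.ndarray, points: np.ndarray, window: int) -> np.ndarray:
    """Foreground pixel count inside a window x window square centered on
    each point (points in (x, y); window odd).  Windows are clipped at the
    image border."""
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    ii = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.int64)
    ii[1:, 1:] = np.cumsum(np.cumsum(mask.astype(np.int64), axis=0), axis=1)
    half = window // 2
    cx = np.clip(np.round(points[:, 0]).astype(int), 0, mask.shape[1] - 1)
    cy = np.clip(np.round(points[:, 1]).astype(int), 0, mask.shape[0] - 1)
    r0 = np.clip(cy - half, 0, mask.shape[0])
    r1 = np.clip(cy + half + 1, 0, mask.shape[0])
    c0 = np.clip(cx - half, 0, mask.shape[1])
    c1 = np.clip(cx + half + 1, 0, mask.shape[1])
    return ii[r1, c1] - ii[r0, c1] - ii[r1, c0] + ii[r0, c0]


def default_tail_window(foreground_area: float) -> int:
    """Area-adaptive sharpness window: max(9, 0.5 sqrt(area)), odd.

    The window scales with the silhouette so the statistic discriminates
    comparably across fish sizes; at roughly one body width it separates a
    genuine extremity from small contour bumps.
    """
    w = max(9, int(round(0.5 * np.sqrt(max(foreground_area, 0.0)))))
    return w if w % 2 == 1 else w + 1


def locate_tail(
    contour: np.ndarray,
    mask: np.ndarray,
    tail_window: int,
    candidates: np.ndarray | None = None,
):
    """Index (and tie flag) of the sharpest contour point.

    The sharpest point minimizes the foreground count inside the square
    window -- the tail, being the thinnest body part, has the smallest
    surrounding foreground area.  ``candidates`` restricts the search to a
    boolean subset of contour indices.  Ties resolve to the smallest contour
    index; the second return value signals an *ambiguous* tie, i.e. one
    between points farther apart than the window itself (adjacent-pixel
    ties along a sharp tip are benign and not flagged).
    """
    if contour.shape[0] < 8:
        raise NoFishError("degenerate contour (< 8 points)")
    counts = window_counts(mask, contour, tail_window)
    if candidates is not None:
        if not np.any(candidates):
            raise NoFishError("no candidate contour points")
        counts = np.where(candidates, counts, np.iinfo(np.int64).max)
    best = int(np.argmin(counts))
    tied = np.nonzero(counts == counts[best])[0]
    d = np.hypot(
        contour[tied, 0] - contour[best, 0], contour[tied, 1] - contour[best, 1]
    )
    tie = bool(np.any(d > tail_window))
    return best, tie


def refine_extremity(
    contour: np.ndarray, counts: np.ndarray, index: int, window: int
) -> np.ndarray:
    """Sub-pixel position of an extremity (tail or snout tip).

    The window statistic is flat over a rounded tip, so the plain argmin
    wanders around the cap; averaging nearby contour points weighted by
    their sharpness margin centers the anchor on the tip.  Falls back to
    the argmin vertex when the neighborhood is degenerate (e.g. a circle,
    where every point ties).
    """
    m = contour.shape[0]
    idx = np.arange(index - window, index + window + 1) % m
    c = counts[idx].astype(float)
    wt = np.clip(c.max() - c, 0.0, None) ** 2
    total = wt.sum()
    if total <= 0:
        return contour[index].copy()
    return (contour[idx] * wt[:, None]).sum(axis=0) / total


def locate_head(contour: np.ndarray, tail_index: int, mask: np.ndarray, tail_window: int):
    """Sharpest point of the proximal half of the contour.

    Proximal = arc distance from S1 along the contour (both directions)
    greater than a quarter of the perimeter, which excludes the caudal end
    around the tail point.
    """
    closed = np.vstack([contour, contour[:1]])
    s = arc_lengths(closed)
    perimeter = s[-1]
    d = np.abs(s[:-1] - s[tail_index])
    arc_dist = np.minimum(d, perimeter - d)
    candidates = arc_dist > perimeter / 4.0
    if not np.any(candidates):
        raise NoFishError("proximal half of the contour is empty")
    return locate_tail(contour, mask, tail_window, candidates=candidates)


def midline_points(
    contour: np.ndarray,
    tail_index: int,
    head_index: int,
    n_midline: int,
    tail_point: np.ndarray | None = None,
    head_point: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Midline points S1..Sn plus the head point S_{n+1}.

    The contour is cut at the tail and head into two arcs.  Each arc is
    parameterized by its normalized arc length from the tail and sampled at
    fractions j/n (j = 1..n-1); matched pairs are averaged into S2..Sn.
    S1 is the tail anchor and S_{n+1} the head anchor (``tail_point`` /
    ``head_point`` override the contour vertices, e.g. for sub-pixel
    refined tips or the juvenile S0 refinement).
    """
    if tail_index == head_index:
        raise ValueError("tail and head coincide")
    m = contour.shape[0]
    # arc A walks the contour forward from tail to head, arc B backward;
    # both are ordered tail -> head so normalized arc position matches up
    if head_index > tail_index:
        ia = np.arange(tail_index, head_index + 1)
        ib = np.r_[np.arange(tail_index, -1, -1), np.arange(m - 1, head_index - 1, -1)]
    else:
        ia = np.r_[np.arange(tail_index, m), np.arange(0, head_index + 1)]
        ib = np.arange(tail_index, head_index - 1, -1)
    arc_a = contour[ia]
    arc_b = contour[ib]
    if arc_a.shape[0] < 2 or arc_b.shape[0] < 2:
        raise ValueError("zero-length contour arc")
    fractions = np.arange(1, n_midline) / n_midline
    pa = resample_polyline(arc_a, fractions)
    pb = resample_polyline(arc_b, fractions)
    mid = 0.5 * (pa + pb)
    s1 = contour[tail_index] if tail_point is None else np.asarray(tail_point, float)
    S = np.vstack([s1, mid])
    head = contour[head_index].copy() if head_point is None else np.asarray(head_point, float)
    return S, head


def refine_tail_juvenile(
    mask_main: np.ndarray,
    mask_sub: np.ndarray,
    s1: np.ndarray,
    head: np.ndarray | None = None,
    tail_window: int | None = None,
):
    """More distal tail anchor S0 from the subtraction channel.

    The direct (no-subtraction) channel erodes a light juvenile tail, so its
    S1 sits too proximal.  The subtraction channel retains the light tail
    tip; its sharpest contour point *distal* to S1 (farther from the head,
    or from the body center when no head is given) replaces S1.  Contour
    points proximal to S1 are excluded, so pectoral lobes present in the
    subtraction channel are never selected.  Falls back to S1 (with a
    low-confidence signal) when no distal candidate exists.

    Returns ``(s0, refined_flag)``.
    """
    s1 = np.asarray(s1, dtype=float)
    try:
        contour, comp = largest_contour(mask_sub)
    except NoFishError:
        return s1.copy(), False
    ref = np.asarray(head, float) if head is not None else centroid(mask_main)
    d_s1 = np.hypot(*(s1 - ref))
    d = np.hypot(contour[:, 0] - ref[0], contour[:, 1] - ref[1])
    candidates = d > d_s1
    if not np.any(candidates):
        return s1.copy(), False
    if tail_window is None:
        tail_window = default_tail_window(comp.sum())
    idx, _ = locate_tail(contour, comp, tail_window, candidates=candidates)
    return contour[idx].copy(), True


# ---------------------------------------------------------------------------
# whole-video tracking


def _track_single_frame(
    gray: np.ndarray,
    params: TrackerParams,
    frame_index: int,
    background: np.ndarray | None,
):
    """Returns (FrameMidline, contour or None)."""
    try:
        return _track_single_frame_inner(gray, params, frame_index, background)
    except ValueError:
        # e.g. a blank frame whose histogram cannot be split
        return FrameMidline.missing(frame_index, params.n_midline), None


def _track_single_frame_inner(
    gray: np.ndarray,
    params: TrackerParams,
    frame_index: int,
    background: np.ndarray | None,
):
    if params.mode == "adult":
        mask, blurred = _threshold_channel(gray, params, dark=True)
        mask_sub = None
    elif params.mode == "larva":
        diff = np.clip(background.astype(int) - gray.astype(int), 0, 255).astype(np.uint8)
        mask, blurred = _threshold_channel(diff, params, dark=False)
        blurred = 255 - blurred  # darkness weighting expects dark = fish
        mask_sub = None
    else:  # juvenile: dual channel
        mask, blurred = _threshold_channel(gray, params, dark=True)
        diff = np.clip(background.astype(int) - gray.astype(int), 0, 255).astype(np.uint8)
        mask_sub = _threshold_mask(diff, params, dark=False)
    if mask.sum() < params.min_area:
        return FrameMidline.missing(frame_index, params.n_midline), None
    try:
        contour, comp = largest_contour(mask, min_area=params.min_area)
    except NoFishError:
        return FrameMidline.missing(frame_index, params.n_midline), None
    area = float(comp.sum())
    # pigment-weighted center of mass: weight = background level - gray
    bg_level = float(np.median(blurred[~mask])) if (~mask).any() else 255.0
    c = centroid(comp, weights=bg_level - blurred.astype(float))
    w = params.tail_window or default_tail_window(area)
    try:
        i_tail, tie_t = locate_tail(contour, comp, w)
        i_head, tie_h = locate_head(contour, i_tail, comp, w)
        counts = window_counts(comp, contour, w)
        tail_point = refine_extremity(contour, counts, i_tail, w)
        head_point = refine_extremity(contour, counts, i_head, w)
        # cut the contour at the vertices nearest the refined tips: the
        # refined anchors are stable where the raw argmin jitters along a
        # rounded cap, and a stable cut keeps the near-anchor midline
        # points reproducible
        i_tail = int(np.argmin(np.hypot(*(contour - tail_point).T)))
        i_head = int(np.argmin(np.hypot(*(contour - head_point).T)))
        if i_tail == i_head:
            raise NoFishError("tail and head collapse onto one vertex")
        if params.mode == "juvenile" and mask_sub is not None:
            s0, refined = refine_tail_juvenile(
                comp, mask_sub, tail_point, head=head_point, tail_window=w
            )
            if refined:
                tail_point = s0
        S, head = midline_points(
            contour, i_tail, i_head, params.n_midline, tail_point, head_point
        )
    except (NoFishError, ValueError):
        return FrameMidline.missing(frame_index, params.n_midline, flag="low_confidence"), contour
    flag = "low_confidence" if (tie_t or tie_h) else "ok"
    fm = FrameMidline(
        frame_index=frame_index,
        C=c,
        S=S,
        head=head,
        foreground_area=area,
        flag=flag,
    )
    return fm, contour


def track(
    frames: Sequence[np.ndarray] | np.ndarray,
    params: TrackerParams,
    fps: float,
    mm_per_px: float,
    annotate: bool = False,
):
    """Track every frame of a video (a sequence of 2-D grayscale arrays).

    Returns a :class:`TrackSeries` with exactly one :class:`FrameMidline`
    per input frame -- frames that fail any stage are flagged, never
    dropped.  With ``annotate=True`` also returns the list of annotated RGB
    frames (contour in a red->green gradient, midline points tail->head in
    a yellow->blue gradient, centroid as a larger yellow dot).
    """
    frames = [np.asarray(f) for f in frames]
    if not frames:
        raise ValueError("no frames to track")
    background = None
    if params.mode in ("juvenile", "larva"):
        step = max(1, len(frames) // params.background_samples)
        sample = frames[::step][: params.background_samples]
        while len(sample) < 3:
            sample = sample + [frames[-1]]
        background = estimate_background(sample)

    records: list[FrameMidline] = []
    annotated: list[np.ndarray] = []
    for i, gray in enumerate(frames):
        fm, contour = _track_single_frame(gray, params, i, background)
        records.append(fm)
        if annotate:
            annotated.append(annotate_frame(gray, fm, contour))
    series = TrackSeries(fps=fps, mm_per_px=mm_per_px, frames=records, params=params)
    if annotate:
        return series, annotated
    return series


def annotate_frame(
    gray: np.ndarray, fm: FrameMidline, contour: np.ndarray | None
) -> np.ndarray:
    """RGB overlay of contour, midline points and centroid on one frame."""
    rgb = np.repeat(np.asarray(gray)[..., None], 3, axis=2).astype(np.uint8)
    h, wdt = gray.shape

    def _dot(pt, color, radius):
        if not np.all(np.isfinite(pt)):
            return
        x, y = int(round(pt[0])), int(round(pt[1]))
        yy, xx = np.ogrid[
            max(0, y - radius) : min(h, y + radius + 1),
            max(0, x - radius) : min(wdt, x + radius + 1),
        ]
        d = (yy - y) ** 2 + (xx - x) ** 2 <= radius**2
        rgb[max(0, y - radius) : min(h, y + radius + 1),
            max(0, x - radius) : min(wdt, x + radius + 1)][d] = color

    if contour is not None and contour.size:
        m = contour.shape[0]
        cols = np.round(np.clip(contour[:, 0], 0, wdt - 1)).astype(int)
        rows = np.round(np.clip(contour[:, 1], 0, h - 1)).astype(int)
        frac = np.arange(m) / max(m - 1, 1)
        rgb[rows, cols, 0] = np.round(255 * (1 - frac)).astype(np.uint8)
        rgb[rows, cols, 1] = np.round(255 * frac).astype(np.uint8)
        rgb[rows, cols, 2] = 0
    if fm.flag != "no_fish":
        n = fm.S.shape[0]
        for j, pt in enumerate(fm.S):
            frac = j / max(n - 1, 1)  # tail yellow -> head blue
            color = (
                int(round(255 * (1 - frac))),
                int(round(255 * (1 - frac))),
                int(round(255 * frac)),
            )
            _dot(pt, color, 1)
        _dot(fm.head, (0, 0, 255), 1)
        _dot(fm.C, (255, 255, 0), 3)
    return rgb
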