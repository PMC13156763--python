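# Methods

`fishgait` quantifies the locomotion of a single fish filmed from above on
a backlit (light) arena. This note documents the models, the algorithms,
the parameters that matter, and the choices made where the design was
genuinely open.

## Posture model

The fish's position is its center of mass C. Its posture is an ordered set
of midline points S1..Sn from the tail (S1, near the base of the caudal
fin) to the cranium, plus a head point S(n+1). The number of midline
points scales with the animal: 10 for large adults, 7 for small adults, 6
for juveniles, 5 for larvae (any n >= 4 is accepted).

Four per-frame quantities derive from the points:

* **speed** `v = |ΔC| · fps · mm/px` (mm/s);
* **orientation** `θ`: the direction of the cranial segment S(n−1)→Sn,
  unwrapped over time so turns accumulate;
* **bend angle** `α`: the signed angle from the cranial tangent
  (S(n−1)→Sn) to the caudal tangent (S1→S2). Straight body: α = 0; the
  magnitude grows with lateral flexion;
* **bend position** `k ∈ [0, 1]`: the fraction of body length from the
  tail at which flexion begins. Walking from the head toward the tail,
  the first midline segment whose tangent deviates from the cranial axis
  by more than a tolerance (default 10°) marks the flexion point; k is its
  arc-length fraction from the tail. A nine-point midline flexed from the
  7th point from the tail gives k = 6/8 = 0.75 exactly. A straight
  midline has no bend position (NaN).

### Sign conventions

One geometric convention is used package-wide: angles are measured as a
viewer of the printed frame reads them, counter-clockwise positive, which
with image y pointing down means `angle = atan2(−Δy, Δx)`. The bend angle
is **left-positive** (a tail swung to the fish's left gives α > 0). Turn
and bend *directions* are reported as left/right labels derived from the
sign of the angle change (positive = left); all detection thresholds act
on magnitudes, so no segmentation decision depends on the convention.
Mirroring a recording exactly negates α and the θ increments and swaps
every left/right label.

## Tracking pipeline (adult mode)

1. **Grayscale + Gaussian blur.** Default σ = 1 px. The blur suppresses
   sensor noise before histogram thresholding. A larger blur widens the
   near-threshold halo around the fish (see below) and costs point
   accuracy, so the default is deliberately small.
2. **Maximum-entropy threshold** (Kapur's criterion, the ImageJ
   `MaxEntropy` formulation): the gray level T maximizing the sum of
   Shannon entropies of the two classes [0..T] and (T..255]. The dark
   class is the fish. An exhaustive search over all 256 candidate levels
   is the built-in test oracle.

   Two properties of this objective shape the rest of the design:

   * On a backlit arena the optimum lands just below the background's
     intensity distribution. The binary mask therefore includes a faint
     *halo* -- the outer part of the blurred edge ramp -- about 1.5–2 px
     wide at σ = 1.
   * The threshold separates the pigmented body from everything at
     near-background intensity. Translucent pectoral fins, which on a
     backlit arena image only slightly darker than the water, fall in the
     background class and never enter the silhouette. This is the reason
     background subtraction is deliberately *not* performed for adults:
     a subtracted image would make the fins visible to the threshold.
     Mid-gray structures, by contrast, would always join the foreground
     class -- fin exclusion works precisely because real fins are nearly
     transparent, and the synthetic fins are rendered accordingly.
3. **Mask cleanup.** A 3×3 binary closing then opening. Halo pixels sit
   exactly at the threshold, so noise otherwise flips them frame to frame
   and jitters the contour.
4. **Largest component & contour.** Smaller components are debris. The
   outer contour is traced at sub-pixel resolution; a frame whose largest
   component is below `min_area` (default 30 px²) is flagged `no_fish`
   (never dropped).
5. **Center of mass.** The pipeline weights each foreground pixel by its
   pigment darkness (background level minus gray), which discounts the
   faint halo and lands within ~0.5 px of the true silhouette centroid;
   the unweighted pixel mean is biased toward halo-heavy regions by about
   a pixel. Both forms are exposed (`centroid(mask)` is the plain mean).
6. **Tail.** For every contour point, count the foreground pixels inside
   a square window centered on it (an integral image makes this O(1) per
   point). The tail is the sharpest point -- the minimum count -- because
   the caudal peduncle is the thinnest part of the body. The window side
   adapts to the animal: `max(9, 0.5·√area)`, rounded odd, roughly one
   body width; smaller windows cannot tell a genuine extremity from a
   contour bump. Ties resolve to the smallest contour index; a tie
   between points farther apart than the window (e.g. a circular mask)
   flags the frame `low_confidence`.
7. **Head.** The same statistic, restricted to the proximal half of the
   contour: points whose arc distance from S1 (both ways) exceeds a
   quarter of the perimeter. Because both tips are rounded, the raw
   argmin wanders along the tip cap; the anchor is refined to the
   sharpness-margin-weighted average of contour points near the argmin
   (sub-pixel), and the contour is cut at the vertex nearest the refined
   anchor so the cut is reproducible.
8. **Midline.** The contour is cut at tail and head into two arcs, each
   parameterized by normalized arc length from the tail and sampled at
   fractions j/n (j = 1..n−1). Midpoints of matched pairs give S2..Sn;
   S1 is the (refined) tail anchor, S(n+1) the head anchor. Pairing by
   normalized position keeps the construction valid when the two arcs
   have unequal lengths.

**Juvenile mode** runs two binarizations in parallel: the direct channel
(as above) and a background-subtracted channel. Direct thresholding erodes
a juvenile's lighter tail, so its S1 sits too proximal; the sharpest point
of the subtraction-channel contour *distal* to S1 (farther from the head)
replaces it (S0). Contour points proximal to S1 -- including pectoral
lobes that reappear in the subtracted image -- are never candidates.
**Larva mode** uses the subtraction channel alone (per-pixel median of
sampled frames as the background estimate), since a larva's body is too
light for direct thresholding.

## Error detection and correction

Fin interference occasionally drops S1 onto the caudal or pectoral fin for
one or a few frames. Such a misplacement flips the caudal tangent
orientation θ(1→2) (and, for pectoral errors, the cranial θ) essentially
instantaneously. Genuine rapid turns change these orientations by at most
~18° (caudal) and ~40° (cranial) per frame at 100 fps, while the
appearance or resolution of a misplacement jumps well above 100°. The
detector flags a transition when either |Δθ(1→2)| or |Δθ| exceeds **57°**
(17° above the fastest genuine movement); the next super-threshold
transition within **5 frames** is the resolution, and the frames strictly
between are errors. Jumps nested inside the window extend the run. An
appearance with no resolution inside the window is only warned about --
runs that long are left for the researcher to inspect on the annotated
video rather than risk overcorrection.

Every point (C, S1..Sn, head) of a flagged frame is replaced by linear
interpolation in time between the flanking clean frames; runs touching the
series boundary hold the nearest clean frame. Unflagged frames are
bit-identical after correction, and re-running detection on a corrected
series finds nothing (idempotence, verified on every injected scenario).

The **accuracy index** of a segment is the fraction of frames tracked
without detected misplacement, AI = (N − E)/N. It is sometimes stated the
other way around (E/N), but only (N − E)/N is consistent with an index of
1.0 for error-free tracking and with 0.9240 for a mean of 456.2 error
frames in a 6000-frame segment; this package uses the consistent form
throughout.

## Burst-and-coast segmentation

Fish swim in discrete *steps*: a short series of tail bends (the burst)
that produces an acceleration and/or a turn, followed by a passive coast.

* **Bends** are maximal monotone sweeps of α between significant extrema
  (prominence ≥ the minimum bend amplitude, default 5°). A near-neutral
  *plateau* (|α| small for ≥ 3 frames) between extrema separates two
  sweeps; a mere zero transit does not. Sweep boundaries get sub-frame
  times -- parabolic interpolation at extrema, quadratic-root
  extrapolation of the departing/arriving limb at neutral boundaries --
  because at 100 fps a 2–4-bend burst spans only a handful of frames and
  frame-quantized durations cannot resolve the bend-wave frequency
  (residual per-step error at this sampling is up to ~8%; per-recording
  means recover the scripted frequency within a few percent).
* **Turns** are maximal intervals with |dθ/dt| above 30°/s (gaps ≤ 2
  frames merged) whose net angle reaches 10°.
* **Accelerations** are trough-to-peak upslopes of the speed (smoothed by
  a centered 5-frame moving average; the raw trace keeps the maximum
  speed) with a speed change of at least 5 mm/s.
* **Steps**: consecutive bends closer than 0.15 s share a burst;
  overlapping turns/accelerations attach to it; the coast runs to the
  next step's start (the final step coasts until speed bottoms out or the
  series ends), and a freezing onset inside the coast ends the step
  there. The obligatory return bend that brings the tail back to neutral
  belongs to the same series by construction and never starts a step.

Each step carries 14 micro-parameters: speed change, acceleration, turn
angle, turn angular velocity, turn duration, bend angle reached, bend
angle traveled, bend angular velocity, total bend duration, bend wave
frequency (bend count / total bend duration), coast duration, step
duration, coast percent, and step length (∫v dt over the step), plus the
bend count and the maximum bend position as auxiliary columns. (Published
descriptions of this analysis style count "13" in one place and "14" in
another; all step metrics listed above are implemented, and the exposed
table simply contains them all.)

Macro-parameters summarize a whole recording: distance traveled, freezing
time (v < 1 mm/s sustained ≥ 1 s), active (non-freezing) mean speed,
maximum speed, thigmotaxis duration (time within one body length of the
arena boundary, via the arena polygon), meandering (total |turn angle| per
active second, in rad/s -- a per-distance variant is a config option),
counts/totals of turns and bends, step count, and the left/right split of
every lateralized total.

## Group statistics

Steps are nested in fish, fish in groups. Each comparison fits a linear
mixed model -- a fixed group effect plus a per-fish random intercept, by
REML -- and refers the Wald statistic of the group coefficient to a t
distribution with `n_fish − 2` degrees of freedom. The group contrast is
a *between-fish* comparison, so its effective degrees of freedom are set
by the number of animals, not the number of steps; the asymptotic normal
reference is anticonservative at typical cohort sizes (empirically ~8%
type-I error at α = 0.05 with 13 fish, vs ~4% for the between-cluster t
reference, 500 null simulations). Fits that are singular or lack two fish
per group fall back to a fish-mean Welch comparison with a prominent
warning. Raw per-comparison p-values are reported by default; a
Benjamini–Hochberg option exists but is off.

**Stratification** is per fish: each fish's steps are cut at its own first
and third quartiles of the stratifying parameter (type-7 linear
interpolation quantiles; ≤ Q1 → low, ≥ Q3 → high, else mid; degenerate
spread → all mid; fish with < 4 usable steps → all mid with a warning).
Strata are then compared separately, which localizes effects confined to,
e.g., the most vigorous steps -- the simulation suite verifies ≥ 80% power
in the high stratum and near-nominal rejection in the low stratum when the
effect lives only in top-quartile speed changes.

**Asymmetry** of any lateralized parameter is (R − L)/(R + L) on per-side
magnitudes (+1 fully right-biased, −1 fully left, NaN when both sides are
zero), computed on per-side means or totals.

## Synthetic fixtures: what they emulate, and what not

The generator renders a dark elongated silhouette on a light arena: a disc
sweep along an exact midline whose cranial part is straight and whose
distal part is a uniformly curved arc beginning at the bend position, so
the bend angle and bend position of every rendered pose are known in
closed form. The width profile ends caudally at a finite-width peduncle
(the translucent caudal fin is not part of the silhouette) and narrows
slightly at the snout; the returned ground-truth midline runs tip to tip
of the rounded end caps (the medial axis of the rendered solid), which is
the honest reference for contour-anchored points. Pectoral fins are two
lobes attached at the body edge sweeping backward, rendered at gray 226 on
a 230 background -- barely darker than water, as real translucent fins
image on a backlit arena. Default conditions add Gaussian sensor noise
(σ = 2 gray levels), a vertical illumination gradient (±6), and 2×
antialiasing.

These conditions are not cosmetic: histogram-based maximum-entropy
thresholding is only well posed when the background has realistic spread.
On an ideal noise-free render the optimum degenerates to just below the
background spike and floods the mask with halo and fins; with realistic
background statistics it lands at the background's lower shoulder and
behaves exactly as described above. Validation against the generator
therefore certifies the pipeline *under realistic imaging statistics*; it
does not certify performance on artifacts the generator does not model:
water-surface reflections, shadows, occlusions, non-uniform pigmentation,
multiple animals, or z-axis (depth) behavior.

Scripted swimming follows the burst-and-coast causal structure: per step,
α is a half-period-wise damped sinusoid (damping ratio 0.8 per lobe, first
lobe exactly at the scripted peak; n monotone sweeps span (n−1)
half-periods), speed rises smoothly by the scripted gain during the burst
and decays exponentially through the coast (time constant = coast
duration / 3), θ ramps by the scripted turn angle during the burst, and k
is constant within the step. The randomized script generator draws 2–4
bends per step at 10–18 Hz bend-wave rates, peaks 15–40°, turns up to
±60°, and speed gains 30–120 mm/s -- adult exploratory swimming that a
100 fps recording resolves at ≥ 5–6 samples per oscillation period.
Injected tracking errors displace S1 (tail-fin mode: S1 reflected past S2,
flipping only the caudal tangent) or rebuild the midline from a pectoral
locus (pectoral-fin mode, disrupting both tangents), reproducing the two
fin-interference failure modes the corrector exists for.

## Numerical choices and degenerate inputs

* Calibration: mm/px = physical arena width / pixel width of the arena
  polygon's bounding box. Frame indices are 0-based; time = frame / fps;
  pixel coordinates x-right, y-down from the crop's top-left. All output
  tables document units in commented headers.
* Angle wrap: differences live in (−π, π]; the unwrap steps over missing
  (NaN) frames.
* Empty masks, blank frames, single-bin histograms, degenerate contours
  (< 8 points) and collapsing tail/head cuts all flag the frame
  (`no_fish` / `low_confidence`) instead of raising, so a series always
  has one record per frame.
* Determinism: every stochastic stage takes a seed (scripts carry their
  own); identical seeds give bit-identical videos, ground truth and
  tables.

## Known limitations

* 2-D only: diving and hovering are invisible from the top view.
* The tracker assumes one animal, darker than the background, on a
  mostly uniform backlit arena.
* Pectoral-fin kinematics are invisible by design (the threshold removes
  the fins).
* Bend-wave frequencies approaching a quarter of the frame rate are at
  the resolution limit of sweep timing; per-step frequency estimates
  carry up to ~8% quantization error at 100 fps.
* The mixed model assumes Gaussian step-level noise and a common
  within-group variance; heavy-tailed micro-parameters may warrant a
  transformation first.
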