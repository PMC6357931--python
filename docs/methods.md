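# Methods

`coroflow` estimates coronary blood-flow velocity from a cine X-ray
angiography sequence alone, by tracking how fast the contrast dye fills
the artery tree. This note documents the model, the algorithmic choices,
the synthetic phantom used for validation, and the limits of what the
validation shows.

## Physical model

Blood in medium coronary arteries is treated as an incompressible fluid
in branching pipes. With flow rate Q conserved across a bifurcation and
all cross-sections assumed equal (A_i = A, the constant-area assumption),

    Q = n1 · A · v1 = n2 · A · v2   =>   v2 = v1 · n1 / n2,

so the dye front slows by half at every two-way bifurcation — but the
*summed* centerline length of dye-covered vessel keeps growing at the
pre-branch speed v1. This is the key identity behind the primary
estimator: over the dye-propagation window [t_s, t_max],

    Mlength:  v_est = ΔL_T / ΔT   [m/s],

where ΔL_T is the growth of the skeletonized (centerline) length of the
segmented tree and ΔT = (t_max − t_s)/fps. A surrogate, Mslope, is the
mean slope of the fitted segmented-area polynomial over the same window,
in pixel-area per frame interval; it correlates with velocity but needs a
typical vessel diameter to convert to m/s, so it is reported as-is.

Vessels not tangential to the projection plane are foreshortened, which
can only shorten the projected skeleton: the estimator underestimates in
that case, monotonically in the tilt (verified as a property test).

## Pipeline

1. **Preprocessing.** Each 8-bit frame is unsharp-masked:
   I_s = I − (I ⊛ f_laplace) with the 3×3 four-neighbour Laplacian and
   replicate borders. This sharpens vessel edges and passes smooth
   organ-shadow gradients through unchanged.
2. **Initial segmentation.** Multiscale Hessian vesselness tuned for dark
   tubes: per scale σ ∈ {2, 3, 4} px the γ-normalized (σ²-scaled) Hessian
   eigenvalues |λ1| ≤ |λ2| give a blobness ratio R_b = |λ1|/|λ2| and
   structureness S; the response
   exp(−R_b²/2α²)·(1 − exp(−S²/2c²)) is zeroed where λ2 ≤ 0 (explicit
   dark-tube polarity gate; scales below 2 px are omitted because they
   lock onto the 1-px ringing that unsharp masking introduces at edges).
   α = 0.5; c defaults to half the per-scale maximum structureness. The
   per-frame map is rescaled to max 1, thresholded at th = 0.15, opened
   (disk 1), closed (disk 2), and reduced to its largest 8-connected
   component — the artery tree, normally connected to the catheter.
3. **Heart-motion registration.** Consecutive segmented frames are
   aligned with a 2D affine (6 DOF — the 2D analogue of the 12-DOF 3D
   affine, since frames are projections) followed by a cubic B-spline
   free-form deformation, scored by mutual information. Binary masks make
   an entropy objective nearly degenerate, so the masks are smoothed
   (Gaussian, σ = 2 px) into soft maps for scoring; binary masks are
   resampled (nearest-neighbour) only when a transform is applied.
   Reported similarity is NMI = (H(A)+H(B))/H(A,B) ∈ [1, 2], computed
   in-package from a 32-bin joint histogram; the optimizer itself climbs
   Mattes mutual information, which the backend supports and which is
   monotonically related. Frame k is registered onto frame k−1 (earlier
   frame fixed) so dye growth appears as *added* pixels.
4. **Iterative refinement.** For each aligned pair the signed pixel-count
   difference d = Σ(B^k − B^{k−1}) should equal one frame of dye growth;
   the satisfaction band accepts 500 ≤ d ≤ 1500 px at 0.2 mm/pixel
   (scaled by (0.2/spacing)² for other pixel sizes — the band reflects
   physical growth per frame, not the field of view). For a failing pair,
   both frames are re-thresholded at th − 0.02 (floor 0.02) and newly
   appearing components are admitted if they come within 5 px of the
   tree's edge or within 20 px of its skeleton. Candidates are the
   disk-1-opened components of the *difference* to the current mask of at
   least 25 px: opening suppresses the 1-px boundary sliver that a lower
   threshold adds around tubes already segmented, and the size gate
   excludes speckle; enhancement therefore only ever adds substantive
   regions, and masks grow monotonically. The loop re-registers changed
   pairs and stops when every pair satisfies the band, when an iteration
   changes no mask, or after max_iter = 10 rounds. A failing pair whose
   distance to the band does not improve after an enhancement round is
   frozen: pre-injection and post-filling pairs have genuinely zero
   growth, and lowering thresholds for them indefinitely would only
   flood the masks.
5. **Timing.** The segmented-area series over *all* frames is fitted
   with a degree-7 polynomial (on the centred/scaled frame coordinate for
   conditioning) — high enough to ride the cardiac fluctuation, low
   enough to stay smooth; residual sums of squares are nested in the
   degree, which the tests verify against 3°/5° fits. The injection
   start t_s is the first (sub-frame, interpolated) time the area
   exceeds 1.5× the catheter-only baseline (median of the first 5
   frames) and stays above it for 3 frames; if the rise is already under
   way inside the baseline window, the fallback is the polynomial's
   minimum before its first maximum. Full propagation t_max is detected
   from the fitted derivative: the first time after t_s that it falls
   below κ = 0.4 of its running peak. The κ → 0 limit of this rule is
   exactly the polynomial's first interior maximum, which is exposed as
   `mode="first_max"`; the default κ exists because a least-squares
   polynomial smears a saturation knee over several frames, and the
   literal first maximum of the fit then lands ~5 frames into the
   plateau (measured on analytic ramp-plateau series while designing the
   detector). A derivative-threshold crossing is the standard way to
   localize a smoothed step edge; κ = 0.4 was calibrated on those same
   analytic design curves (ramp-plateau with and without a cardiac
   modulation), where it localizes the knee to within ±0.6 frames. On
   series with a genuine interior peak the detector triggers slightly
   before the peak as the derivative passes through zero.
6. **Velocity.** ΔL_T is the endpoint difference of per-frame skeleton
   lengths at round(t_max) and round(t_s) (a per-frame-increment sum is
   available behind `mode="increments"`), floored at zero. Skeleton
   length counts orthogonal steps plus √2·diagonal steps along the
   medial axis; inside the growth estimator, spurs shorter than 3 px are
   pruned first, because segmentation boundary roughness decorates the
   skeleton with side twigs on the scale of the vessel half-width and
   inflates growth by ~10% otherwise (the standalone
   `skeleton_length_mm` default is unpruned, which is more faithful at
   branch tips for absolute lengths). Lengths are measured on masks in
   original, unregistered geometry: registration serves to judge and
   refine the segmentation, not to move the measurement frame.

## Synthetic phantom

The phantom emulates what the pipeline must cope with in clinical
sequences: a dark branching tree on a brighter background (background
200, dye-covered vessels −80, 8-bit quantization), 2–4 low-frequency
Gaussian organ shadows of depth ≤ 30, a static catheter curve (−60)
present from frame 0 and ending at the tree root, additive Gaussian
sensor noise, a global cyclic affine (scale and rotation
amplitude 0.03 · sin(2π f_h t), f_h = 1.2 Hz) composed with a cyclic
B-spline warp (4-px amplitude, 32-px grid, same phase), and a slow
breathing drift (0.1 px/frame).

Geometry: each generation doubles the branch count; segment lengths decay
by 0.7 per generation (siblings equal — the constant-area assumption
then holds exactly), branching angles are ±(25°–40°), and segments are
gently curved unit-step traces that steer away from the image border.
The root segment is 0.3× the image size; six generations in a 256-px
field at 0.2 mm/px give a ~250 mm summed centerline, which the 0.25 m/s
front fills in ~1 s (15 frames) — consistent with dye filling a coronary
tree within a couple of heart beats. The vessel half-width is 3.5 px
(1.4 mm diameter — a mid coronary artery; it also makes the phantom's
per-frame pixel growth, (v/fps/spacing)·width ≈ 580 px, fall inside the
500–1500 satisfaction band, as it does for real acquisitions). Dye kinematics
follow the conservation schedule (child speed = parent/2, child starts
when parent finishes), so the covered centerline grows at exactly the
injected speed until saturation — the phantom's truth lengths are
analytic. An optional foreshortening factor compresses the displayed
geometry about the root to emulate out-of-plane tilt, and an optional
per-generation taper probes the constant-area assumption's failure mode.

What the phantom does **not** emulate: contrast dispersion and washout
(the area series saturates instead of peaking), pulsatile (intra-cycle)
flow, vessel overlap from true 3D projection, external objects entering
the frame, and injection-rate variability. Passing the phantom studies
therefore shows the chain of segmentation–registration–timing–velocimetry
is internally consistent and robust to cardiac-like motion, shadows and
noise — not that it meets clinical accuracy on patient data.

## Validation studies and problem sizes

The studies in `scripts/acceptance.py` (also run by the acceptance test
suite) use ten seeded phantoms per condition at 256² px × 48 frames,
six generations, true front speed 0.25 m/s: one clean condition (no
motion, no noise) and one disturbed condition (the cardiac motion model
above plus noise SD 5). These sizes keep a full ten-seed study in the
minutes range on one CPU while leaving ≥ 25 frames of post-injection
signal. Segmentation quality is scored with the marker protocol (30
vessel + 60 background markers on five frames per phantom, vessel
markers in the eroded lumen interior, background markers in a 4–20 px
vicinity ring excluding the catheter) on the clean condition, where the
truth comparison is unconfounded; the disturbed condition feeds the
velocity-robustness study. The registration checks recover a known
(5, −3) px translation and a known 4-px single-bump B-spline warp.

The 21-patient table packaged with the stats module reproduces the
clinical correlation analysis. Note that Spearman correlations computed
from the printed 2-decimal table differ by ~0.01–0.02 from values
computed on unrounded measurements: rounding creates rank ties and
swaps. The Pearson values are insensitive to this.

## Numerical choices and degenerate inputs

- Vesselness maps are rescaled per frame to max 1; thresholds are
  fractions of that max. A numerically flat frame yields an all-zero map.
- NMI of a constant image is defined as 1 (information-free) with a
  warning; NMI is computed with 32 histogram bins throughout.
- Registration in the refinement loop runs a coarse profile (single
  pyramid level at shrink 4, affine 40 iterations, FFD 32-px grid, 10
  L-BFGS-B iterations) — the satisfaction decision needs pixel counts,
  not sub-pixel alignment; the standalone registration API defaults to a
  3-level pyramid, 16-px grid and 200/50 iterations. All metrics use
  full (non-stochastic) sampling, so results are deterministic.
- FFD control displacements beyond 20 px are capped and logged; a
  registration whose similarity decreases returns the identity, flagged.
- Polynomial fits require series length > degree + 1; degenerate
  windows (t_max − t_s < 2 frames) are rejected rather than silently
  producing unstable velocities; a flat area series raises "no injection
  detected".
- Mask enhancement at the threshold floor returns its input unchanged;
  `max_iter=0` returns the input with a warning.

## Known limitations

- Mslope is defined here as the window-mean derivative of the fitted
  polynomial; the maximum derivative or a linear refit are plausible
  alternative readings of an area-slope estimator.
- The t_s detector is a baseline-rise rule with engineering constants
  (n_base 5, rise 50%, persistence 3); on sequences whose recording
  starts after injection it falls back to the polynomial minimum.
- With strong cardiac modulation the rate-threshold t_max can trigger at
  a mid-ramp derivative dip; both window endpoints then lie inside the
  growth phase, which leaves Mlength nearly unbiased but shortens ΔT.
- Skeleton-length differencing assumes the same branches stay segmented
  across the window; wholesale appearance/disappearance of a branch
  between the window endpoints biases ΔL_T.
- The satisfaction band is an empirical constant for 0.2 mm/pixel
  acquisitions of typical coronary trees; very slow flow (growth below
  500 px/frame) is indistinguishable from under-segmentation by this
  criterion and relies on the pair-freezing rule to avoid flooding.
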