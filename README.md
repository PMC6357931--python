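# coroflow

Coronary blood-flow velocity estimation from cine X-ray angiographic
sequences.

Selective coronary angiography — the routine catheter-lab procedure for
patients with suspected coronary artery disease — records the contrast
dye filling the artery tree at ~15 frames/s and 0.2 mm/pixel. `coroflow`
turns that ordinary recording into a flow-velocity estimate, with no
Doppler wire and no extra acquisition: useful for investigating patients
with angina and unobstructed coronaries, where microvascular function
(and eventually coronary flow reserve) is the question.

## Method

For an incompressible fluid in branching pipes with equal cross-sections
(A_i = A), flow conservation across a bifurcation gives

    Q = n1·A·v1 = n2·A·v2   =>   v2 = v1·n1/n2 ,

so the dye front slows at each branching but the **summed centerline
length** of dye-filled vessel grows at the pre-branch speed. The pipeline
therefore:

1. sharpens each frame by unsharp masking, `I_s = I − (I ⊛ f_laplace)`;
2. segments the artery tree per frame with multiscale Hessian
   vesselness (dark-tube polarity), thresholding, morphology and
   largest-component selection;
3. removes heart motion between consecutive segmented frames with an
   affine + B-spline free-form registration scored by normalized mutual
   information, and iteratively re-segments at lower thresholds until
   the per-pair pixel growth ∑(B^k − B^{k−1}) falls in the 500–1500 px
   satisfaction band;
4. fits the segmented-area series with a 7th-degree polynomial and reads
   off the dye-propagation window: injection start t_s (baseline-rise
   rule) and full propagation t_max (first collapse of the fitted growth
   rate; the polynomial's first maximum in the limit);
5. converts skeleton-length growth into the velocity estimate
   **Mlength = ΔL_T/ΔT [m/s]** and the area-slope surrogate **Mslope
   [pixel-area / frame interval]**.

A synthetic phantom (branching tree, conservation-scheduled dye front,
cyclic affine + B-spline cardiac motion, organ shadows, catheter, sensor
noise — with per-frame ground truth) makes every stage testable without
patient data. See `docs/methods.md` for the full model and parameter
rationale.

## Worked example

```bash
python examples/03_velocity_pipeline.py
```

builds a noise-free phantom whose dye front truly moves at 0.25 m/s and
runs the full pipeline:

```
detected window: t_s = 8.33 frames (injection truly at 8), t_max = 22.63 (full propagation truly at 23)
skeleton growth over window: 239.4 mm in 0.95 s
Mlength = 0.251 m/s (true front speed 0.25 m/s, error +0.4%)
Mslope  = 513 pixel-area per frame interval (area-growth surrogate; correlates with velocity but needs the vessel diameter to convert to m/s)
```

The detected window brackets the true propagation (frames 8→23), and the
skeleton-length estimator recovers the front speed within a few percent.
`examples/01_phantom.py`, `02_segment_and_refine.py` and
`04_study_statistics.py` walk through the phantom generator, the
segmentation/refinement loop, and the 21-patient correlation analysis
(Pearson r = 0.585 between Mlength and transthoracic Doppler).

A thin CLI wraps the same library calls:

```bash
coroflow phantom --seed 3 --generations 6 --size 256 --out scratch/ph
coroflow run scratch/ph/frames.tif --fps 15 --spacing 0.2 --out scratch/run
```

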