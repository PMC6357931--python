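"""Heart-motion modelling between consecutive frames.

The beating heart's global motion is modelled by a 2D affine transform (6
degrees of freedom — the 2D analogue of the 12-DOF 3D affine, since the
frames are 2D projections) and the residual local deformation by a
free-form deformation (FFD) on a cubic B-spline control grid. Alignment is
scored with normalized mutual information,

    NMI(A, B) = (H(A) + H(B)) / H(A, B),

which is robust to the frame-to-frame intensity changes caused by dye
propagation. The registration inputs are the *binary* segmented frames; a
two-level image makes an entropy objective nearly degenerate, so masks are
Gaussian-smoothed into soft maps before scoring, and the binary masks are
resampled only when a transform is applied.

The optimizer itself maximizes Mattes mutual information (the numerically
robust formulation the backend provides, monotonically related to NMI);
all reported similarity scores use the NMI definition above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage as ndi

__all__ = [
    "TransformModel",
    "RegistrationReport",
    "RegistrationSettings",
    "normalized_mutual_information",
    "register_affine",
    "register_ffd",
    "apply_transform",
    "register_masks",
]

MASK_SMOOTH_SIGMA = 2.0  # px; turns binary masks into soft maps for scoring
_DISPLACEMENT_CAP = 20.0  # px; oversized FFD displacements are capped


@dataclass
class RegistrationSettings:
    """Tunables of the two-stage registration.

    The pairwise refinement loop uses a coarse profile (single pyramid
    level, 32-px grid) for tractability; the standalone stage defaults are
    finer.
    """

    bins: int = 32
    affine_iterations: int = 200
    affine_shrink: tuple[int, ...] = (4, 2, 1)
    use_ffd: bool = True
    ffd_grid_spacing_px: float = 16.0
    ffd_iterations: int = 50
    ffd_shrink: tuple[int, ...] = (4, 2)
    smooth_sigma: float = MASK_SMOOTH_SIGMA

    @classmethod
    def coarse(cls) -> "RegistrationSettings":
        """Fast profile for the per-pair refinement loop."""
        return cls(affine_iterations=40, affine_shrink=(4,),
                   ffd_grid_spacing_px=32.0, ffd_iterations=10,
                   ffd_shrink=(4,))


@dataclass
class TransformModel:
    """Affine (2x2 linear block + translation) plus optional B-spline FFD.

    ``affine_params`` follows the backend layout ``(a11, a12, a21, a22,
    tx, ty)`` in (col, row)=(x, y) coordinates. ``control_displacements``
    holds the flattened B-spline coefficient vector (empty when only the
    affine stage ran).
    """

    affine_params: np.ndarray
    control_displacements: np.ndarray = field(
        default_factory=lambda: np.zeros(0))
    grid_spacing_px: float = 0.0
    _sitk: sitk.Transform | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.affine_params = np.asarray(self.affine_params, dtype=float)
        lin = self.affine_params[:4].reshape(2, 2)
        if abs(np.linalg.det(lin)) < 1e-6:
            raise ValueError("affine linear block is (near-)singular")

    @property
    def translation_px(self) -> tuple[float, float]:
        """Translation as (row, col): the displacement of the moving frame's
        content relative to the fixed frame."""
        return float(self.affine_params[5]), float(self.affine_params[4])

    @property
    def linear(self) -> np.ndarray:
        return self.affine_params[:4].reshape(2, 2)

    def sitk_transform(self) -> sitk.Transform:
        if self._sitk is None:
            tx = sitk.AffineTransform(2)
            tx.SetParameters(tuple(self.affine_params))
            return tx
        return self._sitk

    @classmethod
    def identity(cls) -> "TransformModel":
        return cls(np.array([1.0, 0.0, 0.0, 1.0, 0.0, 0.0]))


@dataclass
class RegistrationReport:
    nmi_before: float
    nmi_after: float
    converged: bool
    iterations: int
    settings: RegistrationSettings | None = None
    notes: str = ""


def normalized_mutual_information(image_a: np.ndarray, image_b: np.ndarray,
                                  bins: int = 32) -> float:
    """NMI = (H(A)+H(B))/H(A,B) from a joint histogram with ``bins`` bins.

    Lies in [1, 2]: 1 for independent (or information-free) images, 2 for
    identical ones. A constant image carries no information; the degenerate
    marginal-entropy-zero case returns 1 with a warning.
    """
    a = np.asarray(image_a, dtype=float).ravel()
    b = np.asarray(image_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("images must have equal shapes")
    if bins < 2:
        raise ValueError("need at least 2 bins")
    hist, _, _ = np.histogram2d(a, b, bins=bins)
    p = hist / hist.sum()
    pa, pb = p.sum(axis=1), p.sum(axis=0)

    def entropy(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    ha, hb, hab = entropy(pa), entropy(pb), entropy(p.ravel())
    if ha == 0.0 or hb == 0.0:
        warnings.warn("constant image in NMI: information-free, returning 1")
        return 1.0
    return (ha + hb) / hab


def _to_sitk(arr: np.ndarray) -> sitk.Image:
    return sitk.GetImageFromArray(np.ascontiguousarray(arr, dtype=np.float32))


def _pyramid(reg: sitk.ImageRegistrationMethod, shrink: tuple[int, ...]) -> None:
    reg.SetShrinkFactorsPerLevel(list(shrink))
    reg.SetSmoothingSigmasPerLevel([max(s / 2.0, 0.5) for s in shrink])


def register_affine(fixed: np.ndarray, moving: np.ndarray,
                    settings: RegistrationSettings | None = None,
                    ) -> tuple[TransformModel, RegistrationReport]:
    """Affine stage: maximize similarity over rotation/scale/shear/shift.

    Multi-resolution gradient descent over all pixels (deterministic). On
    failure the identity is returned with the report flagged.
    """
    settings = settings or RegistrationSettings()
    fixed = np.asarray(fixed, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving must have equal shapes")
    nmi_before = normalized_mutual_information(fixed, moving, settings.bins)

    fi, mo = _to_sitk(fixed), _to_sitk(moving)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(settings.bins)
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4,
        numberOfIterations=settings.affine_iterations,
        relaxationFactor=0.6)
    reg.SetOptimizerScalesFromPhysicalShift()
    init = sitk.CenteredTransformInitializer(
        fi, mo, sitk.AffineTransform(2),
        sitk.CenteredTransformInitializerFilter.GEOMETRY)
    affine = sitk.AffineTransform(2)
    affine.SetParameters(init.GetParameters())
    affine.SetFixedParameters(init.GetFixedParameters())
    reg.SetInitialTransform(affine, inPlace=True)
    _pyramid(reg, settings.affine_shrink)
    try:
        reg.Execute(fi, mo)
        converged = True
    except RuntimeError as err:
        warnings.warn(f"affine registration failed: {err}; returning identity")
        model = TransformModel.identity()
        report = RegistrationReport(nmi_before, nmi_before, False, 0,
                                    settings, notes="non-convergence")
        return model, report

    # fold the fixed (centre) parameters into a plain parameter vector
    flat = sitk.AffineTransform(2)
    centre = np.asarray(affine.GetCenter())
    lin = np.asarray(affine.GetMatrix()).reshape(2, 2)
    trans = np.asarray(affine.GetTranslation())
    offset = centre + trans - lin @ centre
    flat.SetMatrix(affine.GetMatrix())
    flat.SetTranslation(tuple(offset))
    params = np.concatenate([lin.ravel(), offset])

    aligned = sitk.GetArrayFromImage(
        sitk.Resample(mo, fi, flat, sitk.sitkLinear, 0.0))
    nmi_after = normalized_mutual_information(fixed, aligned, settings.bins)
    if nmi_after < nmi_before - 1e-3:
        model = TransformModel.identity()
        return model, RegistrationReport(
            nmi_before, nmi_before, False, int(reg.GetOptimizerIteration()),
            settings, notes="similarity decreased; identity returned")
    model = TransformModel(params, _sitk=flat)
    report = RegistrationReport(nmi_before, nmi_after, converged,
                                int(reg.GetOptimizerIteration()), settings)
    return model, report


def register_ffd(fixed: np.ndarray, moving: np.ndarray,
                 init: TransformModel,
                 grid_spacing_px: float | None = None,
                 settings: RegistrationSettings | None = None,
                 ) -> tuple[TransformModel, RegistrationReport]:
    """B-spline FFD stage on top of an affine initialization.

    Optimizes cubic B-spline control-point displacements with L-BFGS-B;
    the returned model composes (affine then FFD correction). Oversized
    control displacements are capped and logged.
    """
    settings = settings or RegistrationSettings()
    grid = grid_spacing_px or settings.ffd_grid_spacing_px
    fixed = np.asarray(fixed, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    nmi_before = normalized_mutual_information(fixed, moving, settings.bins)

    fi, mo = _to_sitk(fixed), _to_sitk(moving)
    mesh = [max(2, int(round(s / grid))) for s in fixed.shape[::-1]]
    btx = sitk.BSplineTransformInitializer(fi, mesh)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(settings.bins)
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsLBFGSB(
        gradientConvergenceTolerance=1e-3,
        numberOfIterations=settings.ffd_iterations)
    reg.SetMovingInitialTransform(init.sitk_transform())
    reg.SetInitialTransform(btx, inPlace=True)
    _pyramid(reg, settings.ffd_shrink)
    converged = True
    try:
        reg.Execute(fi, mo)
    except RuntimeError as err:
        warnings.warn(f"FFD registration failed: {err}; keeping affine only")
        return init, RegistrationReport(nmi_before, nmi_before, False, 0,
                                        settings, notes="non-convergence")

    coeffs = np.asarray(btx.GetParameters())
    notes = ""
    if np.abs(coeffs).max() > _DISPLACEMENT_CAP:
        notes = (f"capped {int((np.abs(coeffs) > _DISPLACEMENT_CAP).sum())} "
                 f"control displacements at {_DISPLACEMENT_CAP} px")
        coeffs = np.clip(coeffs, -_DISPLACEMENT_CAP, _DISPLACEMENT_CAP)
        btx.SetParameters(tuple(coeffs))

    composite = sitk.CompositeTransform(2)
    composite.AddTransform(init.sitk_transform())
    composite.AddTransform(btx)
    aligned = sitk.GetArrayFromImage(
        sitk.Resample(mo, fi, composite, sitk.sitkLinear, 0.0))
    nmi_after = normalized_mutual_information(fixed, aligned, settings.bins)
    model = TransformModel(init.affine_params.copy(),
                           control_displacements=coeffs,
                           grid_spacing_px=float(grid), _sitk=composite)
    report = RegistrationReport(nmi_before, nmi_after, converged,
                                int(reg.GetOptimizerIteration()), settings,
                                notes=notes)
    return model, report


def apply_transform(mask_or_image: np.ndarray, t: TransformModel,
                    background: float = 0.0) -> np.ndarray:
    """Resample an array through a transform.

    Binary masks use nearest-neighbour interpolation (so the output stays
    binary), intensity images use linear; out-of-bounds pixels are filled
    with ``background``.
    """
    arr = np.asarray(mask_or_image)
    is_mask = arr.dtype == bool
    img = _to_sitk(arr.astype(np.float32))
    interp = sitk.sitkNearestNeighbor if is_mask else sitk.sitkLinear
    out = sitk.Resample(img, img, t.sitk_transform(), interp,
                        float(background))
    res = sitk.GetArrayFromImage(out)
    return res > 0.5 if is_mask else res.astype(np.float64)


def transform_points(t: TransformModel, points_rc: np.ndarray) -> np.ndarray:
    """Map (row, col) points through the transform (fixed -> moving)."""
    tx = t.sitk_transform()
    out = np.empty_like(np.asarray(points_rc, dtype=float))
    for i, (r, c) in enumerate(points_rc):
        x, y = tx.TransformPoint((float(c), float(r)))
        out[i] = (y, x)
    return out


def register_masks(fixed_mask: np.ndarray, moving_mask: np.ndarray,
                   settings: RegistrationSettings | None = None,
                   ) -> tuple[TransformModel, RegistrationReport, np.ndarray]:
    """Register one binary mask onto another (earlier frame fixed).

    Masks are Gaussian-smoothed into soft maps for the entropy objective;
    the returned aligned mask is the raw binary moving mask resampled with
    nearest-neighbour interpolation through the recovered transform.
    """
    settings = settings or RegistrationSettings.coarse()
    soft_fixed = ndi.gaussian_filter(
        np.asarray(fixed_mask, dtype=np.float64), settings.smooth_sigma)
    soft_moving = ndi.gaussian_filter(
        np.asarray(moving_mask, dtype=np.float64), settings.smooth_sigma)
    model, report = register_affine(soft_fixed, soft_moving, settings)
    if settings.use_ffd:
        model, report_ffd = register_ffd(soft_fixed, soft_moving, model,
                                         settings=settings)
        # keep the better-scoring stage's report for provenance
        if report_ffd.nmi_after >= report.nmi_after - 1e-3:
            report = report_ffd
    aligned = apply_transform(np.asarray(moving_mask, dtype=bool), model)
    return model, report, aligned
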