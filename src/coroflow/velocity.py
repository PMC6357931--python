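"""Velocity estimators from skeleton-length growth and area slope.

Under the constant-cross-section assumption, flow conservation through a
bifurcation (``Q = n1*A*v1 = n2*A*v2``) gives ``v2 = v1*n1/n2``: the front
slows as the branch count grows, but the *summed* centerline length keeps
growing at the pre-branch speed. The primary estimator therefore is

    Mlength:  v_est = delta_L_T / delta_T      [m/s]

with ``delta_L_T`` the skeleton-length growth of the segmented tree over
the dye-propagation window and ``delta_T = (t_max - t_s)/fps``. The
surrogate

    Mslope:   (p(t_max) - p(t_s)) / (t_max - t_s)

is the mean slope of the fitted area polynomial over the window, in pixel
area per frame interval; it correlates with velocity but converts to m/s
only through the (unknown) typical vessel diameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize

from .core import MaskSequence
from .timing import PolyFitResult

__all__ = [
    "BranchModel",
    "VelocityResult",
    "skeleton_length_mm",
    "branch_velocity",
    "prebranch_velocity",
    "estimate_mlength",
    "estimate_mslope",
]


@dataclass
class BranchModel:
    """Idealized branching-pipe bookkeeping around one bifurcation.

    Cross-sections are all equal (carried symbolically; the flow rate
    ``Q = n*A*v`` is never evaluated numerically). ``v2`` is derived from
    conservation.
    """

    n1: int = 1
    n2: int = 2
    v1: float = 0.25           # m/s, mean cross-section speed before branch
    L1: float = 30.0           # mm
    L2: float = 21.0
    L3: float = 21.0

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("branch counts are positive integers")
        if min(self.L1, self.L2, self.L3) < 0 or self.v1 <= 0:
            raise ValueError("lengths non-negative, speed positive")

    @property
    def v2(self) -> float:
        return branch_velocity(self.v1, self.n1, self.n2)

    @property
    def t_tot(self) -> float:
        """Traversal time root + one child, seconds."""
        return (self.L1 / 1000.0) / self.v1 + (self.L2 / 1000.0) / self.v2


@dataclass
class VelocityResult:
    """Mlength and Mslope with their provenance."""

    v_mlength_m_per_s: float
    m_slope: float                       # pixel area per frame interval
    delta_L_T_mm: float
    delta_T_s: float
    window: tuple[float, float]          # (t_s, t_max) in frames
    skeleton_lengths_mm: np.ndarray = field(
        default_factory=lambda: np.zeros(0))
    notes: str = ""

    def __post_init__(self) -> None:
        if self.delta_T_s <= 0:
            raise ValueError("window duration must be positive")
        if self.delta_L_T_mm < 0:
            raise ValueError("length growth cannot be negative")


DEFAULT_PRUNE_PX = 3


def _prune_spurs(skel: np.ndarray, n_iter: int) -> np.ndarray:
    """Iteratively strip skeleton endpoints, removing side spurs shorter
    than ``n_iter`` px that boundary roughness introduces."""
    skel = skel.copy()
    kernel = np.ones((3, 3), dtype=int)
    for _ in range(n_iter):
        neighbours = ndi.convolve(skel.astype(int), kernel,
                                  mode="constant") - skel
        endpoints = skel & (neighbours <= 1)
        if not endpoints.any():
            break
        skel &= ~endpoints
    return skel


def skeleton_length_mm(mask: np.ndarray, pixel_spacing_mm: float,
                       prune_px: int = 0) -> float:
    """Centerline length of a binary mask in millimetres.

    The mask is thinned to its medial axis and the length is the number
    of orthogonal adjacencies plus sqrt(2) times the diagonal adjacencies
    along the skeleton (standard geodesic pixel-path length). With
    ``prune_px`` > 0, spurs shorter than that many pixels are stripped
    first — segmentation boundary roughness otherwise inflates the
    skeleton with side twigs on the scale of the vessel half-width (the
    growth-based estimator prunes by default; for absolute lengths the
    unpruned skeleton is more faithful at the branch tips). Empty mask: 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    skel = skeletonize(mask)
    if prune_px > 0:
        skel = _prune_spurs(skel, prune_px)
    # count each 8-neighbour adjacency once via forward shifts
    orth = (np.count_nonzero(skel[1:, :] & skel[:-1, :])
            + np.count_nonzero(skel[:, 1:] & skel[:, :-1]))
    diag = (np.count_nonzero(skel[1:, 1:] & skel[:-1, :-1])
            + np.count_nonzero(skel[1:, :-1] & skel[:-1, 1:]))
    # diagonal steps between pixels that are also orthogonally connected
    # would double-count; medial-axis thinning leaves few such triangles,
    # so the straightforward count is used
    return float((orth + np.sqrt(2.0) * diag) * pixel_spacing_mm)


def branch_velocity(v1: float, n1: int, n2: int) -> float:
    """Post-branch mean speed by conservation: ``v2 = v1 * n1 / n2``."""
    if n1 < 1 or n2 < 1:
        raise ValueError("branch counts are positive integers")
    return v1 * n1 / n2


def prebranch_velocity(L1_mm: float, L2_mm: float, L3_mm: float,
                       t_tot_s: float) -> float:
    """Pre-branch speed from the summed path lengths and total time.

    For a symmetric bifurcation (equal child lengths), the time to
    traverse root plus child at the conservation-slowed speed equals the
    time to traverse ``L1 + L2 + L3`` at the pre-branch speed, hence
    ``v1 = (L1 + L2 + L3) / t_tot`` (inputs mm and s, output m/s).
    """
    if t_tot_s <= 0:
        raise ValueError("total time must be positive")
    return (L1_mm + L2_mm + L3_mm) / 1000.0 / t_tot_s


def estimate_mlength(masks: MaskSequence, fit: PolyFitResult, fps: float,
                     pixel_spacing_mm: float,
                     mode: str = "endpoint",
                     prune_px: int = DEFAULT_PRUNE_PX) -> VelocityResult:
    """Mlength: skeleton-length growth over the window divided by its
    duration.

    ``mode="endpoint"`` (default) takes ``L(round(t_max)) -
    L(round(t_s))``, robust to single-frame segmentation flicker;
    ``mode="increments"`` sums the positive per-frame increments across
    the window instead. Negative growth is floored at zero with a warning.
    """
    if not np.isfinite(fit.t_s) or not np.isfinite(fit.t_max):
        raise ValueError("fit carries no detected window; run fit_timing")
    if fit.t_max - fit.t_s < 2.0:
        raise ValueError("propagation window shorter than 2 frames")
    n = masks.n_frames
    ka = int(np.clip(round(fit.t_s), 0, n - 1))
    kb = int(np.clip(round(fit.t_max), 0, n - 1))
    lengths = np.array([skeleton_length_mm(m, pixel_spacing_mm,
                                           prune_px=prune_px)
                        for m in masks.masks])
    if mode == "endpoint":
        delta_L = lengths[kb] - lengths[ka]
    elif mode == "increments":
        inc = np.diff(lengths[ka:kb + 1])
        delta_L = float(np.sum(inc[inc > 0]))
    else:
        raise ValueError(f"unknown Mlength mode: {mode!r}")
    notes = ""
    if delta_L <= 0:
        warnings.warn("no skeleton growth over the window; velocity is 0")
        notes = "no growth"
        delta_L = 0.0
    delta_T = (fit.t_max - fit.t_s) / fps
    v = delta_L / 1000.0 / delta_T
    return VelocityResult(v_mlength_m_per_s=v,
                          m_slope=estimate_mslope(fit),
                          delta_L_T_mm=float(delta_L), delta_T_s=delta_T,
                          window=(fit.t_s, fit.t_max),
                          skeleton_lengths_mm=lengths, notes=notes)


def estimate_mslope(fit: PolyFitResult) -> float:
    """Mslope: mean slope of the fitted area polynomial over the window,
    in pixel area per frame interval."""
    if not np.isfinite(fit.t_s) or not np.isfinite(fit.t_max):
        raise ValueError("fit carries no detected window; run fit_timing")
    if fit.t_max - fit.t_s < 2.0:
        raise ValueError("propagation window shorter than 2 frames")
    p = fit.poly
    return float((p(fit.t_max) - p(fit.t_s)) / (fit.t_max - fit.t_s))
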