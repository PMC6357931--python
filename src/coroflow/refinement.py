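"""Iterative segmentation refinement driven by registration results.

After aligning consecutive segmented frames, the pixel-count difference

    d = sum(B^k) - sum(B^{k-1})

should equal the dye growth over one frame interval; the satisfaction
criterion accepts a pair when d lies inside an empirically chosen band
(500..1500 px at 0.2 mm/pixel). A pair outside the band indicates poor
segmentation: both frames are re-thresholded at a lower vesselness
threshold and nearby newly appearing components are admitted into the
tree, then the pair is registered again. The loop ends when every pair
satisfies the band, when an iteration changes no mask (a fixed point —
further rounds would only lower thresholds without effect), or when the
iteration budget is exhausted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk, skeletonize

from .core import MaskSequence, VesselnessMap
from .registration import RegistrationSettings, register_masks

__all__ = [
    "SatisfactionCriterion",
    "pair_satisfactory",
    "enhance_mask",
    "refine_sequence",
]

DEFAULT_TH_STEP = 0.02
TH_FLOOR = 0.02
DEFAULT_D_EDGE_PX = 5.0
DEFAULT_D_CENTER_PX = 20.0
#: Smallest admissible candidate component: anything below a few tens of
#: pixels is speckle, not a missed branch (a branch segment is at least a
#: few pixels of width times a few pixels of length).
DEFAULT_MIN_SIZE_PX = 25


@dataclass
class SatisfactionCriterion:
    """Acceptable per-pair segmented-pixel growth band.

    The 500..1500 px limits are calibrated at 0.2 mm/pixel; for other
    pixel spacings they scale with the pixel area ``(0.2/spacing)**2``,
    since the band reflects physical dye growth per frame interval
    (mm of new centerline times vessel width), not the field of view.
    """

    lower_px: float = 500.0
    upper_px: float = 1500.0
    reference_spacing_mm: float = 0.2

    def __post_init__(self) -> None:
        if not 0 <= self.lower_px < self.upper_px:
            raise ValueError("need 0 <= lower_px < upper_px")

    def scaled(self, pixel_spacing_mm: float) -> tuple[float, float]:
        f = (self.reference_spacing_mm / pixel_spacing_mm) ** 2
        return self.lower_px * f, self.upper_px * f


def pair_satisfactory(mask_prev: np.ndarray, mask_curr: np.ndarray,
                      crit: SatisfactionCriterion,
                      pixel_spacing_mm: float = 0.2) -> bool:
    """Is the aligned pair's signed pixel-count difference inside the band?

    ``mask_curr`` is the registered current mask. A negative difference
    (shrinking tree) is always unsatisfactory.
    """
    if mask_prev.shape != mask_curr.shape:
        raise ValueError("masks must share a shape")
    d = int(np.count_nonzero(mask_curr)) - int(np.count_nonzero(mask_prev))
    lo, hi = crit.scaled(pixel_spacing_mm)
    return lo <= d <= hi


def enhance_mask(vesselness: VesselnessMap, current_mask: np.ndarray,
                 th_current: float, th_step: float = DEFAULT_TH_STEP,
                 th_floor: float = TH_FLOOR,
                 d_edge_px: float = DEFAULT_D_EDGE_PX,
                 d_center_px: float = DEFAULT_D_CENTER_PX,
                 min_size_px: int = DEFAULT_MIN_SIZE_PX,
                 ) -> tuple[np.ndarray, float]:
    """Re-threshold lower and admit nearby newly appearing components.

    Candidate additions are the connected components of the opened
    difference ``threshold(v, th-step) \\ current_mask`` (the same disk-1
    opening as the initial cleanup, which suppresses the 1-px boundary
    sliver that a lower threshold adds around already-segmented tubes),
    of at least ``min_size_px`` pixels. A candidate is admitted when its
    edge-to-edge distance to the main tree is at most ``d_edge_px`` OR its
    centroid lies within ``d_center_px`` of the tree's skeleton.
    Enhancement only ever adds pixels.

    Returns the (possibly grown) mask and the threshold now in effect;
    when the floor is reached the inputs are returned unchanged.
    """
    new_th = th_current - th_step
    if new_th < th_floor:
        return np.asarray(current_mask, dtype=bool), th_current
    current_mask = np.asarray(current_mask, dtype=bool)
    new_binary = vesselness.scores >= new_th
    candidates = ndi.binary_opening(new_binary & ~current_mask,
                                structure=disk(1))
    if not candidates.any() or not current_mask.any():
        return current_mask, new_th

    labels, n = ndi.label(candidates, structure=np.ones((3, 3), dtype=int))
    dist_to_tree = ndi.distance_transform_edt(~current_mask)
    skel = skeletonize(current_mask)
    dist_to_skel = (ndi.distance_transform_edt(~skel)
                    if skel.any() else np.full(current_mask.shape, np.inf))

    admitted = current_mask.copy()
    comp_sizes = ndi.sum_labels(candidates, labels, np.arange(1, n + 1))
    comp_min_edge = ndi.minimum(dist_to_tree, labels, np.arange(1, n + 1))
    centroids = ndi.center_of_mass(candidates, labels, np.arange(1, n + 1))
    for lab in range(1, n + 1):
        if comp_sizes[lab - 1] < min_size_px:
            continue
        ok = comp_min_edge[lab - 1] <= d_edge_px
        if not ok:
            r, c = (int(round(x)) for x in centroids[lab - 1])
            ok = dist_to_skel[r, c] <= d_center_px
        if ok:
            admitted |= labels == lab
    return admitted, new_th


def refine_sequence(masks: MaskSequence,
                    vesselness_maps: list[VesselnessMap],
                    crit: SatisfactionCriterion | None = None,
                    max_iter: int = 10,
                    pixel_spacing_mm: float = 0.2,
                    settings: RegistrationSettings | None = None,
                    th_step: float = DEFAULT_TH_STEP,
                    d_edge_px: float = DEFAULT_D_EDGE_PX,
                    d_center_px: float = DEFAULT_D_CENTER_PX,
                    min_size_px: int = DEFAULT_MIN_SIZE_PX,
                    log: list | None = None) -> MaskSequence:
    """Run the registration / satisfaction / enhancement loop.

    Each iteration registers frame ``k`` onto frame ``k-1`` (earlier frame
    fixed, so dye growth appears as added pixels), tests the satisfaction
    band on the aligned pair, and enhances both members of every failing
    pair (each frame's threshold is lowered at most once per iteration).

    A failing pair whose distance to the band did not improve after an
    enhancement round is frozen: its misalignment is not segmentation-
    caused (e.g. pre-injection pairs, whose growth is genuinely zero), so
    further threshold lowering would only flood the masks. Pairs whose
    masks did not change since their last registration reuse the cached
    difference. Appends one dict per examined pair to ``log``.
    """
    crit = crit or SatisfactionCriterion()
    settings = settings or RegistrationSettings.coarse()
    if len(vesselness_maps) != masks.n_frames:
        raise ValueError("need one vesselness map per frame")
    out = masks.copy()
    n = out.n_frames
    lo, hi = crit.scaled(pixel_spacing_mm)
    d_cache: dict[int, float] = {}
    dirty = [True] * n
    active = [True] * n          # pair k still eligible for enhancement
    gap_prev = [np.inf] * n      # pair k's last distance to the band
    unsatisfied: list[int] = []

    for iteration in range(max_iter):
        any_change = False
        all_ok = True
        enhanced_this_iter: set[int] = set()
        unsatisfied = []
        for k in range(1, n):
            if dirty[k - 1] or dirty[k] or k not in d_cache:
                _, report, aligned = register_masks(out.masks[k - 1],
                                                    out.masks[k], settings)
                d = int(np.count_nonzero(aligned)) - int(
                    np.count_nonzero(out.masks[k - 1]))
                d_cache[k] = d
            else:
                d = d_cache[k]
                report = None
            gap = max(lo - d, d - hi, 0.0)
            ok = gap == 0.0
            if log is not None:
                log.append({"iteration": iteration, "pair": (k - 1, k),
                            "d": d, "satisfactory": ok, "active": active[k],
                            "nmi_after": getattr(report, "nmi_after", None)})
            if ok:
                continue
            all_ok = False
            unsatisfied.append(k)
            if not active[k]:
                continue
            if gap >= gap_prev[k] - 1.0:
                active[k] = False  # enhancement did not help this pair
                continue
            gap_prev[k] = gap
            for j in (k - 1, k):
                if j in enhanced_this_iter:
                    continue
                enhanced_this_iter.add(j)
                new_mask, new_th = enhance_mask(
                    vesselness_maps[j], out.masks[j], out.thresholds[j],
                    th_step=th_step, d_edge_px=d_edge_px,
                    d_center_px=d_center_px, min_size_px=min_size_px)
                changed = bool(np.any(new_mask != out.masks[j]))
                out.thresholds[j] = new_th
                if changed:
                    out.masks[j] = new_mask
                    any_change = True
        dirty = [j in enhanced_this_iter for j in range(n)]
        if all_ok:
            break
        if not any_change:
            break  # fixed point: enhancement no longer grows any mask
    else:
        if unsatisfied:
            warnings.warn(f"refinement budget exhausted; unsatisfied pairs "
                          f"at frames {unsatisfied}")
        else:
            warnings.warn("refinement called with max_iter=0; masks unchanged")
    out.refined = True
    return out
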