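"""Segmentation assessment and the statistical layer.

Segmentations are scored against manually placed markers: vessel markers
inside the mask are true positives, background markers inside it false
positives, and so on, yielding sensitivity, specificity and accuracy
without requiring full manual segmentations. Velocity estimates are
compared with reference Doppler velocities via Pearson and Spearman
correlation, with marginal normality checked by a one-sample
Kolmogorov-Smirnov test.

The packaged 21-patient study table (per-patient Mslope, Mlength and
transthoracic-Doppler velocity) ships with the module so the clinical
correlation analysis runs with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import permutations
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats as sps

__all__ = [
    "MarkerSet",
    "ConfusionSummary",
    "marker_confusion",
    "generate_markers",
    "pearson_r",
    "spearman_r",
    "ks_normality",
    "load_flow_study",
]

VESSEL = "vessel"
BACKGROUND = "background"


@dataclass
class MarkerSet:
    """Labelled point annotations: (row, col, label) with 0-based
    row-major pixel indices."""

    points: list[tuple[int, int, str]]

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("marker set cannot be empty")
        for r, c, lab in self.points:
            if lab not in (VESSEL, BACKGROUND):
                raise ValueError(f"unknown marker label {lab!r}")

    def __len__(self) -> int:
        return len(self.points)

    def to_text(self) -> str:
        return "\n".join(f"{r} {c} {lab}" for r, c, lab in self.points) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "MarkerSet":
        pts = []
        for line in text.strip().splitlines():
            r, c, lab = line.split()
            pts.append((int(r), int(c), lab))
        return cls(pts)


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else 0.0

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else 0.0


def marker_confusion(mask: np.ndarray, markers: MarkerSet) -> ConfusionSummary:
    """Score a binary segmentation against labelled markers.

    Vessel markers inside the segmentation are TP, outside FN; background
    markers inside are FP, outside TN.
    """
    mask = np.asarray(mask, dtype=bool)
    tp = fp = tn = fn = 0
    for i, (r, c, lab) in enumerate(markers.points):
        if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
            raise ValueError(f"marker {i} at ({r}, {c}) outside image bounds")
        inside = mask[r, c]
        if lab == VESSEL:
            tp, fn = tp + inside, fn + (not inside)
        else:
            fp, tn = fp + inside, tn + (not inside)
    return ConfusionSummary(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn))


def generate_markers(vessel_mask: np.ndarray, exclude_mask: np.ndarray | None,
                     n_vessel: int = 30, n_background: int = 60,
                     seed: int = 0,
                     vicinity_px: tuple[float, float] = (4.0, 20.0),
                     ) -> MarkerSet:
    """Emulate the manual marker protocol on a known truth mask.

    Vessel markers are sampled inside the visible arteries — from the
    1-px-eroded interior of ``vessel_mask``, since an annotator marks the
    vessel lumen, not its faint boundary. Background markers go in the
    close vicinity: a ring ``vicinity_px`` pixels away from the vessel
    boundary, excluding pixels of ``exclude_mask`` (e.g. the catheter,
    which an annotator would mark as neither artery nor plain background).
    """
    rng = np.random.default_rng(seed)
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if not vessel_mask.any():
        raise ValueError("vessel mask is empty; no markers can be placed")
    interior = ndi.binary_erosion(vessel_mask)
    if not interior.any():
        interior = vessel_mask
    avoid = vessel_mask if exclude_mask is None else vessel_mask | exclude_mask
    dist = ndi.distance_transform_edt(~avoid)
    ring = (dist >= vicinity_px[0]) & (dist <= vicinity_px[1])

    def sample(region: np.ndarray, k: int) -> np.ndarray:
        idx = np.flatnonzero(region)
        if len(idx) < k:
            raise ValueError("not enough candidate pixels for markers")
        return idx[rng.choice(len(idx), size=k, replace=False)]

    shape = vessel_mask.shape
    pts = [(int(i // shape[1]), int(i % shape[1]), VESSEL)
           for i in sample(interior, n_vessel)]
    pts += [(int(i // shape[1]), int(i % shape[1]), BACKGROUND)
            for i in sample(ring, n_background)]
    return MarkerSet(pts)


def _check_pair(x, y, min_n: int = 3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D vectors")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} pairs")
    return x, y


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided p from the t transform
    (n - 2 degrees of freedom)."""
    x, y = _check_pair(x, y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def spearman_r(x, y) -> tuple[float, float]:
    """Rank correlation (mid-ranks for ties).

    Equals the Pearson correlation of the rank-transformed data. The
    p-value is exact (full permutation enumeration) for n <= 8 and the
    usual t approximation for larger samples.
    """
    x, y = _check_pair(x, y)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector has no ranks to correlate")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    r = float(sps.pearsonr(rx, ry).statistic)
    n = len(x)
    if n <= 8:
        obs = abs(r)
        count = total = 0
        for perm in permutations(ry):
            rp = float(sps.pearsonr(rx, np.asarray(perm)).statistic)
            count += abs(rp) >= obs - 1e-12
            total += 1
        return r, count / total
    t = r * np.sqrt((n - 2) / max(1e-300, 1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return r, float(min(p, 1.0))


class KSResult(NamedTuple):
    statistic: float
    p_value: float
    #: the normal parameters were estimated from the sample, so the
    #: asymptotic p-value is anti-conservative (Lilliefors condition)
    params_estimated: bool


def ks_normality(x) -> KSResult:
    """One-sample Kolmogorov-Smirnov test against a normal distribution
    with the sample's own mean and SD."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 5:
        raise ValueError("need a 1D sample of at least 5 values")
    if np.std(x) == 0:
        raise ValueError("degenerate (constant) sample")
    res = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return KSResult(float(res.statistic), float(res.pvalue), True)


def load_flow_study() -> pd.DataFrame:
    """The packaged 21-patient table: per-patient Mslope (pixel area per
    frame interval), Mlength and Doppler reference velocity (m/s)."""
    with resources.files("coroflow.data").joinpath("flow_study.csv").open() as fh:
        return pd.read_csv(fh)
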