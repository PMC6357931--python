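"""Dye-propagation window detection from the segmented-area series.

The segmented artery-tree area per frame rises roughly linearly while the
contrast dye propagates and levels off (or peaks, once cardiac deformation
and washout modulate it) when the tree is full. A 7th-degree polynomial is
fitted to the whole series — high enough to follow the cardiac-cycle
fluctuation riding on the propagation ramp, low enough to stay smooth —
and the propagation window [t_s, t_max] is read off the fit:

* ``t_s`` — injection start: the first time the area rises persistently
  above the catheter-only baseline.
* ``t_max`` — full propagation: the first time the fitted growth rate
  falls below a fraction ``kappa`` of its running peak. For ``kappa -> 0``
  this is exactly the polynomial's first interior maximum (the classical
  reading, available as ``mode="first_max"``); the default ``kappa = 0.4``
  localizes the saturation knee of a monotone series, which a least-squares
  polynomial smears over several frames, to well under a frame interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import Polynomial

from .core import AreaSeries, MaskSequence

__all__ = [
    "PolyFitResult",
    "compute_area_series",
    "fit_area_polynomial",
    "detect_t_max",
    "detect_t_s",
    "fit_timing",
]

DEFAULT_DEGREE = 7
DEFAULT_KAPPA = 0.4
DEFAULT_N_BASE = 5
DEFAULT_RISE_FRAC = 0.5
DEFAULT_PERSIST = 3


@dataclass
class PolyFitResult:
    """Polynomial model of the area series with the detected window."""

    degree: int
    coefficients: np.ndarray          # original-coordinate, ascending powers
    rss: float
    domain: tuple[float, float]
    t_s: float = float("nan")
    t_max: float = float("nan")
    t_s_method: str = ""
    t_max_fallback: bool = False
    _poly: Polynomial = field(default=None, repr=False)  # type: ignore

    @property
    def delta_T_frames(self) -> float:
        return self.t_max - self.t_s

    @property
    def poly(self) -> Polynomial:
        if self._poly is None:
            return Polynomial(self.coefficients)
        return self._poly

    def __call__(self, t):
        return self.poly(t)


def compute_area_series(masks: MaskSequence) -> AreaSeries:
    """Pixel count of the segmented tree per frame."""
    if masks.n_frames == 0:
        raise ValueError("empty mask sequence")
    counts = masks.masks.reshape(masks.n_frames, -1).sum(axis=1)
    return AreaSeries(np.arange(masks.n_frames), counts.astype(float))


def fit_area_polynomial(series: AreaSeries,
                        degree: int = DEFAULT_DEGREE) -> PolyFitResult:
    """Least-squares polynomial fit of the area series.

    Fitting runs on the centred/scaled frame coordinate for conditioning;
    the reported coefficients are converted back to the original frame
    coordinate. The residual sum of squares decreases (weakly) with degree
    — a nested-model property used to compare 3/5/7-degree fits.
    """
    if degree < 1:
        raise ValueError("degree must be at least 1")
    if len(series) <= degree + 1:
        raise ValueError(f"series of length {len(series)} cannot support "
                         f"a degree-{degree} fit")
    t = series.frame_index.astype(float)
    p = Polynomial.fit(t, series.area_px, deg=degree)
    rss = float(np.sum((p(t) - series.area_px) ** 2))
    return PolyFitResult(degree=degree, coefficients=p.convert().coef,
                         rss=rss, domain=(float(t[0]), float(t[-1])),
                         _poly=p)


def detect_t_max(fit: PolyFitResult,
                 domain: tuple[float, float] | None = None,
                 mode: str = "rate_threshold",
                 kappa: float = DEFAULT_KAPPA) -> tuple[float, bool]:
    """Detect full propagation from the fitted polynomial.

    ``mode="first_max"``: the smallest derivative root inside ``domain``
    with negative second derivative (the polynomial's first interior
    maximum); falls back to the right endpoint (flagged) if none exists.

    ``mode="rate_threshold"`` (default): the first time the derivative
    falls below ``kappa`` times its running peak — the first-maximum
    criterion relaxed so that the saturation knee of a monotone series is
    localized instead of overshot; a genuine interior maximum triggers it
    as the derivative passes through zero.

    Returns ``(t_max, fallback_flag)``.
    """
    lo, hi = domain if domain is not None else fit.domain
    if not lo < hi:
        raise ValueError("empty detection domain")
    p = fit.poly
    if mode == "first_max":
        d1, d2 = p.deriv(), p.deriv(2)
        roots = d1.roots()
        real = sorted(r.real for r in roots
                      if abs(r.imag) < 1e-9 and lo < r.real < hi)
        maxima = [r for r in real if d2(r) < 0]
        if maxima:
            return float(maxima[0]), False
        return float(hi), True
    if mode != "rate_threshold":
        raise ValueError(f"unknown t_max mode: {mode!r}")
    tt = np.linspace(lo, hi, 4000)
    dv = p.deriv()(tt)
    peak = np.maximum.accumulate(np.maximum(dv, 0.0))
    hit = (peak > 1e-12) & (dv <= kappa * peak)
    if hit.any():
        return float(tt[int(np.argmax(hit))]), False
    return float(hi), True


def detect_t_s(series: AreaSeries, fit: PolyFitResult | None = None,
               n_base: int = DEFAULT_N_BASE,
               rise_frac: float = DEFAULT_RISE_FRAC,
               persist: int = DEFAULT_PERSIST) -> tuple[float, str]:
    """Detect the injection start from the area series.

    The catheter-only baseline is the median area of the first ``n_base``
    frames; ``t_s`` is the (sub-frame, linearly interpolated) time at which
    the area first exceeds ``baseline * (1 + rise_frac)`` and stays above
    for ``persist`` frames. If the rise is already underway inside the
    baseline window, the fallback places ``t_s`` at the fitted
    polynomial's minimum before its first maximum. A flat series (no
    injection present) raises.

    Returns ``(t_s, method)`` with ``method`` in {"baseline", "fallback"}.
    """
    area = series.area_px
    n = len(area)
    if n <= n_base + persist:
        raise ValueError("series too short for injection detection")
    baseline = float(np.median(area[:n_base]))
    if np.ptp(area) < 1e-12 or np.all(area <= baseline * (1 + rise_frac)):
        raise ValueError("no injection detected: the area never rises above "
                         "the catheter baseline; provide t_s manually")
    thresh = baseline * (1 + rise_frac)
    above = area > thresh
    run = np.convolve(above.astype(int), np.ones(persist, dtype=int),
                      mode="full")[persist - 1:n]
    qualifying = np.flatnonzero((run == persist))
    if len(qualifying) == 0:
        raise ValueError("area rises but not persistently; provide t_s "
                         "manually")
    k = int(qualifying[0])
    if k > n_base:
        if area[k - 1] < thresh:  # sub-frame crossing by interpolation
            frac = (thresh - area[k - 1]) / (area[k] - area[k - 1])
            return float(k - 1 + frac), "baseline"
        return float(k), "baseline"
    # rise underway from frame 0: baseline is contaminated, use the fitted
    # polynomial's minimum before its first maximum
    if fit is None:
        return 0.0, "fallback"
    t_max, _ = detect_t_max(fit)
    tt = np.linspace(fit.domain[0], max(t_max, fit.domain[0] + 1e-6), 1000)
    return float(tt[int(np.argmin(fit.poly(tt)))]), "fallback"


def fit_timing(series: AreaSeries, degree: int = DEFAULT_DEGREE,
               mode: str = "rate_threshold", kappa: float = DEFAULT_KAPPA,
               n_base: int = DEFAULT_N_BASE,
               rise_frac: float = DEFAULT_RISE_FRAC,
               persist: int = DEFAULT_PERSIST) -> PolyFitResult:
    """Fit the polynomial and detect the full window [t_s, t_max].

    ``t_max`` is searched after ``t_s`` so that small pre-injection
    undulations of the fit cannot masquerade as the propagation maximum.
    """
    fit = fit_area_polynomial(series, degree=degree)
    t_s, method = detect_t_s(series, fit, n_base=n_base,
                             rise_frac=rise_frac, persist=persist)
    t_max, fallback = detect_t_max(fit, domain=(t_s, fit.domain[1]),
                                   mode=mode, kappa=kappa)
    fit.t_s, fit.t_max = t_s, t_max
    fit.t_s_method, fit.t_max_fallback = method, fallback
    if not fit.t_s < fit.t_max:
        raise ValueError(f"degenerate window: t_s={t_s:.2f} >= "
                         f"t_max={t_max:.2f}")
    return fit
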