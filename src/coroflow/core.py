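"""Shared in-memory containers for the angiographic velocimetry pipeline.

The pipeline's raw input is an :class:`AngioSequence` (an ordered stack of
grayscale frames with acquisition metadata), its central intermediate is a
:class:`MaskSequence` (per-frame binary artery-tree segmentations), and the
per-frame tubular-structure likelihoods live in :class:`VesselnessMap`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AngioSequence", "VesselnessMap", "MaskSequence", "AreaSeries"]

#: Acquisition defaults for cine coronary angiography: 15 frames/s,
#: 0.2 mm per pixel, 8-bit intensities.
DEFAULT_FPS = 15.0
DEFAULT_PIXEL_SPACING_MM = 0.2
DEFAULT_BIT_DEPTH = 8


@dataclass
class AngioSequence:
    """Ordered stack of 2D grayscale frames with frame rate and pixel spacing.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, rows, cols)``. Stored as float64 so the
        preprocessing stages can work without clipping; 8-bit sources are
        kept on their native 0..255 scale.
    fps
        Frame rate in frames per second.
    pixel_spacing_mm
        Physical length of one pixel in millimetres.
    bit_depth
        Intensity quantization of the source data.
    """

    frames: np.ndarray
    fps: float = DEFAULT_FPS
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM
    bit_depth: int = DEFAULT_BIT_DEPTH

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) stack")
        if len(self.frames) < 2:
            raise ValueError("a sequence needs at least 2 frames")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]  # type: ignore[return-value]

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class VesselnessMap:
    """Per-pixel tubular-structure likelihood in [0, 1] for one frame."""

    scores: np.ndarray
    scales_px: tuple[float, ...]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 2:
            raise ValueError("scores must be 2D")
        if self.scores.min() < 0 or self.scores.max() > 1:
            raise ValueError("vesselness scores must lie in [0, 1]")


@dataclass
class MaskSequence:
    """Per-frame binary artery-tree segmentations ``B^k``.

    ``thresholds`` records the vesselness threshold used for each frame
    (provenance for the refinement loop, which lowers them adaptively).
    """

    masks: np.ndarray
    thresholds: list[float] = field(default_factory=list)
    refined: bool = False

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 3:
            raise ValueError("masks must be a (n_frames, rows, cols) stack")
        if not self.thresholds:
            self.thresholds = [float("nan")] * len(self.masks)
        if len(self.thresholds) != len(self.masks):
            raise ValueError("one threshold per frame required")

    @property
    def n_frames(self) -> int:
        return len(self.masks)

    def __len__(self) -> int:
        return self.n_frames

    def copy(self) -> "MaskSequence":
        return MaskSequence(self.masks.copy(), list(self.thresholds), self.refined)


@dataclass
class AreaSeries:
    """Segmented artery-tree area (pixel count) per frame."""

    frame_index: np.ndarray
    area_px: np.ndarray

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.area_px = np.asarray(self.area_px, dtype=np.float64)
        if self.frame_index.shape != self.area_px.shape:
            raise ValueError("frame_index and area_px must align")
        if np.any(self.area_px < 0):
            raise ValueError("areas are pixel counts and cannot be negative")

    def __len__(self) -> int:
        return len(self.frame_index)
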