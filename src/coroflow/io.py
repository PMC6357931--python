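"""Sequence readers and writers.

Reads multi-frame DICOM XA files or ordered TIFF/PNG stacks into an
:class:`~coroflow.core.AngioSequence`; frame rate and pixel spacing come
from DICOM metadata when present, then from explicit overrides, then from
the acquisition defaults (15 fps, 0.2 mm/pixel) with a warning.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pydicom
import tifffile

from .core import (AngioSequence, DEFAULT_FPS, DEFAULT_PIXEL_SPACING_MM,
                   MaskSequence)

__all__ = ["read_sequence", "write_sequence", "write_masks", "read_masks"]

_FRAME_SUFFIXES = {".png", ".tif", ".tiff"}


def _read_dicom(path: Path, fps_override, spacing_override) -> AngioSequence:
    ds = pydicom.dcmread(path)
    frames = np.asarray(ds.pixel_array, dtype=np.float64)
    if frames.ndim == 2:
        raise ValueError(f"{path} holds a single frame, not a cine sequence")
    fps = fps_override
    if fps is None:
        if "CineRate" in ds:
            fps = float(ds.CineRate)
        elif "FrameTime" in ds and float(ds.FrameTime) > 0:
            fps = 1000.0 / float(ds.FrameTime)
        else:
            fps = DEFAULT_FPS
            warnings.warn(f"no frame-rate tag in {path.name}; "
                          f"assuming {fps} fps")
    spacing = spacing_override
    if spacing is None:
        tag = ds.get("ImagerPixelSpacing") or ds.get("PixelSpacing")
        if tag is not None:
            spacing = float(tag[0])
        else:
            spacing = DEFAULT_PIXEL_SPACING_MM
            warnings.warn(f"no pixel-spacing tag in {path.name}; "
                          f"assuming {spacing} mm/px")
    bits = int(ds.get("BitsStored", 8))
    return AngioSequence(frames, fps=fps, pixel_spacing_mm=spacing,
                         bit_depth=bits)


def _read_frames_dir(path: Path, fps, spacing) -> AngioSequence:
    files = sorted(p for p in path.iterdir()
                   if p.suffix.lower() in _FRAME_SUFFIXES)
    if not files:
        raise ValueError(f"no frame images found in {path}")
    frames = []
    for f in files:
        try:
            img = iio.imread(f)
        except Exception as err:
            raise ValueError(f"unreadable frame file {f.name}: {err}") from err
        if img.ndim == 3:  # collapse RGB(A) to grayscale
            img = img[..., :3].mean(axis=-1)
        frames.append(np.asarray(img, dtype=np.float64))
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"mixed frame shapes in {path}: {sorted(shapes)}")
    return AngioSequence(np.stack(frames), fps=fps, pixel_spacing_mm=spacing)


def read_sequence(path, fps_override: float | None = None,
                  spacing_override_mm: float | None = None) -> AngioSequence:
    """Read a cine sequence from a DICOM file, a multi-page TIFF, or a
    directory of lexically ordered TIFF/PNG frames."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        fps = fps_override
        spacing = spacing_override_mm
        if fps is None:
            fps = DEFAULT_FPS
            warnings.warn(f"no frame rate given for {path.name}; "
                          f"assuming {fps} fps")
        if spacing is None:
            spacing = DEFAULT_PIXEL_SPACING_MM
            warnings.warn(f"no pixel spacing given for {path.name}; "
                          f"assuming {spacing} mm/px")
        return _read_frames_dir(path, fps, spacing)
    if path.suffix.lower() in (".dcm", ".dicom", ""):
        try:
            return _read_dicom(path, fps_override, spacing_override_mm)
        except pydicom.errors.InvalidDicomError:
            pass  # fall through to image-stack readers
    if path.suffix.lower() in (".tif", ".tiff"):
        frames = np.asarray(tifffile.imread(path), dtype=np.float64)
        if frames.ndim != 3:
            raise ValueError(f"{path} is not a multi-frame stack")
        fps = fps_override if fps_override is not None else DEFAULT_FPS
        spacing = (spacing_override_mm if spacing_override_mm is not None
                   else DEFAULT_PIXEL_SPACING_MM)
        if fps_override is None or spacing_override_mm is None:
            warnings.warn(f"metadata-free stack {path.name}: using "
                          f"{fps} fps, {spacing} mm/px")
        return AngioSequence(frames, fps=fps, pixel_spacing_mm=spacing)
    raise ValueError(f"unsupported sequence source: {path}")


def write_sequence(seq: AngioSequence, path) -> None:
    """Write frames as an 8-bit multi-page TIFF."""
    arr = np.clip(np.round(seq.frames), 0, 255).astype(np.uint8)
    tifffile.imwrite(Path(path), arr, photometric='minisblack')


def write_masks(masks: MaskSequence, path) -> None:
    tifffile.imwrite(Path(path), masks.masks.astype(np.uint8) * 255,
                     photometric='minisblack')


def read_masks(path) -> MaskSequence:
    arr = tifffile.imread(Path(path)) > 0
    if arr.ndim == 2:
        arr = arr[None]
    return MaskSequence(arr)
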