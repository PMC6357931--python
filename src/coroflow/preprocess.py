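"""Edge sharpening and background suppression by unsharp masking.

A blurred estimate of each frame is produced by convolving with a 3x3
Laplacian kernel and subtracted from the frame:

    I_s = I - (I * f_laplace)

with ``f_laplace`` the 4-neighbour Laplacian [[0,1,0],[1,-4,1],[0,1,0]].
Since the kernel sums to zero, the interior mean is preserved; edges are
enhanced while smooth organ-shadow gradients pass through unchanged.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

__all__ = ["unsharp_mask", "LAPLACE_KERNEL"]

LAPLACE_KERNEL = np.array([[0.0, 1.0, 0.0],
                           [1.0, -4.0, 1.0],
                           [0.0, 1.0, 0.0]])


def unsharp_mask(frame: np.ndarray, alpha: float | None = None) -> np.ndarray:
    """Sharpen one frame: ``I - (I * f_laplace)``.

    The output stays in floating representation (no clipping back to 8
    bits) and borders are replicate-padded, which avoids ringing where the
    catheter enters the image.

    Parameters
    ----------
    frame
        2D intensity array, at least 3x3.
    alpha
        If given, use the classic parametric 3x3 unsharp kernel of strength
        ``alpha`` (as built from the negative of a scaled Laplacian)
        instead of the plain Laplacian subtraction, for sensitivity checks.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2 or min(frame.shape) < 3:
        raise ValueError("frame must be a 2D array of at least 3x3 pixels")
    if alpha is None:
        lap = ndi.convolve(frame, LAPLACE_KERNEL, mode="nearest")
        return frame - lap
    # classic parametric 3x3 unsharp kernel (identity minus an
    # alpha-weighted Laplacian, normalized so a constant is unchanged)
    kernel = np.array([[-alpha, alpha - 1.0, -alpha],
                       [alpha - 1.0, alpha + 5.0, alpha - 1.0],
                       [-alpha, alpha - 1.0, -alpha]]) / (alpha + 1.0)
    return ndi.convolve(frame, kernel, mode="nearest")
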