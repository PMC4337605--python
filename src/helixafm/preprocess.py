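"""Image preprocessing applied before any measurement.

Two filters: spike-noise removal (replace pixels that deviate from their
local median by more than a threshold) and first-order plane flattening
(subtract a least-squares plane fitted to background pixels). Both are
idempotent and preserve genuine topography.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .frames import HeightFrame

__all__ = ["remove_spike_noise", "flatten_plane", "local_median"]


def local_median(grid: np.ndarray, window_px: int) -> np.ndarray:
    """Median over a window clipped at the frame edges.

    Border pixels use the shrinking neighborhood that remains inside the
    frame (no padding values are invented).
    """
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window_px must be an odd integer >= 3")
    r = window_px // 2
    padded = np.full(
        (grid.shape[0] + 2 * r, grid.shape[1] + 2 * r), np.nan, dtype=float
    )
    padded[r:-r, r:-r] = grid
    stack = np.stack(
        [
            padded[r + dy : r + dy + grid.shape[0], r + dx : r + dx + grid.shape[1]]
            for dy in range(-r, r + 1)
            for dx in range(-r, r + 1)
        ]
    )
    return np.nanmedian(stack, axis=0)


def remove_spike_noise(
    frame: HeightFrame, window_px: int = 3, spike_threshold_nm: float = 2.0
) -> HeightFrame:
    """Replace spike pixels by their local median.

    A pixel deviating from the median of its ``window_px`` x ``window_px``
    neighborhood by more than ``spike_threshold_nm`` is replaced by that
    median; every other pixel is left bit-identical. Frames already
    within threshold everywhere pass through unchanged, which also makes
    the filter idempotent.
    """
    med = local_median(frame.grid, window_px)
    out = frame.grid.copy()
    spikes = np.abs(frame.grid - med) > spike_threshold_nm
    out[spikes] = med[spikes]
    return frame.copy_with(out)


def flatten_plane(frame: HeightFrame, mask: Optional[np.ndarray] = None) -> HeightFrame:
    """Subtract the least-squares plane fitted to background pixels.

    Parameters
    ----------
    mask : bool array, optional
        True marks *foreground* (filaments etc.) excluded from the fit.
        With no mask, the plane is fitted to every pixel.

    After subtraction the background mean is zero and height differences
    between any two pixels are preserved up to the fitted plane.
    """
    grid = frame.grid
    rows, cols = np.mgrid[0 : grid.shape[0], 0 : grid.shape[1]]
    if mask is None:
        bg = np.ones(grid.shape, dtype=bool)
    else:
        bg = ~np.asarray(mask, dtype=bool)
    if bg.sum() < 3:
        raise ValueError("need at least 3 background pixels to fit a plane")
    A = np.column_stack([np.ones(bg.sum()), cols[bg], rows[bg]])
    if np.linalg.matrix_rank(A) < 3:
        raise ValueError("background pixels are collinear; plane fit is degenerate")
    coef, *_ = np.linalg.lstsq(A, grid[bg], rcond=None)
    plane = coef[0] + coef[1] * cols + coef[2] * rows
    return frame.copy_with(grid - plane)
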