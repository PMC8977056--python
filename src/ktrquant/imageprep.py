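"""Per-channel preprocessing that turns raw stacks into segmentation-ready images.

Three operations, applied per frame: constant subtraction for the nuclear
marker channel (removes cytoplasmic counts from marker overexpression),
rolling-ball background removal for the Akt reporter channel, and a
blur-plus-threshold cell mask from the ERK reporter channel. Channels are
not unmixed (cross-excitation and bleed-through are assumed negligible).
"""

from __future__ import annotations

import math

import numpy as np
from skimage import restoration, transform
from skimage.measure import block_reduce
from scipy import ndimage


def subtract_constant(image: np.ndarray, c: float) -> np.ndarray:
    """Subtract ``c`` counts, clamping at zero. Integer-valued output."""
    if c < 0:
        raise ValueError("c must be >= 0")
    out = np.asarray(image, dtype=np.int64) - int(c)
    np.maximum(out, 0, out=out)
    return out


def rolling_ball_background(image: np.ndarray, radius: float = 70.0,
                            *, downscale: int | None = None,
                            return_background: bool = False):
    """Rolling-ball background subtraction.

    Estimates the background as the surface traced by a ball of the given
    radius rolled under the intensity landscape and subtracts it. For large
    radii the image is first reduced by a local-minimum downscale (the same
    scheme FIJI uses), the ball is rolled on the reduced image, and the
    background is upscaled; the estimate is finally clipped to lie at or
    below the image so the output is nonnegative everywhere.

    Features narrower than the ball radius ride on top of the estimated
    background and are preserved.
    """
    image = np.asarray(image, dtype=float)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius >= max(image.shape):
        raise ValueError(
            f"ball radius {radius} does not fit in image of shape {image.shape}")
    if downscale is None:
        downscale = max(1, int(radius) // 10)
    if downscale > 1:
        small = block_reduce(image, (downscale, downscale), np.min)
        bg_small = restoration.rolling_ball(small, radius=radius / downscale)
        bg = transform.resize(bg_small,
                              (small.shape[0] * downscale, small.shape[1] * downscale),
                              order=1, mode="edge", anti_aliasing=False)
        bg = bg[: image.shape[0], : image.shape[1]]
    else:
        bg = restoration.rolling_ball(image, radius=radius)
    np.minimum(bg, image, out=bg)
    out = image - bg
    if return_background:
        return out, bg
    return out


def make_cell_mask(image: np.ndarray, sigma: float = 2.0,
                   lo: float = 300.0, hi: float = 65535.0) -> np.ndarray:
    """Binary cell mask: Gaussian blur then an inclusive [lo, hi] threshold.

    Defaults match a sigma-2 blur and a 300-65535 manual threshold on raw
    counts. ``sigma=0`` reduces to direct thresholding.
    """
    if not lo < hi:
        raise ValueError("lo must be < hi")
    image = np.asarray(image, dtype=float)
    if sigma > 0:
        blurred = ndimage.gaussian_filter(image, sigma=sigma, mode="reflect")
    else:
        blurred = image
    return (blurred >= lo) & (blurred <= hi)


def preprocess_stack(stack: np.ndarray, *, nuclear_subtract: float = 250.0,
                     akt_ball_radius: float = 70.0, mask_sigma: float = 2.0,
                     mask_lo: float = 300.0, mask_hi: float = 65535.0,
                     nuclear_ch: int = 0, akt_ch: int = 1, erk_ch: int = 2):
    """Apply the per-channel preprocessing to a (T, C, H, W) stack.

    Returns (nuclear_frames, akt_frames, erk_frames, cell_masks), each a
    (T, H, W) array. The ERK channel is used raw for quantification and,
    blurred and thresholded, for the cell mask.
    """
    n_t = stack.shape[0]
    nuc = np.empty(stack.shape[0:1] + stack.shape[2:], dtype=np.int64)
    akt = np.empty_like(nuc, dtype=float)
    masks = np.empty_like(nuc, dtype=bool)
    for t in range(n_t):
        nuc[t] = subtract_constant(stack[t, nuclear_ch], nuclear_subtract)
        akt[t] = rolling_ball_background(stack[t, akt_ch], akt_ball_radius)
        masks[t] = make_cell_mask(stack[t, erk_ch], mask_sigma, mask_lo, mask_hi)
    erk = np.asarray(stack[:, erk_ch], dtype=float)
    return nuc, akt, erk, masks
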