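"""Signal isolation from registered section images.

Two independent channels are handled:

* axon label: probability-weighted intensity, edge-enhanced by subtracting a
  Gaussian blur, then binarized at a multiple of the standard deviation of
  the whole processed stack;
* activity marker: rolling-ball background subtraction followed by
  Laplacian-of-Gaussian blob detection at a fixed physical spot diameter,
  thresholded at a multiple of the SD of the background-subtracted stack.

Both SD thresholds are global over the full multi-slice stack, so results
are invariant under affine intensity rescaling of the input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.restoration import rolling_ball

__all__ = [
    "BinaryMask",
    "SpotList",
    "binarize_axon_signal",
    "subtract_background",
    "detect_spots",
]


@dataclass(frozen=True)
class BinaryMask:
    mask: np.ndarray  # boolean, same shape as the source stack
    pixel_um: float
    threshold: float  # absolute intensity threshold that was applied


@dataclass(frozen=True)
class SpotList:
    """Detected spot centers in physical units.

    ``centers`` has columns slice, x_um, y_um (x = column axis, y = row
    axis); within a slice all pairwise center distances are at least the
    detection spot diameter.
    """

    centers: pd.DataFrame
    detection_threshold: float
    spot_diameter_um: float


def _as_stack(image: np.ndarray) -> tuple[np.ndarray, bool]:
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        return arr[None, ...], True
    if arr.ndim == 3:
        return arr, False
    raise ValueError("expected a 2-D image or a 3-D stack")


def binarize_axon_signal(
    image: np.ndarray,
    probability_map: np.ndarray | None = None,
    gaussian_sigma_px: float = 10.0,
    sd_multiplier: float = 6.0,
    pixel_um: float = 1.0,
) -> BinaryMask:
    """Binarize the axon-label channel.

    The image (2-D or stack) is multiplied pixel-wise by ``probability_map``
    (min-max normalized intensity when omitted — a stand-in for an external
    pixel classifier), edge-enhanced by subtracting its Gaussian blur, and
    thresholded at ``sd_multiplier`` times the SD of the whole processed
    stack.  A constant input (SD = 0) yields an all-false mask with a
    warning rather than an error.
    """
    stack, squeeze = _as_stack(image)
    if probability_map is None:
        lo, hi = stack.min(), stack.max()
        prob = (stack - lo) / (hi - lo) if hi > lo else np.zeros_like(stack)
    else:
        prob, _ = _as_stack(probability_map)
        if prob.shape != stack.shape:
            raise ValueError("image and probability_map shapes differ")
        if prob.min() < 0 or prob.max() > 1:
            raise ValueError("probability_map values must lie in [0, 1]")
    filtered = stack * prob
    blurred = np.stack(
        [ndi.gaussian_filter(sl, gaussian_sigma_px) for sl in filtered]
    )
    enhanced = filtered - blurred
    sd = float(enhanced.std())
    if sd == 0.0:
        warnings.warn("constant processed stack (SD = 0): empty mask", stacklevel=2)
        mask = np.zeros_like(enhanced, dtype=bool)
        thr = np.inf
    else:
        thr = sd_multiplier * sd
        mask = enhanced > thr
    if squeeze:
        mask = mask[0]
    return BinaryMask(mask, pixel_um, thr)


def subtract_background(image: np.ndarray, rolling_radius_px: int = 50) -> np.ndarray:
    """Rolling-ball background subtraction, slice-wise; output clipped >= 0."""
    if rolling_radius_px < 1:
        raise ValueError("rolling_radius_px must be >= 1")
    stack, squeeze = _as_stack(image)
    out = np.stack(
        [sl - rolling_ball(sl, radius=rolling_radius_px) for sl in stack]
    )
    out = np.clip(out, 0.0, None)
    return out[0] if squeeze else out


def _log_response(img: np.ndarray, sigma_px: float) -> np.ndarray:
    # scale-normalized negative Laplacian of Gaussian (bright blobs -> peaks)
    return -(sigma_px**2) * ndi.gaussian_laplace(img, sigma_px)


def detect_spots(
    image: np.ndarray,
    pixel_um: float,
    spot_diameter_um: float = 10.0,
    sd_multiplier: float = 2.0,
) -> SpotList:
    """Detect cell-sized spots in a background-subtracted image or stack.

    Laplacian-of-Gaussian filtering at sigma = diameter / (2*sqrt(2)) is
    followed by local-maximum picking with a minimum separation of one spot
    diameter; maxima are kept when their response exceeds ``sd_multiplier``
    times the SD of the input stack.  Centers are refined to sub-pixel
    precision by the center of mass of a diameter-sized window and reported
    in micrometers.  Ties between equal maxima resolve to the lowest
    (row, col).  A constant stack yields an empty list with a warning.
    """
    if pixel_um > spot_diameter_um / 3.0:
        raise ValueError("pixel_um must be <= spot_diameter_um / 3")
    stack, _ = _as_stack(image)
    sd = float(stack.std())
    sigma_px = spot_diameter_um / (2.0 * np.sqrt(2.0)) / pixel_um
    min_dist_px = max(1, int(round(spot_diameter_um / pixel_um)))
    win = max(1, int(round(spot_diameter_um / pixel_um / 2.0)))

    rows = []
    if sd == 0.0:
        warnings.warn("constant stack (SD = 0): no spots detected", stacklevel=2)
    else:
        thr = sd_multiplier * sd
        for z, sl in enumerate(stack):
            resp = _log_response(sl, sigma_px)
            peaks = peak_local_max(
                resp, min_distance=min_dist_px, threshold_abs=thr, exclude_border=False
            )
            for r, c in peaks:
                r0, r1 = max(0, r - win), min(sl.shape[0], r + win + 1)
                c0, c1 = max(0, c - win), min(sl.shape[1], c + win + 1)
                patch = np.clip(sl[r0:r1, c0:c1], 0.0, None)
                tot = patch.sum()
                if tot > 0:
                    rr, cc = np.mgrid[r0:r1, c0:c1]
                    r_sub = float((rr * patch).sum() / tot)
                    c_sub = float((cc * patch).sum() / tot)
                else:
                    r_sub, c_sub = float(r), float(c)
                rows.append(
                    {"slice": z, "x_um": c_sub * pixel_um, "y_um": r_sub * pixel_um}
                )
        thr_out = thr
    centers = pd.DataFrame(rows, columns=["slice", "x_um", "y_um"])
    return SpotList(centers, thr_out if sd > 0 else np.inf, spot_diameter_um)
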