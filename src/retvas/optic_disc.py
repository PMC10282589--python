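"""Optic-disc detection and masking.

The optic disc (OD) is the bright, roughly circular region where vessels
enter the retina; it must be masked out before graph morphometrics so the
vascular trees are rooted.  Detection proceeds in three steps:

1. a rectangular region of interest (ROI) is centred on the brightest
   box-filtered spot of the mean-of-channels image inside the FOV;
2. the Shannon entropy (bits, 256-bin histogram) of each RGB channel within
   the ROI is measured, and the most informative channel — the one with
   maximal entropy — is selected for the geometric search;
3. a circular Hough transform over an edge map of the selected channel votes
   for (centre, radius); the accumulator peak, normalized by circumference,
   is the detection confidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import sobel
from skimage.transform import hough_circle

from .preprocess import FundusImage

__all__ = [
    "OpticDisc",
    "OpticDiscNotFoundError",
    "locate_od_roi",
    "channel_entropy",
    "hough_circle_od",
    "detect_od",
    "mask_od",
]

#: Disc radius search range as a fraction of the FOV diameter.
DEFAULT_RADIUS_FRAC = (0.04, 0.10)
#: ROI side as a fraction of the FOV diameter.
DEFAULT_ROI_FRAC = 0.30
#: Margin (fraction of detected radius) added when masking the disc.
DEFAULT_MARGIN_FRAC = 0.1
#: Minimum normalized accumulator peak for a detection to count.
DEFAULT_CONFIDENCE_FLOOR = 0.25

_CHANNELS = ("R", "G", "B")


class OpticDiscNotFoundError(RuntimeError):
    """Raised when no circle scores above the confidence floor."""


@dataclass(frozen=True)
class OpticDisc:
    centre: tuple[int, int]  # (row, col), full-image coordinates
    radius: int
    channel_used: str  # one of R, G, B
    entropies: tuple[float, float, float]  # bits, per channel
    confidence: float = 0.0


def locate_od_roi(
    image: FundusImage, fov: np.ndarray, roi_frac: float = DEFAULT_ROI_FRAC
) -> tuple[int, int, int, int]:
    """Locate the square ROI ``(r0, r1, c0, c1)`` that should contain the OD.

    The ROI is centred on the maximum of a box-filtered mean-of-channels
    brightness map inside the FOV; its side is ``roi_frac`` times the FOV
    (equivalent) diameter, clipped to the frame.  When all candidates tie
    (featureless image) the ROI centres on the FOV centroid.
    """
    if not (0 < roi_frac <= 0.5):
        raise ValueError("roi_frac must lie in (0, 0.5]")
    fov = np.asarray(fov, dtype=bool)
    if not fov.any():
        raise ValueError("FOV empty")
    h, w = fov.shape
    diameter = 2.0 * np.sqrt(fov.sum() / np.pi)
    side = max(16, int(round(roi_frac * diameter)))

    brightness = image.pixels.mean(axis=2)
    smooth = ndi.uniform_filter(brightness, size=max(3, side // 4))
    smooth = np.where(fov, smooth, -np.inf)
    peak = smooth.max()
    ties_r, ties_c = np.nonzero(smooth == peak)
    if len(ties_r) > 1:
        rr, cc = np.nonzero(fov)
        cr, ccol = int(round(rr.mean())), int(round(cc.mean()))
    else:
        cr, ccol = int(ties_r[0]), int(ties_c[0])

    half = side // 2
    r0 = min(max(cr - half, 0), max(h - side, 0))
    c0 = min(max(ccol - half, 0), max(w - side, 0))
    return (r0, min(r0 + side, h), c0, min(c0 + side, w))


def channel_entropy(roi_pixels: np.ndarray) -> float:
    """Shannon entropy in bits of the 256-bin grey histogram of one channel."""
    roi_pixels = np.asarray(roi_pixels)
    if roi_pixels.size == 0:
        raise ValueError("ROI is empty")
    hist = np.bincount(roi_pixels.astype(np.uint8).ravel(), minlength=256).astype(float)
    p = hist / hist.sum()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def hough_circle_od(
    grey_roi: np.ndarray,
    radius_range: tuple[int, int],
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
    edge_quantile: float = 0.90,
) -> tuple[tuple[int, int], int, float]:
    """Find the best circle in a grey ROI; returns ((row, col), radius, confidence).

    The edge map thresholds the Sobel gradient magnitude at ``edge_quantile``;
    edge pixels vote into a (centre, radius) accumulator at integer-pixel
    centres and 1-px radius steps.  The peak of the circumference-normalized
    accumulator wins; ties break to the larger radius, then the smaller row,
    then the smaller column.

    Raises
    ------
    OpticDiscNotFoundError
        If the peak confidence falls below ``confidence_floor``.
    """
    rmin, rmax = int(radius_range[0]), int(radius_range[1])
    if rmin >= rmax:
        raise ValueError("radius_range must satisfy rmin < rmax")
    grey_roi = np.asarray(grey_roi, dtype=np.float64)
    if min(grey_roi.shape) <= 2 * rmax:
        raise ValueError("ROI must be larger than twice the maximum radius")
    grad = sobel(grey_roi)
    if grad.max() <= 0:
        raise OpticDiscNotFoundError("blank ROI: no edges to vote")
    edges = grad >= np.quantile(grad[grad > 0], edge_quantile)
    radii = np.arange(rmin, rmax + 1)
    acc = hough_circle(edges, radii)  # (n_radii, H, W), circumference-normalized

    peak = acc.max()
    if peak < confidence_floor:
        raise OpticDiscNotFoundError(f"confidence {peak:.3f} below floor {confidence_floor}")
    ir, rr, cc = np.nonzero(acc == peak)
    # tie-break: larger radius, then smaller row, then smaller col
    order = np.lexsort((cc, rr, -radii[ir]))
    k = order[0]
    return (int(rr[k]), int(cc[k])), int(radii[ir[k]]), float(peak)


def detect_od(
    image: FundusImage,
    fov: np.ndarray,
    roi_frac: float = DEFAULT_ROI_FRAC,
    radius_frac: tuple[float, float] = DEFAULT_RADIUS_FRAC,
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
) -> OpticDisc:
    """Full OD detection: ROI, entropy-based channel choice, Hough search."""
    fov = np.asarray(fov, dtype=bool)
    r0, r1, c0, c1 = locate_od_roi(image, fov, roi_frac)
    roi = image.pixels[r0:r1, c0:c1]
    entropies = tuple(channel_entropy(roi[..., ch]) for ch in range(3))
    ch = int(np.argmax(entropies))
    diameter = 2.0 * np.sqrt(fov.sum() / np.pi)
    rmin = max(4, int(round(radius_frac[0] * diameter)))
    rmax = max(rmin + 2, int(round(radius_frac[1] * diameter)))
    rmax = min(rmax, (min(r1 - r0, c1 - c0) - 1) // 2)
    (pr, pc), radius, conf = hough_circle_od(
        roi[..., ch], (rmin, rmax), confidence_floor=confidence_floor
    )
    return OpticDisc(
        centre=(pr + r0, pc + c0),
        radius=radius,
        channel_used=_CHANNELS[ch],
        entropies=tuple(float(e) for e in entropies),
        confidence=conf,
    )


def mask_od(
    vessel_mask: np.ndarray, od: OpticDisc, margin_frac: float = DEFAULT_MARGIN_FRAC
) -> np.ndarray:
    """Remove vessel pixels within ``(1 + margin_frac) * radius`` of the disc centre."""
    mask = np.asarray(vessel_mask, dtype=bool).copy()
    h, w = mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    keep_out = np.hypot(yy - od.centre[0], xx - od.centre[1]) <= (1.0 + margin_frac) * od.radius
    mask[keep_out] = False
    return mask
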