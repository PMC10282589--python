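"""Segmentation-quality control and pair curation.

Two failure modes drive curation of paired comparisons:

* **Under-segmentation** — the mask misses most true vessels (dark,
  low-contrast captures).  With ground truth available the rule is direct:
  less than three-quarters of the true vessel pixels recovered.  Without
  truth (field mode) a coverage proxy is used: the fraction of 12 angular
  FOV sectors containing any skeleton pixel must reach three-quarters.
* **Over-segmentation** — lacework-like false vessels in elongated background
  patches.  The proxy is geometric: mask components that are blob-like
  (solidity above 0.5 and area above a floor, i.e. not curvilinear)
  contributing more than a set fraction of the total mask area.

Evaluability follows a disc-anchored grid extending 6.5 disc radii from the
disc centre toward the macula, truncated at the vertical extremes; an image
is acceptable when at least one of its two (superior/inferior) quadrants is
evaluable.  Both flags accept manual overrides so a human curation pass can
be replayed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as _sk_label
from skimage.measure import regionprops

from .optic_disc import OpticDisc
from .skeleton import skeletonize

__all__ = [
    "EvaluabilityGrid",
    "QcFlags",
    "build_grid",
    "assess_quadrant",
    "flag_under_segmentation",
    "flag_over_segmentation",
    "curate_pairs",
    "CurationResult",
]

UNDER_SEGMENTATION_FRACTION = 0.75  # of true vessels that must be recovered
N_ANGULAR_SECTORS = 12
DEFAULT_R_TOL = 10.0  # px; "reaches the grid boundary" tolerance
DEFAULT_DENSITY_FLOOR = 0.01  # vessel fraction a quadrant must exceed
DEFAULT_BLOB_MIN = 400.0  # px^2; smaller solid components are ignored
DEFAULT_PATCH_FRAC = 0.15  # of mask area in blobs that trips the flag
GRID_REACH_RADII = 6.5  # grid extent in disc radii


@dataclass(frozen=True)
class EvaluabilityGrid:
    """Disc-anchored assessment grid with two quadrants toward the macula."""

    disc_centre: tuple[int, int]
    disc_radius: float
    outer_reach: float  # = GRID_REACH_RADII * disc_radius
    macula_side: str  # "left" | "right"
    frame_shape: tuple[int, int]
    vertical_margin: int

    def quadrant_mask(self, quadrant: str) -> np.ndarray:
        """Boolean mask of one quadrant ('superior' | 'inferior')."""
        if quadrant not in ("superior", "inferior"):
            raise ValueError("quadrant must be 'superior' or 'inferior'")
        h, w = self.frame_shape
        yy, xx = np.mgrid[0:h, 0:w]
        d = np.hypot(yy - self.disc_centre[0], xx - self.disc_centre[1])
        m = (d > self.disc_radius) & (d <= self.outer_reach)
        if self.macula_side == "left":
            m &= xx <= self.disc_centre[1]
        else:
            m &= xx >= self.disc_centre[1]
        if quadrant == "superior":
            m &= yy <= self.disc_centre[0]
        else:
            m &= yy >= self.disc_centre[0]
        m[: self.vertical_margin] = False
        if self.vertical_margin:
            m[-self.vertical_margin :] = False
        return m


@dataclass(frozen=True)
class QcFlags:
    """Per-image curation flags; ``evaluable`` means >= 1 evaluable quadrant."""

    evaluable: bool
    quadrants_evaluable: tuple[bool, bool]
    under_segmented: bool
    over_segmented: bool

    @property
    def clean(self) -> bool:
        return not (self.under_segmented or self.over_segmented)


def build_grid(
    od: OpticDisc | None,
    frame_shape: tuple[int, int],
    macula_side: str = "left",
    vertical_margin_frac: float = 0.05,
) -> EvaluabilityGrid | None:
    """Build the evaluability grid; ``None`` when the disc was not found
    (such an image is unevaluable by definition)."""
    if od is None:
        return None
    if macula_side not in ("left", "right"):
        raise ValueError("macula_side must be 'left' or 'right'")
    return EvaluabilityGrid(
        disc_centre=tuple(int(v) for v in od.centre),
        disc_radius=float(od.radius),
        outer_reach=GRID_REACH_RADII * float(od.radius),
        macula_side=macula_side,
        frame_shape=tuple(frame_shape),
        vertical_margin=int(round(vertical_margin_frac * frame_shape[0])),
    )


def assess_quadrant(
    mask: np.ndarray,
    grid: EvaluabilityGrid,
    quadrant: str,
    r_tol: float = DEFAULT_R_TOL,
    density_floor: float = DEFAULT_DENSITY_FLOOR,
) -> bool:
    """A quadrant is evaluable when the major trees reach the grid boundary.

    Concretely: some skeleton pixel of the quadrant-restricted mask lies
    within ``r_tol`` of the quadrant's outer arc, and the quadrant's vessel
    pixel density exceeds ``density_floor`` (a serious-artefact proxy).
    """
    mask = np.asarray(mask, dtype=bool)
    qmask = grid.quadrant_mask(quadrant)
    area = qmask.sum()
    if area == 0:
        return False
    inq = mask & qmask
    if inq.sum() / area <= density_floor:
        return False
    skel = skeletonize(inq)
    rr, cc = np.nonzero(skel)
    if rr.size == 0:
        return False
    d = np.hypot(rr - grid.disc_centre[0], cc - grid.disc_centre[1])
    return bool((d >= grid.outer_reach - r_tol).any())


def flag_under_segmentation(
    mask: np.ndarray,
    fov: np.ndarray,
    truth: np.ndarray | None = None,
) -> bool:
    """True when fewer than three-quarters of the vessels were segmented.

    With ``truth``, the recovered fraction |mask & truth| / |truth| is tested
    directly.  In field mode (no truth) the FOV is divided into 12 angular
    sectors about its centroid and the fraction of sectors containing any
    skeleton pixel stands in for coverage; ties at exactly three-quarters
    pass.
    """
    mask = np.asarray(mask, dtype=bool)
    fov = np.asarray(fov, dtype=bool)
    if mask.shape != fov.shape:
        raise ValueError("mask and fov must be congruent")
    if truth is not None:
        truth = np.asarray(truth, dtype=bool) & fov
        n_true = truth.sum()
        if n_true == 0:
            raise ValueError("truth mask empty inside FOV")
        return bool((mask & truth).sum() / n_true < UNDER_SEGMENTATION_FRACTION)

    rr, cc = np.nonzero(fov)
    cr, ccol = rr.mean(), cc.mean()
    skel = skeletonize(mask & fov)
    sr, sc = np.nonzero(skel)
    if sr.size == 0:
        return True
    ang = np.arctan2(sr - cr, sc - ccol)
    sectors = np.unique(((ang + np.pi) / (2 * np.pi) * N_ANGULAR_SECTORS).astype(int) % N_ANGULAR_SECTORS)
    return bool(sectors.size / N_ANGULAR_SECTORS < UNDER_SEGMENTATION_FRACTION)


def flag_over_segmentation(
    mask: np.ndarray,
    fov: np.ndarray | None = None,
    blob_min: float = DEFAULT_BLOB_MIN,
    patch_frac: float = DEFAULT_PATCH_FRAC,
) -> bool:
    """True when blob-like (non-curvilinear) components dominate the mask.

    A component counts as a lacework/patch artefact when its solidity exceeds
    0.5 and its area exceeds ``blob_min`` px²; the flag trips when such
    components exceed ``patch_frac`` of the total mask area.
    """
    mask = np.asarray(mask, dtype=bool)
    if fov is not None:
        mask = mask & np.asarray(fov, dtype=bool)
    total = mask.sum()
    if total == 0:
        return False
    blob_area = 0
    for prop in regionprops(_sk_label(mask, connectivity=2)):
        if prop.area > blob_min and prop.solidity > 0.5:
            blob_area += prop.area
    return bool(blob_area / total > patch_frac)


@dataclass
class CurationResult:
    retained: list[int]
    eliminated: list[int]
    counts: dict  # Table-2-shaped contingency of failure types by arm

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def curate_pairs(pair_flags: list[tuple[QcFlags, QcFlags]]) -> CurationResult:
    """Retain the pairs in which neither arm is under- or over-segmented.

    ``pair_flags`` holds one ``(reference_arm, handheld_arm)`` flag pair per
    eye.  The counts table records, by failure type, whether the failure hit
    the reference arm only, the handheld arm only, or both.
    """
    retained, eliminated = [], []
    counts = {
        "n_pairs": len(pair_flags),
        "handheld_only": 0,
        "reference_only": 0,
        "both": 0,
        "under_segmented": {"reference": 0, "handheld": 0},
        "over_segmented": {"reference": 0, "handheld": 0},
    }
    for i, (fl_ref, fl_hh) in enumerate(pair_flags):
        bad_ref = not fl_ref.clean
        bad_hh = not fl_hh.clean
        if fl_ref.under_segmented:
            counts["under_segmented"]["reference"] += 1
        if fl_hh.under_segmented:
            counts["under_segmented"]["handheld"] += 1
        if fl_ref.over_segmented:
            counts["over_segmented"]["reference"] += 1
        if fl_hh.over_segmented:
            counts["over_segmented"]["handheld"] += 1
        if bad_ref and bad_hh:
            counts["both"] += 1
        elif bad_ref:
            counts["reference_only"] += 1
        elif bad_hh:
            counts["handheld_only"] += 1
        (eliminated if (bad_ref or bad_hh) else retained).append(i)
    counts["n_retained"] = len(retained)
    return CurationResult(retained=retained, eliminated=eliminated, counts=counts)
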