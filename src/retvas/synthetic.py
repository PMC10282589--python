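"""Synthetic paired fundus photographs with full ground truth.

The study design this package supports compares retinal vessel morphometrics
between a desktop reference camera and a handheld device photographing the
same eye.  This module generates matched image pairs for that design: one
shared ground-truth vascular tree per eye, rendered twice — once cleanly
(reference arm) and once through a configurable degradation profile
(handheld arm) imposing underexposure, reduced contrast, blur, vignetting,
sensor noise and a controlled vessel thinning that creates a *known*
vessel-density deficit for parameter-recovery experiments.

The tree generator grows a planar rooted forest from the optic-disc rim by
recursive branching: each branch is a jittered polyline; at its distal end it
either bifurcates (child widths tapered by a fixed factor, bifurcation angle
sampled in [20 deg, 50 deg]) or terminates.  The model aims at visual and
statistical plausibility (branching density, width taper, tortuosity), not at
haemodynamic realism.

Everything is deterministic for a fixed seed, bit for bit.
"""

from __future__ import annotations

import csv
import json

import imageio.v3 as iio
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import line as _draw_line

from .preprocess import FundusImage, save_image
from .skeleton import GraphEdge, GraphNode, VesselGraph

__all__ = [
    "DeviceProfile",
    "REFERENCE_PROFILE",
    "HANDHELD_PROFILE",
    "VesselTree",
    "GroundTruth",
    "SegmentationScore",
    "generate_vessel_tree",
    "rasterize",
    "render_fundus",
    "render_float",
    "effective_vessel_mask",
    "make_paired_dataset",
    "score_segmentation",
    "write_dataset",
]

#: Default raster size — a desk-scale stand-in for full-resolution fundus frames.
DEFAULT_IMAGE_SIZE = (768, 768)

#: Green-channel depth (grey levels) by which vessels sit below the local background.
DEFAULT_VESSEL_DEPTH = 60.0


@dataclass(frozen=True)
class DeviceProfile:
    """Fixed photometric/geometric degradation profile of one camera arm.

    The reference arm is the identity profile.  ``vessel_erosion_px`` thins
    the rendered vessels before drawing, imposing a mask-level density
    deficit that downstream recovery tests can use as exact truth.
    """

    name: str
    brightness_gain: float = 1.0
    contrast_gain: float = 1.0
    blur_sigma: float = 0.0
    noise_sd: float = 0.0
    vignette_strength: float = 0.0
    vessel_erosion_px: int = 0

    def __post_init__(self) -> None:
        for attr in ("brightness_gain", "contrast_gain"):
            v = getattr(self, attr)
            if not (0 < v <= 2) or not np.isfinite(v):
                raise ValueError(f"{attr} must lie in (0, 2], got {v}")
        for attr in ("blur_sigma", "noise_sd"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if not (0 <= self.vignette_strength <= 1):
            raise ValueError("vignette_strength must lie in [0, 1]")
        if self.vessel_erosion_px < 0:
            raise ValueError("vessel_erosion_px must be >= 0")


REFERENCE_PROFILE = DeviceProfile(name="reference")

#: Default handheld arm: underexposed, low-contrast, slightly blurred and
#: noisy, with a mild vignette — the failure pattern handheld fundus cameras
#: show in practice.  Capture-to-capture variability is added on top by
#: :func:`make_paired_dataset`'s jitter.
HANDHELD_PROFILE = DeviceProfile(
    name="handheld",
    brightness_gain=0.85,
    contrast_gain=0.82,
    blur_sigma=0.8,
    noise_sd=2.0,
    vignette_strength=0.45,
    vessel_erosion_px=1,
)


@dataclass
class VesselTree:
    """A generated centre-line forest, before rasterization."""

    graph: VesselGraph
    widths: list[float]  # per edge, px
    fov_centre: tuple[float, float]
    fov_radius: float
    od_centre: tuple[float, float]
    od_radius: float

    @property
    def n_edges(self) -> int:
        return self.graph.n_edges

    @property
    def n_terminal(self) -> int:
        return self.graph.n_terminal

    @property
    def n_bifurcation(self) -> int:
        return sum(n.kind == "bifurcation" for n in self.graph.nodes)


@dataclass
class GroundTruth:
    """Rasterized truth for one synthetic eye."""

    vessel_mask: np.ndarray
    centerline_graph: VesselGraph
    od_centre: tuple[float, float]
    od_radius: float
    fov_mask: np.ndarray
    true_density: float  # % of FOV pixels that are vessel
    tree: VesselTree | None = field(default=None, repr=False)


@dataclass(frozen=True)
class SegmentationScore:
    tpr: float
    fpr: float


# ---------------------------------------------------------------------------
# tree growth
# ---------------------------------------------------------------------------

def generate_vessel_tree(
    seed: int,
    n_roots: int = 8,
    branch_prob: float = 0.85,
    depth_max: int = 6,
    width_root_px: float = 10.0,
    fov_radius: float = 368.0,
    fov_centre: tuple[float, float] = (384.0, 384.0),
    od_radius: float = 40.0,
    root_len: float = 115.0,
    width_taper: float = 0.8,
    len_taper: float = 0.85,
    turn_sd_deg: float = 7.0,
) -> VesselTree:
    """Grow a planar rooted vessel forest emanating from the optic-disc rim.

    With ``branch_prob=0`` each root yields a single unbranched edge; with
    ``branch_prob=1`` every branch bifurcates until ``depth_max``, giving a
    full binary tree per root.  Child widths shrink strictly by
    ``width_taper`` per generation.  All coordinates stay inside the FOV
    circle (branches are truncated at 95% of the FOV radius).
    """
    if n_roots < 1:
        raise ValueError("n_roots must be >= 1")
    if not (0 <= branch_prob <= 1):
        raise ValueError("branch_prob must lie in [0, 1]")
    if width_root_px < 1:
        raise ValueError("width_root_px must be >= 1 px")
    if fov_radius <= 0 or od_radius <= 0 or depth_max < 1 or root_len <= 0:
        raise ValueError("geometry parameters must be positive")

    rng = np.random.default_rng(int(seed))
    cr, cc = float(fov_centre[0]), float(fov_centre[1])
    # optic disc sits nasally, halfway to the FOV edge; macula side is -col
    od_centre = (cr, cc + 0.52 * fov_radius)
    r_limit = 0.95 * fov_radius

    graph = VesselGraph()
    widths: list[float] = []

    def add_node(pos, kind):
        graph.nodes.append(GraphNode(pos=(int(round(pos[0])), int(round(pos[1]))), kind=kind))
        return len(graph.nodes) - 1

    def inside(p) -> bool:
        return (p[0] - cr) ** 2 + (p[1] - cc) ** 2 <= r_limit**2

    def clamp_to_fov(p0, p1):
        """Shorten the step p0->p1 so its end lies on the FOV limit circle."""
        d = np.asarray(p1) - np.asarray(p0)
        lo, hi = 0.0, 1.0
        for _ in range(40):
            mid = (lo + hi) / 2
            if inside(np.asarray(p0) + mid * d):
                lo = mid
            else:
                hi = mid
        return tuple(np.asarray(p0) + lo * d)

    def grow(start, start_node, angle, width, length, depth) -> None:
        n_steps = 4
        step = length / n_steps
        pts = [start]
        a = angle
        truncated = False
        for _ in range(n_steps):
            a += np.deg2rad(rng.normal(0.0, turn_sd_deg))
            nxt = (pts[-1][0] + step * np.sin(a), pts[-1][1] + step * np.cos(a))
            if not inside(nxt):
                nxt = clamp_to_fov(pts[-1], nxt)
                pts.append(nxt)
                truncated = True
                break
            pts.append(nxt)
        end = pts[-1]
        branching = (
            not truncated and depth < depth_max and rng.random() < branch_prob
        )
        end_node = add_node(end, "bifurcation" if branching else "terminal")
        poly = np.array(pts, dtype=float)
        seglen = float(np.sum(np.hypot(*np.diff(poly, axis=0).T)))
        graph.edges.append(GraphEdge(a=start_node, b=end_node, polyline=poly, length=seglen))
        widths.append(width)
        if branching:
            half1 = np.deg2rad(rng.uniform(10.0, 25.0))
            half2 = np.deg2rad(rng.uniform(10.0, 25.0))
            child_w = width * 0.8
            child_len = length * len_taper
            grow(end, end_node, a - half1, child_w, child_len, depth + 1)
            grow(end, end_node, a + half2, child_w, child_len, depth + 1)

    # roots fan out from the disc rim toward the macula half of the fundus
    base_angles = np.linspace(np.pi / 2, 3 * np.pi / 2, n_roots + 2)[1:-1]
    for ang in base_angles:
        a = float(ang + np.deg2rad(rng.normal(0.0, 6.0)))
        start = (
            od_centre[0] + od_radius * np.sin(a),
            od_centre[1] + od_radius * np.cos(a),
        )
        root_node = add_node(start, "root")
        grow(start, root_node, a, width_root_px, root_len, 1)

    # degrees from incidence; roots and provisional kinds kept
    deg = [0] * len(graph.nodes)
    for e in graph.edges:
        deg[e.a] += 1
        deg[e.b] += 1
    for i, n in enumerate(graph.nodes):
        n.degree = deg[i]

    return VesselTree(
        graph=graph,
        widths=widths,
        fov_centre=(cr, cc),
        fov_radius=float(fov_radius),
        od_centre=od_centre,
        od_radius=float(od_radius),
    )


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _half_width_disk(width: float) -> np.ndarray:
    """Offsets within the stroke half-width (w-1)/2 of the centre pixel.

    With the centre pixel included a width-``w`` stroke spans exactly ``w``
    pixels across.
    """
    half = max(0.0, (width - 1.0) / 2.0)
    r = int(np.floor(half))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return np.hypot(yy, xx) <= half


def rasterize(tree: VesselTree, image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE) -> GroundTruth:
    """Rasterize a vessel tree into binary vessel and FOV masks.

    Vessel pixels are those within each segment's half-width of its centre
    polyline (euclidean); the FOV is the circle recorded in the tree.  The
    true density is recomputed from the raster.
    """
    h, w = int(image_size[0]), int(image_size[1])
    for k, e in enumerate(tree.graph.edges):
        poly = np.asarray(e.polyline, dtype=float)
        if (poly[:, 0].min() < 0 or poly[:, 0].max() > h - 1
                or poly[:, 1].min() < 0 or poly[:, 1].max() > w - 1):
            raise ValueError(f"segment {k} leaves the raster: polyline bounds "
                             f"{poly.min(axis=0)}..{poly.max(axis=0)} for image {image_size}")

    yy, xx = np.mgrid[0:h, 0:w]
    fov = (yy - tree.fov_centre[0]) ** 2 + (xx - tree.fov_centre[1]) ** 2 <= tree.fov_radius**2

    mask = np.zeros((h, w), dtype=bool)
    by_width: dict[int, list[int]] = {}
    for k, wd in enumerate(tree.widths):
        by_width.setdefault(int(round(wd * 2)), []).append(k)  # half-px width bins
    for wkey, idxs in by_width.items():
        centre = np.zeros((h, w), dtype=bool)
        for k in idxs:
            poly = np.rint(np.asarray(tree.graph.edges[k].polyline, dtype=float)).astype(int)
            for (r0, c0), (r1, c1) in zip(poly[:-1], poly[1:]):
                rr, cc = _draw_line(r0, c0, r1, c1)
                centre[rr, cc] = True
        width = wkey / 2.0
        se = _half_width_disk(width)
        if se.shape == (1, 1):
            mask |= centre
        else:
            mask |= ndi.binary_dilation(centre, structure=se)
    mask &= fov

    density = 100.0 * mask.sum() / fov.sum()
    return GroundTruth(
        vessel_mask=mask,
        centerline_graph=tree.graph,
        od_centre=tree.od_centre,
        od_radius=tree.od_radius,
        fov_mask=fov,
        true_density=float(density),
        tree=tree,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def effective_vessel_mask(gt: GroundTruth, profile: DeviceProfile) -> np.ndarray:
    """The vessel mask actually drawn for this arm (after erosion)."""
    mask = gt.vessel_mask
    if profile.vessel_erosion_px > 0:
        mask = ndi.binary_erosion(mask, structure=_half_width_disk(2 * profile.vessel_erosion_px + 1))
    return mask


def _base_fundus(gt: GroundTruth, shape: tuple[int, int]) -> np.ndarray:
    """Clean retinal background: radial orange gradient, bright disc with rim."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cr, cc = (gt.tree.fov_centre if gt.tree is not None else (h / 2, w / 2))
    rad = gt.tree.fov_radius if gt.tree is not None else min(h, w) * 0.48
    d2 = ((yy - cr) ** 2 + (xx - cc) ** 2) / rad**2
    img = np.empty((h, w, 3), dtype=np.float64)
    img[..., 0] = 190.0 - 50.0 * d2
    img[..., 1] = 120.0 - 35.0 * d2
    img[..., 2] = 45.0 - 18.0 * d2

    od_d = np.hypot(yy - gt.od_centre[0], xx - gt.od_centre[1])
    rim = (od_d > gt.od_radius) & (od_d <= gt.od_radius + 3)
    disc = od_d <= gt.od_radius
    img[rim] = (170.0, 110.0, 55.0)
    img[disc] = (240.0, 205.0, 135.0)
    for ch in range(3):
        img[..., ch] = ndi.gaussian_filter(img[..., ch], 1.5)
    img[~gt.fov_mask] = 3.0
    return img


def render_float(
    gt: GroundTruth,
    profile: DeviceProfile,
    seed: int,
    vessel_depth: float = DEFAULT_VESSEL_DEPTH,
) -> np.ndarray:
    """Render one arm as a float RGB image, before clipping/quantization.

    Degradations are applied in fixed order: erode vessels -> vignette ->
    contrast -> brightness -> blur -> additive Gaussian noise.
    """
    rng = np.random.default_rng(int(seed))
    img = _base_fundus(gt, gt.fov_mask.shape)

    vmask = effective_vessel_mask(gt, profile)
    img[..., 0][vmask] -= 0.45 * vessel_depth
    img[..., 1][vmask] -= vessel_depth
    img[..., 2][vmask] -= 0.20 * vessel_depth

    h, w = gt.fov_mask.shape
    if profile.vignette_strength > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        cr, cc = h / 2.0, w / 2.0
        rad = gt.tree.fov_radius if gt.tree is not None else min(h, w) * 0.48
        fall = 1.0 - profile.vignette_strength * ((yy - cr) ** 2 + (xx - cc) ** 2) / rad**2
        img *= np.clip(fall, 0.0, None)[..., None]
    if profile.contrast_gain != 1.0:
        for ch in range(3):
            m = img[..., ch][gt.fov_mask].mean()
            img[..., ch] = m + profile.contrast_gain * (img[..., ch] - m)
    if profile.brightness_gain != 1.0:
        img *= profile.brightness_gain
    if profile.blur_sigma > 0:
        for ch in range(3):
            img[..., ch] = ndi.gaussian_filter(img[..., ch], profile.blur_sigma)
    if profile.noise_sd > 0:
        img = img + rng.normal(0.0, profile.noise_sd, size=img.shape)
    return img


def render_fundus(
    gt: GroundTruth,
    profile: DeviceProfile,
    seed: int,
    vessel_depth: float = DEFAULT_VESSEL_DEPTH,
) -> FundusImage:
    """Render one arm of a synthetic eye as an 8-bit RGB fundus photograph."""
    img = render_float(gt, profile, seed, vessel_depth)
    px = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return FundusImage(pixels=px, device_label=profile.name, fov_mask=gt.fov_mask.copy())


# ---------------------------------------------------------------------------
# paired dataset
# ---------------------------------------------------------------------------

def make_paired_dataset(
    n_eyes: int,
    ref_profile: DeviceProfile = REFERENCE_PROFILE,
    hh_profile: DeviceProfile = HANDHELD_PROFILE,
    seed: int = 0,
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE,
    hh_jitter: float = 0.0,
    tree_kwargs: dict | None = None,
) -> list[tuple[FundusImage, FundusImage, GroundTruth]]:
    """Generate ``n_eyes`` paired renders sharing one ground truth per eye.

    Per-eye sub-seeds are derived deterministically from the master seed.
    ``hh_jitter`` adds capture-to-capture variability to the handheld arm:
    its brightness and contrast gains are multiplied by per-eye uniform
    factors in [1-j, 1+j], emulating the inconsistent exposure of handheld
    photography.  With ``hh_jitter=0`` and ``hh_profile == ref_profile`` the
    two renders of an eye are bit-identical.
    """
    if n_eyes < 1:
        raise ValueError("n_eyes must be >= 1")
    h, w = image_size
    kw = dict(
        fov_radius=0.48 * min(h, w),
        fov_centre=(h / 2.0, w / 2.0),
    )
    scale = min(h, w) / 768.0
    kw.update(
        od_radius=40.0 * scale,
        root_len=115.0 * scale,
        width_root_px=max(2.0, 10.0 * scale),
    )
    if tree_kwargs:
        kw.update(tree_kwargs)

    out = []
    children = np.random.SeedSequence(int(seed)).spawn(n_eyes)
    for child in children:
        s_tree, s_render, s_jit = (int(x) & 0x7FFFFFFF for x in child.generate_state(3))
        tree = generate_vessel_tree(s_tree, **kw)
        gt = rasterize(tree, image_size)
        hh_eye = hh_profile
        if hh_jitter > 0:
            jrng = np.random.default_rng(s_jit)
            u = jrng.uniform(1.0 - hh_jitter, 1.0 + hh_jitter, size=2)
            hh_eye = replace(
                hh_profile,
                brightness_gain=float(np.clip(hh_profile.brightness_gain * u[0], 0.05, 2.0)),
                contrast_gain=float(np.clip(hh_profile.contrast_gain * u[1], 0.05, 2.0)),
            )
        img_ref = render_fundus(gt, ref_profile, s_render)
        img_hh = render_fundus(gt, hh_eye, s_render)
        out.append((img_ref, img_hh, gt))
    return out


# ---------------------------------------------------------------------------
# scoring and I/O
# ---------------------------------------------------------------------------

def score_segmentation(
    predicted: np.ndarray, truth: np.ndarray, fov: np.ndarray
) -> SegmentationScore:
    """True/false positive rates of a predicted mask, within the FOV only."""
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    fov = np.asarray(fov, dtype=bool)
    if predicted.shape != truth.shape or truth.shape != fov.shape:
        raise ValueError("raster geometries differ")
    t = truth & fov
    p = predicted & fov
    n_pos = t.sum()
    if n_pos == 0:
        raise ValueError("truth mask empty inside FOV: TPR undefined")
    n_neg = fov.sum() - n_pos
    tp = (p & t).sum()
    fp = (p & ~t & fov).sum()
    return SegmentationScore(
        tpr=float(tp / n_pos),
        fpr=float(fp / n_neg) if n_neg else 0.0,
    )


def _graph_to_jsonable(graph: VesselGraph) -> dict:
    return {
        "nodes": [
            {"pos": [int(n.pos[0]), int(n.pos[1])], "degree": int(n.degree), "kind": n.kind}
            for n in graph.nodes
        ],
        "edges": [
            {"a": int(e.a), "b": int(e.b), "length": float(e.length)} for e in graph.edges
        ],
    }


def write_dataset(pairs, outdir) -> Path:
    """Write renders as PNGs with ground-truth sidecars and a manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img_ref, img_hh, gt) in enumerate(pairs):
        eye = f"eye{i:03d}"
        for arm, img in (("reference", img_ref), ("handheld", img_hh)):
            path = outdir / f"{eye}_{arm}.png"
            save_image(img, path)
            rows.append({"eye_id": eye, "arm": arm, "path": path.name})
        iio.imwrite(outdir / f"{eye}_truth_mask.png", gt.vessel_mask.astype(np.uint8) * 255)
        iio.imwrite(outdir / f"{eye}_fov_mask.png", gt.fov_mask.astype(np.uint8) * 255)
        sidecar = {
            "od_centre": [float(gt.od_centre[0]), float(gt.od_centre[1])],
            "od_radius": float(gt.od_radius),
            "true_density": float(gt.true_density),
            "graph": _graph_to_jsonable(gt.centerline_graph),
        }
        (outdir / f"{eye}_truth.json").write_text(json.dumps(sidecar))
    with open(outdir / "manifest.csv", "w", newline="") as fh:
        wr = csv.DictWriter(fh, fieldnames=["eye_id", "arm", "path"])
        wr.writeheader()
        wr.writerows(rows)
    return outdir
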