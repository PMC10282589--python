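"""End-to-end study orchestration.

``run_synthetic_study`` generates paired synthetic eyes, processes both arms
of every pair through segmentation, optic-disc masking, graph extraction,
morphometrics and QC, curates the pairs, and writes the agreement report.
``run_folder`` runs the same per-image chain over an existing folder of image
pairs listed in a manifest CSV, using truth-free QC proxies.

Every run writes its resolved configuration next to its outputs so any table
regenerates from the config and seed alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import morphometrics, qc, stats
from .optic_disc import OpticDiscNotFoundError, detect_od, mask_od
from .preprocess import FundusImage, detect_fov, load_image
from .segmentation import SegmentationConfig, segment_vessels
from .skeleton import DEFAULT_SPUR_MIN_LEN, skeleton_to_graph, skeletonize
from .synthetic import (
    DEFAULT_IMAGE_SIZE,
    HANDHELD_PROFILE,
    REFERENCE_PROFILE,
    DeviceProfile,
    make_paired_dataset,
    score_segmentation,
)

logger = logging.getLogger("retvas")

__all__ = ["RunConfig", "ImageResult", "process_image", "run_synthetic_study", "run_folder"]


@dataclass
class RunConfig:
    """Resolved parameters of one study run; round-trips through JSON."""

    mode: str = "synthetic"  # synthetic | folder
    n_eyes: int = 30
    seed: int = 0
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE
    hh_jitter: float = 0.25
    ref_profile: DeviceProfile = field(default_factory=lambda: REFERENCE_PROFILE)
    hh_profile: DeviceProfile = field(default_factory=lambda: HANDHELD_PROFILE)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    spur_min_len: float = DEFAULT_SPUR_MIN_LEN
    od_margin_frac: float = 0.1
    macula_side: str = "left"
    exclude_od_from_density: bool = False
    alpha: float = stats.DEFAULT_ALPHA

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (("ref_profile", DeviceProfile), ("hh_profile", DeviceProfile),
                         ("segmentation", SegmentationConfig)):
            if key in d and isinstance(d[key], dict):
                sub = {k: tuple(v) if isinstance(v, list) else v for k, v in d[key].items()}
                d[key] = typ(**sub)
        if "image_size" in d:
            d["image_size"] = tuple(d["image_size"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ImageResult:
    """Everything computed for a single image."""

    eye_id: str
    arm: str
    mask: np.ndarray
    fov: np.ndarray
    od: object | None
    graph: object
    metrics: morphometrics.MetricSet
    flags: qc.QcFlags
    score: object | None = None  # SegmentationScore vs ground truth, if any


def process_image(
    image: FundusImage,
    config: RunConfig,
    eye_id: str = "",
    arm: str = "",
    truth=None,
) -> ImageResult:
    """Run the per-image chain: segment, mask OD, graph, metrics, QC flags."""
    fov = image.fov_mask if image.fov_mask is not None else detect_fov(image)
    image.fov_mask = fov
    mask = segment_vessels(image, config.segmentation)

    od = None
    try:
        od = detect_od(image, fov)
    except (OpticDiscNotFoundError, ValueError) as exc:
        logger.warning("%s/%s: optic disc not found (%s)", eye_id, arm, exc)
    masked = mask_od(mask, od, config.od_margin_frac) if od is not None else mask

    skel = skeletonize(masked)
    graph = skeleton_to_graph(skel, spur_min_len=config.spur_min_len)

    density_mask = masked if config.exclude_od_from_density else mask
    density = morphometrics.vessel_density(density_mask, fov)
    en, inn, n_edges = morphometrics.count_nodes(graph)
    fd = None
    if skel.any():
        fd = morphometrics.fractal_dimension(skel)
    metrics = morphometrics.MetricSet(
        density_pct=density,
        edge_lengths=graph.edge_lengths(),
        n_external=en,
        n_internal=inn,
        n_edges=n_edges,
        fd=fd,
    )

    grid = qc.build_grid(od, fov.shape, macula_side=config.macula_side)
    if grid is not None:
        quads = (
            qc.assess_quadrant(mask, grid, "superior"),
            qc.assess_quadrant(mask, grid, "inferior"),
        )
    else:
        quads = (False, False)
    truth_mask = truth.vessel_mask if truth is not None else None
    under = qc.flag_under_segmentation(mask, fov, truth=truth_mask)
    over = qc.flag_over_segmentation(mask, fov)
    flags = qc.QcFlags(
        evaluable=any(quads),
        quadrants_evaluable=quads,
        under_segmented=under,
        over_segmented=over,
    )

    score = None
    if truth is not None:
        score = score_segmentation(mask, truth.vessel_mask, fov)
    return ImageResult(eye_id, arm, mask, fov, od, graph, metrics, flags, score)


def _metric_row(res: ImageResult) -> dict:
    return {
        "eye_id": res.eye_id,
        "arm": res.arm,
        "density_pct": res.metrics.density_pct,
        "n_external": res.metrics.n_external,
        "n_internal": res.metrics.n_internal,
        "n_edges": res.metrics.n_edges,
        "fd": res.metrics.fd_value,
        "fd_r2": res.metrics.fd.fit_r2 if res.metrics.fd else float("nan"),
    }


def _qc_row(res: ImageResult) -> dict:
    return {
        "eye_id": res.eye_id,
        "arm": res.arm,
        "evaluable": res.flags.evaluable,
        "quadrant_superior": res.flags.quadrants_evaluable[0],
        "quadrant_inferior": res.flags.quadrants_evaluable[1],
        "under_segmented": res.flags.under_segmented,
        "over_segmented": res.flags.over_segmented,
        "tpr": res.score.tpr if res.score else float("nan"),
        "fpr": res.score.fpr if res.score else float("nan"),
    }


def _compare_and_write(results: list[ImageResult], outdir: Path, config: RunConfig) -> stats.AgreementReport:
    metrics_df = pd.DataFrame([_metric_row(r) for r in results])
    qc_df = pd.DataFrame([_qc_row(r) for r in results])
    metrics_df.to_csv(outdir / "metrics.csv", index=False)
    qc_df.to_csv(outdir / "qc.csv", index=False)

    by_eye: dict[str, dict[str, ImageResult]] = {}
    for r in results:
        by_eye.setdefault(r.eye_id, {})[r.arm] = r
    eyes = sorted(e for e, arms in by_eye.items() if {"reference", "handheld"} <= set(arms))
    dropped = sorted(set(by_eye) - set(eyes))
    for e in dropped:
        logger.warning("eye %s missing one arm; excluded from pairing", e)

    pair_flags = [(by_eye[e]["reference"].flags, by_eye[e]["handheld"].flags) for e in eyes]
    curation = qc.curate_pairs(pair_flags)
    (outdir / "curation.json").write_text(json.dumps(curation.counts, indent=2))

    lengths = {
        arm: {e: by_eye[e][arm].metrics.edge_lengths for e in eyes}
        for arm in ("reference", "handheld")
    }
    paired_df = metrics_df[metrics_df.eye_id.isin(eyes)]
    report = stats.compare_metrics(paired_df, curation.retained, edge_lengths=lengths)
    report.table.to_csv(outdir / "agreement.csv", index=False)
    report.plot_data.to_csv(outdir / "bland_altman_points.csv", index=False)
    summary = {
        "strata": report.strata,
        "ks": {k: {"D": v[0], "p": v[1]} for k, v in report.ks.items()},
        "curation": curation.counts,
    }
    (outdir / "agreement.json").write_text(json.dumps(summary, indent=2))
    config.save(outdir / "config.json")
    return report


def run_synthetic_study(config: RunConfig, outdir) -> Path:
    """Generate and analyse a full synthetic paired study; returns the output dir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    pairs = make_paired_dataset(
        config.n_eyes,
        ref_profile=config.ref_profile,
        hh_profile=config.hh_profile,
        seed=config.seed,
        image_size=tuple(config.image_size),
        hh_jitter=config.hh_jitter,
    )
    logger.info("generated %d pairs in %.1fs", len(pairs), time.time() - t0)

    results: list[ImageResult] = []
    for i, (img_ref, img_hh, gt) in enumerate(pairs):
        eye = f"eye{i:03d}"
        for arm, img in (("reference", img_ref), ("handheld", img_hh)):
            t1 = time.time()
            img.fov_mask = None  # detect the FOV exactly as folder mode would
            try:
                results.append(process_image(img, config, eye_id=eye, arm=arm, truth=gt))
            except Exception:
                logger.exception("eye %s arm %s failed; continuing", eye, arm)
                continue
            logger.info("processed %s/%s in %.1fs", eye, arm, time.time() - t1)

    _compare_and_write(results, outdir, config)
    return outdir


def run_folder(config: RunConfig, manifest_path, outdir) -> Path:
    """Process an existing folder of paired images listed in a manifest CSV.

    The manifest must have columns ``eye_id, arm, path`` with arm labels
    ``reference`` and ``handheld``; paths are relative to the manifest.
    QC runs in truth-free field mode.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    if manifest.empty:
        raise ValueError("manifest is empty")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    results: list[ImageResult] = []
    for row in manifest.itertuples():
        path = manifest_path.parent / row.path
        try:
            img = load_image(path, device_label=row.arm)
        except Exception:
            logger.exception("unreadable image %s; row skipped", path)
            continue
        results.append(process_image(img, config, eye_id=str(row.eye_id), arm=row.arm))

    _compare_and_write(results, outdir, config)
    return outdir
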