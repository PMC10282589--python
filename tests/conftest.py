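"""Shared fixtures: synthetic eyes at study scale and at reduced scale.

Everything is generated programmatically and cached per session; the
full-scale eye (768 px, the package's default raster) backs the tests that
probe absolute geometry (optic-disc radius, grid reach), while reduced-scale
eyes keep the property suites fast.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from retvas.pipeline import RunConfig
from retvas.segmentation import segment_vessels
from retvas.synthetic import (
    REFERENCE_PROFILE,
    generate_vessel_tree,
    make_paired_dataset,
    rasterize,
    render_fundus,
)


def make_eye(seed: int, size: int = 768, **tree_kwargs):
    """One synthetic eye: (tree, ground truth, reference render)."""
    scale = size / 768.0
    kw = dict(
        fov_radius=0.48 * size,
        fov_centre=(size / 2.0, size / 2.0),
        od_radius=40.0 * scale,
        root_len=115.0 * scale,
        width_root_px=max(2.0, 9.0 * scale),
    )
    kw.update(tree_kwargs)
    tree = generate_vessel_tree(seed, **kw)
    gt = rasterize(tree, (size, size))
    img = render_fundus(gt, REFERENCE_PROFILE, seed)
    return tree, gt, img


@pytest.fixture(scope="session")
def eye768():
    """Full-scale reference-arm eye with its segmentation mask."""
    tree, gt, img = make_eye(7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mask = segment_vessels(img)
    return {"tree": tree, "gt": gt, "img": img, "mask": mask}


@pytest.fixture(scope="session")
def eyes384():
    """Ten reduced-scale ground truths + reference renders for property suites."""
    return [make_eye(s, size=384) for s in range(10)]


@pytest.fixture(scope="session")
def paired256():
    """Five paired eyes at coarse scale for pipeline tests."""
    return make_paired_dataset(5, seed=11, image_size=(256, 256), hh_jitter=0.25)


@pytest.fixture()
def run_config():
    return RunConfig()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
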