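"""Shared fixtures: one synthetic crown pipeline context per session."""

from types import SimpleNamespace

import numpy as np
import pytest

from occlumap.generator import fit_linear_generator, mirror_augment, split_dataset
from occlumap.normalization import normalize_orientation
from occlumap.pipeline import canonical_projection
from occlumap.projection import (
    ProjectionConfig,
    project_depth,
    sample_surface,
)
from occlumap.reconstruction import FourierFeatureExtractor
from occlumap.synthetic import ToothShapeParams, generate_dataset, generate_tooth_mesh


@pytest.fixture(scope="session")
def base_params():
    return ToothShapeParams()


@pytest.fixture(scope="session")
def tooth_mesh(base_params):
    return generate_tooth_mesh(base_params, seed=3)


@pytest.fixture(scope="session")
def normalized(tooth_mesh):
    return normalize_orientation(tooth_mesh)


@pytest.fixture(scope="session")
def cfg128():
    return ProjectionConfig(resolution=128, n_sample=200_000)


@pytest.fixture(scope="session")
def cfg64():
    return ProjectionConfig(resolution=64, n_sample=100_000)


@pytest.fixture(scope="session")
def truth_projection(normalized, cfg128):
    """Canonical projection context of the session tooth (no in-plane step)."""
    cloud = sample_surface(normalized.mesh, cfg128.n_sample, seed=1)
    z_shift = cfg128.z_norm - cloud.points[:, 2].max()
    pts = cloud.points.copy()
    pts[:, 2] += z_shift
    dmap = project_depth(pts, cfg128)
    return SimpleNamespace(
        dmap=dmap,
        z_shift=z_shift,
        offset=np.asarray(dmap.provenance["xy_offset_mm"]),
        cloud=cloud,
    )


@pytest.fixture(scope="session")
def tooth_suite64(cfg64):
    """Small population study context: 26 crowns at 64x64, trained generator.

    21 crowns (mirrored to 42) train the linear generator; 5 held-out test
    crowns drive the reconstruction experiments.
    """
    meshes = generate_dataset(26, seed=11, n_radial=70, n_theta=280)
    maps = [
        canonical_projection(m, cfg64, seed=100 + i)[0]
        for i, m in enumerate(meshes)
    ]
    train, test = split_dataset(maps, 5, seed=2)
    G = fit_linear_generator(mirror_augment(train), 16)
    return SimpleNamespace(
        maps=maps,
        train=train,
        test=test,
        G=G,
        extractor=FourierFeatureExtractor(64),
        config=cfg64,
    )
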