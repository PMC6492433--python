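"""Shared fixtures: synthetic nuclei and their distance fields."""

import numpy as np
import pytest

from perilad import imaging as im
from perilad import synthetic as sy


@pytest.fixture(scope="session")
def sphere_spec():
    """Isotropic 0.1 μm voxel sphere of radius 2.5 μm (a 2C-like nucleus)."""
    return sy.NucleusSpec(semi_axes_um=(2.5, 2.5, 2.5), voxel_size_um=(0.1, 0.1, 0.1))


@pytest.fixture(scope="session")
def sphere_mask(sphere_spec):
    return sy.make_nucleus(sphere_spec).mask


@pytest.fixture(scope="session")
def sphere_field(sphere_mask, sphere_spec):
    return im.boundary_distance_field(sphere_mask, sphere_spec.voxel_size_um)


@pytest.fixture()
def sphere_img(sphere_spec):
    """Fresh (mutable) sphere nucleus per test."""
    return sy.make_nucleus(sphere_spec)


def random_blob_mask(rng, shape):
    """Random connected-ish blob mask for oracle tests (may be empty)."""
    from scipy import ndimage

    noise = rng.normal(size=shape)
    smooth = ndimage.gaussian_filter(noise, sigma=2.0)
    return smooth > np.quantile(smooth, 0.7)
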