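"""Shared fixtures: small clean scenes for exactness and geometry tests."""

import numpy as np
import pytest

import endoquant as eq


@pytest.fixture
def two_channel_imaging():
    return eq.ImagingConfig.for_roles(("protein", "reference_dye"))


def make_clean_scene(
    rho: float = 0.64,
    radius: float = 0.4,
    channels=("protein", "reference_dye"),
    cytosol: float = 0.0,
    receptor_rho: float | None = None,
    seed: int = 1,
    n_vesicles: int = 1,
):
    """One cell with vesicles of fixed rho; zero cytosol by default.

    Zero cytosol makes the membrane fields of all channels exactly
    proportional, the condition under which the ratiometric estimator is
    exact to machine precision.
    """
    cyt = {c: 0.0 for c in channels}
    cyt["protein"] = cytosol
    cfg = eq.GeometryConfig(channels=tuple(channels), cytosol_level=cyt)
    scene = eq.build_cell_geometry(cfg, seed=seed)
    rho_map = {"protein": rho, "reference_dye": 1.0}
    if receptor_rho is not None:
        rho_map["receptor"] = receptor_rho
    spec = eq.VesicleSpec(
        count=n_vesicles, rho=rho_map, radius_range=(radius, radius)
    )
    return eq.place_vesicles(scene, spec, seed=seed + 1)


def noiseless_image(scene, psf_sigma=0.15, roles=None):
    roles = roles or tuple(scene.channels)
    imaging = eq.ImagingConfig.for_roles(roles, psf_sigma=psf_sigma)
    return eq.render_image(scene, imaging, seed=0, noise=False)


@pytest.fixture
def uniform_image():
    """A flat two-channel image of value 7 (10 x 10 μm at 0.1 μm pixels)."""
    pixels = np.full((2, 100, 100), 7.0)
    return eq.MultiChannelImage(
        pixels=pixels, pixel_size=0.1,
        channel_roles={"protein": 0, "reference_dye": 1},
    )
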