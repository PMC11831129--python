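"""Shared fixtures: small grids, toy mosaics and decoder configurations."""

import numpy as np
import pytest

from driftvision.decoder import DecoderConfig
from driftvision.diffusion import DiffusionParams, make_transition_kernel
from driftvision.retina import RGCMosaic, RGCParams, orientation_overlap_tables


@pytest.fixture(scope="session")
def toy_params() -> RGCParams:
    return RGCParams(r0=20.0, dr=120.0, w=0.8, dt=0.05)


@pytest.fixture(scope="session")
def toy_mosaic(toy_params) -> RGCMosaic:
    """Three hand-placed cells on a coarse 1-arcmin grid."""
    return RGCMosaic(centers=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, -1.0]]),
                     sigmas=np.array([0.5, 0.6, 0.5]), params=toy_params)


@pytest.fixture(scope="session")
def toy_overlaps(toy_mosaic) -> np.ndarray:
    """(4, 3, 3, 3) overlap tables: 3x3 grid at 1 arcmin, 0.25-arcmin bars."""
    return orientation_overlap_tables(toy_mosaic, bar_size=0.25, grid_extent=3,
                                      grid_spacing=1.0)


@pytest.fixture(scope="session")
def toy_diffusion() -> DiffusionParams:
    return DiffusionParams(D=4.0, dt=0.05, grid_spacing=1.0, grid_extent=3,
                           kernel_radius=1)


@pytest.fixture(scope="session")
def toy_decoder_config(toy_diffusion, toy_overlaps, toy_params) -> DecoderConfig:
    return DecoderConfig(transition=make_transition_kernel(toy_diffusion),
                         overlap_tables=toy_overlaps, rgc=toy_params)
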