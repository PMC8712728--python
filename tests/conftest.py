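"""Shared fixtures: the default branching phantom and its fitted models.

Heavy objects (phantom signal, calibrated response, FOD field, tensor field,
baseline and multi-level reconstructions) are session-scoped so the suite
computes them once.
"""

import numpy as np
import pytest

from mlftrack.fod_model import (
    SphericalHarmonicBasis,
    calibrate_response_recursive,
    csd_deconvolve,
)
from mlftrack.formats_io import BinaryMask
from mlftrack.mlft import mlft_track
from mlftrack.phantom import PhantomSpec, make_branching_phantom
from mlftrack.tensor_model import fit_tensor
from mlftrack.tracking import TrackingParams, track_bundle


@pytest.fixture(scope="session")
def basis():
    return SphericalHarmonicBasis(6)


@pytest.fixture(scope="session")
def default_phantom():
    return make_branching_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def models(default_phantom, basis):
    """Calibrated response, FOD field and tensor field of the default phantom."""
    dwi, truth = default_phantom
    response = calibrate_response_recursive(dwi, truth.tracking_mask, basis)
    fods = csd_deconvolve(dwi, response, truth.tracking_mask, basis)
    tensors = fit_tensor(dwi, truth.tracking_mask)
    return {"dwi": dwi, "truth": truth, "response": response, "fods": fods,
            "tensors": tensors}


@pytest.fixture(scope="session")
def params():
    return TrackingParams(rng_seed=1)


@pytest.fixture(scope="session")
def csd_left(models, params):
    truth = models["truth"]
    return track_bundle(
        "csd",
        models["fods"],
        truth.seed_mask,
        truth.tracking_mask,
        truth.motor_mask_left,
        params,
    )


@pytest.fixture(scope="session")
def mlft_left(models, params):
    truth = models["truth"]
    return mlft_track(
        models["fods"],
        truth.seed_mask,
        truth.motor_mask_left,
        truth.tracking_mask,
        params,
    )


@pytest.fixture(scope="session")
def branch70_left(models):
    truth = models["truth"]
    return next(
        b for b in truth.branches if b.hemisphere == "left" and b.angle == 70.0
    )


@pytest.fixture(scope="session")
def branch70_target(models, branch70_left):
    """Small mask around the lateral 70-degree branch endpoint."""
    truth = models["truth"]
    grid = truth.tracking_mask.grid
    values = np.zeros(grid.dims, dtype=np.uint8)
    x, y, z = branch70_left.endpoint_voxel
    values[
        max(x - 1, 0) : x + 2, max(y - 1, 0) : y + 2, max(z - 1, 0) : z + 2
    ] = 1
    return BinaryMask(values=values, grid=grid)
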