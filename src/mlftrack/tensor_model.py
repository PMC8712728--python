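"""Diffusion tensor fitting, fractional anisotropy and principal directions.

Per voxel the single-tensor model ``ln(S_i/S0) = -b_i g_i^T D g_i`` is solved
by ordinary least squares on the log signal (the deterministic baseline
estimator). S0 is the mean of all b0 volumes; signals at or below zero are
clipped to a small positive floor before the log. Negative eigenvalues, which
noise can produce, are kept for FA (the standard formula handles them) while
the principal direction uses the algebraically largest eigenvalue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .formats_io import BinaryMask, DWIDataset, ValidationError, VolumeGrid

logger = logging.getLogger(__name__)

#: column order of the unique tensor components
TENSOR_COMPONENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


@dataclass(frozen=True)
class TensorField:
    """Per-voxel tensor components (x,y,z,6), FA map and principal directions."""

    components: np.ndarray  # (X, Y, Z, 6) mm^2/s, order TENSOR_COMPONENTS
    fa: np.ndarray  # (X, Y, Z) in [0, 1]
    principal_dir: np.ndarray  # (X, Y, Z, 3) unit vectors (0 outside mask)
    grid: VolumeGrid


def fractional_anisotropy(eigenvalues: np.ndarray) -> np.ndarray:
    """FA of tensor eigenvalues: ``sqrt(3/2) ||lam - mean|| / ||lam||``; 0 for all-zero.

    Total function: real (possibly negative) eigenvalues are accepted and the
    result is clamped into [0, 1].
    """
    lam = np.asarray(eigenvalues, dtype=float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt((np.square(lam - mean)).sum(axis=-1))
    den = np.sqrt(np.square(lam).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den == 0, 0.0, fa)
    return np.clip(fa, 0.0, 1.0)


def tensor_design_matrix(gradients_bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows of ``-b * [gx^2, gy^2, gz^2, 2gxgy, 2gxgz, 2gygz]``."""
    g = np.asarray(bvecs, dtype=float)
    b = np.asarray(gradients_bvals, dtype=float)[:, None]
    return -b * np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )


def components_to_matrices(components: np.ndarray) -> np.ndarray:
    """(..., 6) unique components to (..., 3, 3) symmetric matrices."""
    c = np.asarray(components, dtype=float)
    out = np.empty(c.shape[:-1] + (3, 3))
    out[..., 0, 0] = c[..., 0]
    out[..., 1, 1] = c[..., 1]
    out[..., 2, 2] = c[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = c[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = c[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = c[..., 5]
    return out


def eigen_from_components(components: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (ascending) and eigenvectors of symmetric (..., 6) tensors."""
    return np.linalg.eigh(components_to_matrices(components))


def fit_tensor(dwi: DWIDataset, mask: BinaryMask) -> TensorField:
    """Log-linear OLS tensor fit inside ``mask``; all fields zero outside."""
    gradients = dwi.gradients
    if gradients.n_dwi < 6:
        raise ValidationError("tensor fit needs at least 6 DWI volumes")
    dwi_sel = gradients.dwi_mask
    design = tensor_design_matrix(gradients.bvals[dwi_sel], gradients.bvecs[dwi_sel])
    if np.linalg.matrix_rank(design) < 6:
        raise ValidationError("fewer than 6 non-collinear DWI directions")
    pinv = np.linalg.pinv(design)

    vox = np.argwhere(mask.values > 0)
    dims = dwi.grid.dims
    components = np.zeros(dims + (6,))
    fa = np.zeros(dims)
    principal = np.zeros(dims + (3,))
    if len(vox):
        sig = dwi.signal[vox[:, 0], vox[:, 1], vox[:, 2], :]  # (n_vox, n_vol)
        s0 = sig[:, gradients.b0_mask].mean(axis=1)
        floor = 1e-8 * max(float(s0.max()), 1.0)
        s0 = np.maximum(s0, floor)
        y = np.log(np.maximum(sig[:, dwi_sel], floor) / s0[:, None])
        comp = y @ pinv.T  # (n_vox, 6)
        evals, evecs = eigen_from_components(comp)
        fa_vals = fractional_anisotropy(evals)
        pdir = evecs[:, :, 2]  # eigenvector of the largest eigenvalue
        components[vox[:, 0], vox[:, 1], vox[:, 2]] = comp
        fa[vox[:, 0], vox[:, 1], vox[:, 2]] = fa_vals
        principal[vox[:, 0], vox[:, 1], vox[:, 2]] = pdir
    logger.info("tensor fit: %d voxels", len(vox))
    return TensorField(
        components=components, fa=fa, principal_dir=principal, grid=dwi.grid
    )
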