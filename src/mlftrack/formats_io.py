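"""Domain types and neuroimaging file I/O.

Volumes and masks are NIfTI-1 (via nibabel), gradient tables are FSL-style
bval/bvec text files, and streamlines are MRtrix ``.tck`` or TrackVis ``.trk``
(via :mod:`nibabel.streamlines`). All streamline coordinates are world
millimetres (scanner/RAS space); voxel indices appear only at interpolation and
visitation time.

Voxel convention: 0-based indices, voxel centre at the integer index, so a
world point belongs to voxel ``floor(index + 0.5)`` per axis. No resampling or
registration is performed anywhere — all inputs must share one grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import nibabel as nib
import numpy as np
from nibabel.streamlines import Field as _TrkField
from nibabel.streamlines import TckFile, TrkFile
from nibabel.streamlines import Tractogram as _NibTractogram

logger = logging.getLogger(__name__)

#: b-values at or below this (s/mm^2) are treated as unweighted b0 volumes.
B0_THRESHOLD = 50.0


class FormatError(ValueError):
    """A file does not conform to its expected on-disk format."""


class ValidationError(ValueError):
    """Inputs are well-formed but violate a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GradientTable:
    """Diffusion acquisition scheme: b-values (s/mm^2) and unit gradient directions."""

    bvals: np.ndarray
    bvecs: np.ndarray
    b0_threshold: float = B0_THRESHOLD

    def __post_init__(self):
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise FormatError(f"bvecs must be (n, 3), got {bvecs.shape}")
        if len(bvals) != len(bvecs):
            raise FormatError(
                f"count mismatch: {len(bvals)} b-values vs {len(bvecs)} b-vectors"
            )
        if np.any(bvals < 0):
            raise ValidationError("negative b-value in gradient table")
        dwi = bvals > self.b0_threshold
        if not np.any(~dwi):
            raise ValidationError(
                f"gradient table has no b0 entry (b <= {self.b0_threshold})"
            )
        norms = np.linalg.norm(bvecs, axis=1)
        if np.any(norms[dwi] == 0):
            raise ValidationError("zero gradient vector with b > b0 threshold")
        off = np.abs(norms[dwi] - 1.0) > 1e-6
        if np.any(off):
            logger.warning(
                "renormalizing %d non-unit gradient vector(s)", int(off.sum())
            )
            bvecs = bvecs.copy()
            bvecs[dwi] = bvecs[dwi] / norms[dwi, None]
        bvals = bvals.copy()
        bvals.setflags(write=False)
        bvecs.setflags(write=False)
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= self.b0_threshold

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > self.b0_threshold

    @property
    def n_b0(self) -> int:
        return int(self.b0_mask.sum())

    @property
    def n_dwi(self) -> int:
        return int(self.dwi_mask.sum())


@dataclass(frozen=True)
class VolumeGrid:
    """Sampling grid: voxel dimensions, voxel size (mm) and voxel-to-world affine."""

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self):
        dims = tuple(int(d) for d in self.dims)
        vs = tuple(float(v) for v in self.voxel_size)
        affine = np.asarray(self.affine, dtype=float)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValidationError(f"dims must be 3 positive integers, got {dims}")
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValidationError(f"voxel_size must be 3 positive lengths, got {vs}")
        if affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValidationError("affine is singular")
        affine = affine.copy()
        affine.setflags(write=False)
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "voxel_size", vs)
        object.__setattr__(self, "affine", affine)

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    def voxel_to_world(self, index: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices (..., 3) to world mm."""
        index = np.asarray(index, dtype=float)
        return index @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points (..., 3) to continuous voxel coordinates."""
        points = np.asarray(points, dtype=float)
        inv = self.inverse_affine
        return points @ inv[:3, :3].T + inv[:3, 3]

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Containing voxel of each world point: floor(index + 0.5) per axis."""
        return np.floor(self.world_to_voxel(points) + 0.5).astype(int)

    def same_grid(self, other: "VolumeGrid", affine_tol: float = 1e-4) -> bool:
        return self.dims == other.dims and np.allclose(
            self.affine, other.affine, atol=affine_tol
        )


@dataclass(frozen=True)
class DWIDataset:
    """4-D diffusion-weighted signal with its grid and gradient table."""

    signal: np.ndarray
    grid: VolumeGrid
    gradients: GradientTable

    def __post_init__(self):
        signal = np.asarray(self.signal, dtype=float)
        if signal.ndim != 4:
            raise FormatError(f"DWI signal must be 4-D, got {signal.ndim}-D")
        if signal.shape[:3] != self.grid.dims:
            raise ValidationError(
                f"signal dims {signal.shape[:3]} do not match grid {self.grid.dims}"
            )
        if signal.shape[3] != len(self.gradients):
            raise ValidationError(
                f"signal has {signal.shape[3]} volumes but gradient table has "
                f"{len(self.gradients)} entries"
            )
        if not np.all(np.isfinite(signal)):
            raise ValidationError("DWI signal contains non-finite values")
        if np.any(signal < 0):
            raise ValidationError("DWI signal contains negative values")
        object.__setattr__(self, "signal", signal)


@dataclass(frozen=True)
class BinaryMask:
    """3-D {0,1} mask on a grid."""

    values: np.ndarray
    grid: VolumeGrid

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.shape != self.grid.dims:
            raise ValidationError(
                f"mask dims {values.shape} do not match grid {self.grid.dims}"
            )
        uniq = np.unique(values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValidationError("mask values must be 0 or 1")
        values = values.astype(np.uint8)
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def contains_points(self, points: np.ndarray) -> np.ndarray:
        """Boolean per world point: does its containing voxel lie in the mask?"""
        idx = self.grid.world_to_index(np.atleast_2d(points))
        inside = np.all((idx >= 0) & (idx < np.array(self.grid.dims)), axis=1)
        out = np.zeros(len(idx), dtype=bool)
        if inside.any():
            ii = idx[inside]
            out[inside] = self.values[ii[:, 0], ii[:, 1], ii[:, 2]] > 0
        return out


@dataclass(frozen=True)
class Streamline:
    """Ordered world-mm polyline of a reconstructed pathway."""

    points: np.ndarray

    def __post_init__(self):
        points = np.asarray(self.points, dtype=float)
        if points.ndim != 2 or points.shape[1] != 3:
            raise ValidationError("streamline points must be (n, 3)")
        if len(points) < 2:
            raise ValidationError("streamline needs at least 2 points")
        if not np.all(np.isfinite(points)):
            raise ValidationError("streamline contains non-finite coordinates")
        points = points.copy()
        points.setflags(write=False)
        object.__setattr__(self, "points", points)

    def __len__(self) -> int:
        return len(self.points)

    def step_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)


@dataclass(frozen=True)
class Tractogram:
    """A list of streamlines referencing one grid. May be empty."""

    streamlines: tuple[Streamline, ...]
    grid: VolumeGrid

    def __init__(self, streamlines: Iterable[Streamline], grid: VolumeGrid):
        sls = tuple(
            s if isinstance(s, Streamline) else Streamline(np.asarray(s))
            for s in streamlines
        )
        object.__setattr__(self, "streamlines", sls)
        object.__setattr__(self, "grid", grid)

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _load_numeric_rows(path: str | Path) -> np.ndarray:
    try:
        arr = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"non-numeric content in {path}: {exc}") from exc
    return arr


def read_gradient_table(bval_path: str | Path, bvec_path: str | Path) -> GradientTable:
    """Read an FSL-dialect bval/bvec pair into a validated :class:`GradientTable`.

    The bvec file may hold three rows (FSL convention) or three columns; the
    orientation is disambiguated by the b-value count. Non-unit vectors with
    b > b0 threshold are renormalized with a logged warning.
    """
    bvals = _load_numeric_rows(bval_path).ravel()
    bvecs = _load_numeric_rows(bvec_path)
    if bvecs.shape[0] == 3 and bvecs.shape[1] == len(bvals):
        bvecs = bvecs.T
    elif bvecs.shape[1] == 3 and bvecs.shape[0] == len(bvals):
        pass
    else:
        raise FormatError(
            f"bvec shape {bvecs.shape} incompatible with {len(bvals)} b-values"
        )
    return GradientTable(bvals=bvals, bvecs=bvecs)


def write_gradient_table(
    gradients: GradientTable, bval_path: str | Path, bvec_path: str | Path
) -> None:
    """Write FSL-style bval (one row) and bvec (three rows) text files."""
    np.savetxt(bval_path, gradients.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, gradients.bvecs.T, fmt="%.10g")


def _grid_from_nifti(img: nib.Nifti1Image) -> VolumeGrid:
    zooms = img.header.get_zooms()[:3]
    return VolumeGrid(
        dims=tuple(int(d) for d in img.shape[:3]),
        voxel_size=tuple(float(z) for z in zooms),
        affine=np.asarray(img.affine, dtype=float),
    )


def read_dwi(nifti_path: str | Path, gradients: GradientTable) -> DWIDataset:
    """Read a 4-D NIfTI and bind it to its gradient table."""
    img = nib.load(str(nifti_path))
    if img.ndim != 4:
        raise FormatError(f"expected 4-D DWI NIfTI, got {img.ndim}-D: {nifti_path}")
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.shape[3] != len(gradients):
        raise ValidationError(
            f"DWI has {data.shape[3]} volumes but gradient table has "
            f"{len(gradients)} entries"
        )
    return DWIDataset(signal=data, grid=_grid_from_nifti(img), gradients=gradients)


def write_dwi(dataset: DWIDataset, nifti_path: str | Path) -> None:
    img = nib.Nifti1Image(dataset.signal.astype(np.float64), dataset.grid.affine)
    img.header.set_zooms(dataset.grid.voxel_size + (1.0,))
    nib.save(img, str(nifti_path))


def read_mask(nifti_path: str | Path, grid: VolumeGrid) -> BinaryMask:
    """Read a 3-D NIfTI as a binary mask on ``grid`` (values > 0.5 map to 1).

    The file must already live on the supplied grid (equal dims, affine within
    1e-4); there is deliberately no silent resampling.
    """
    img = nib.load(str(nifti_path))
    if img.ndim != 3:
        raise FormatError(f"expected 3-D mask NIfTI, got {img.ndim}-D: {nifti_path}")
    file_grid = _grid_from_nifti(img)
    if not file_grid.same_grid(grid):
        raise ValidationError(
            f"mask grid mismatch for {nifti_path}: dims {file_grid.dims} / affine "
            "differ from the reference grid (no resampling is performed)"
        )
    data = np.asarray(img.dataobj, dtype=float)
    return BinaryMask(values=(data > 0.5).astype(np.uint8), grid=grid)


def write_mask(mask: BinaryMask, nifti_path: str | Path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), mask.grid.affine)
    img.header.set_zooms(mask.grid.voxel_size)
    nib.save(img, str(nifti_path))


def write_tractogram(
    tractogram: Tractogram, path: str | Path, format: str | None = None
) -> None:
    """Write a tractogram as MRtrix ``.tck`` or TrackVis ``.trk`` (world mm)."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format not in ("tck", "trk"):
        raise ValueError(f"unknown tractogram format: {format!r} (use 'tck' or 'trk')")
    grid = tractogram.grid
    nib_t = _NibTractogram(
        [s.points for s in tractogram.streamlines], affine_to_rasmm=np.eye(4)
    )
    if format == "tck":
        TckFile(nib_t).save(str(path))
    else:
        header = {
            _TrkField.VOXEL_TO_RASMM: grid.affine.copy(),
            _TrkField.VOXEL_SIZES: grid.voxel_size,
            _TrkField.DIMENSIONS: grid.dims,
        }
        TrkFile(nib_t, header).save(str(path))


def read_tractogram(path: str | Path, grid: VolumeGrid) -> Tractogram:
    """Read a ``.tck``/``.trk`` file into world-mm streamlines on ``grid``."""
    tf = nib.streamlines.load(str(path))
    return Tractogram(
        [Streamline(np.asarray(s, dtype=float)) for s in tf.tractogram.streamlines],
        grid=grid,
    )
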