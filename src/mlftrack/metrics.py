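"""Quantitative bundle assessment: visitation masks, coverage, radial extent.

Coverage answers "how much of a reference reconstruction (conventionally the
tensor-based one) is also visited by a candidate reconstruction": the
percentage of reference visitation-mask voxels contained in the candidate's
visitation mask, so 90% coverage means 90% of the reference bundle volume is
included in the candidate bundle.

Radial extent measures how much of the motor-cortex mask a bundle fans into:
the motor mask and the bundle-overlap are projected onto the coronal plane,
every projected motor pixel receives a polar angle about an arc centre, the
motor projection's angular span is rescaled to a 90 degree arc, and the extent
is the portion of that arc covered by the bundle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .formats_io import BinaryMask, Tractogram, ValidationError, VolumeGrid

logger = logging.getLogger(__name__)

_BIN_WIDTH_DEG = 1.0


@dataclass(frozen=True)
class CoverageResult:
    percent: float
    reference_voxels: int
    intersect_voxels: int


@dataclass(frozen=True)
class RadialExtentResult:
    degrees: float
    covered_bins: tuple[tuple[float, float], ...]  # merged covered arc intervals


@dataclass(frozen=True)
class OutlierResult:
    indices: tuple[int, ...]
    mean: float
    sd: float
    threshold: float


def visitation_mask(tractogram: Tractogram, grid: VolumeGrid) -> BinaryMask:
    """Voxels visited by at least one streamline point.

    Points map to their containing voxel (centre convention); points falling
    outside the grid are ignored. With tracking steps at or below half a voxel
    a straight segment cannot skip a voxel, so point (rather than segment)
    rasterization is exact for the trackers in this package.
    """
    values = np.zeros(grid.dims, dtype=np.uint8)
    dims = np.array(grid.dims)
    for s in tractogram:
        idx = grid.world_to_index(s.points)
        keep = np.all((idx >= 0) & (idx < dims), axis=1)
        idx = idx[keep]
        values[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
    return BinaryMask(values=values, grid=grid)


def coverage(reference: BinaryMask, candidate: BinaryMask) -> CoverageResult:
    """Percentage of the reference mask's voxels included in the candidate mask."""
    if not reference.grid.same_grid(candidate.grid):
        raise ValidationError("coverage masks must share one grid")
    n_ref = reference.n_voxels
    if n_ref == 0:
        raise ValidationError("coverage is undefined for an empty reference mask")
    n_int = int((reference.values & candidate.values).sum())
    return CoverageResult(
        percent=100.0 * n_int / n_ref, reference_voxels=n_ref, intersect_voxels=n_int
    )


def _anterior_posterior_axis(grid: VolumeGrid) -> int:
    """Grid axis most aligned with the world anterior-posterior (y) direction."""
    return int(np.argmax(np.abs(grid.affine[1, :3])))


def radial_extent(
    bundle_mask: BinaryMask,
    motor_mask: BinaryMask,
    hemisphere: str = "left",
    ap_axis: int | None = None,
) -> RadialExtentResult:
    """Arc coverage of the coronal motor-mask projection by a bundle.

    The anterior-posterior axis (derived from the affine unless given) is
    collapsed; remaining world coordinates are (lateral, superior). Polar
    angles are measured about the midpoint of the inferior edge of the
    projected motor mask's bounding box. The motor projection's angular span
    is rescaled to [0, 90] degrees and partitioned into 1 degree bins; the
    extent is 90 degrees times the fraction of motor-occupied bins that also
    contain a projected bundle-overlap pixel, so full overlap gives exactly
    90 degrees regardless of how sparsely the mask populates the bins.
    """
    if hemisphere not in ("left", "right"):
        raise ValidationError("hemisphere must be 'left' or 'right'")
    grid = motor_mask.grid
    if not bundle_mask.grid.same_grid(grid):
        raise ValidationError("bundle and motor masks must share one grid")
    if motor_mask.n_voxels == 0:
        raise ValidationError("empty motor mask")
    if ap_axis is None:
        ap_axis = _anterior_posterior_axis(grid)
    keep_axes = [a for a in range(3) if a != ap_axis]

    def project(mask_values: np.ndarray) -> np.ndarray:
        vox = np.argwhere(mask_values > 0)
        if len(vox) == 0:
            return np.zeros((0, 2))
        world = grid.voxel_to_world(vox.astype(float))
        pix = np.unique(np.round(world[:, keep_axes], 6), axis=0)
        return pix

    motor_pix = project(motor_mask.values)
    overlap_pix = project(bundle_mask.values & motor_mask.values)

    # lateral, superior world coordinates
    lat, sup = motor_pix[:, 0], motor_pix[:, 1]
    cx = 0.5 * (lat.min() + lat.max())
    cz = sup.min()

    def angles(pix: np.ndarray) -> np.ndarray:
        if len(pix) == 0:
            return np.zeros(0)
        a = np.degrees(np.arctan2(pix[:, 0] - cx, pix[:, 1] - cz))
        return -a if hemisphere == "left" else a  # medial -> lateral sweep

    motor_theta = angles(motor_pix)
    lo, hi = motor_theta.min(), motor_theta.max()
    if hi - lo < 1e-9:
        deg = 90.0 if len(overlap_pix) else 0.0
        bins = ((0.0, 90.0),) if deg else ()
        return RadialExtentResult(degrees=deg, covered_bins=bins)

    def to_bins(theta: np.ndarray) -> np.ndarray:
        scaled = 90.0 * (theta - lo) / (hi - lo)
        return np.unique(
            np.clip(np.floor(scaled / _BIN_WIDTH_DEG).astype(int), 0, 89)
        )

    occupied = to_bins(motor_theta)
    covered = np.intersect1d(to_bins(angles(overlap_pix)), occupied)
    width = 90.0 / len(occupied)
    degrees = width * len(covered)

    # merge runs of consecutive occupied bins that are covered into intervals
    intervals: list[tuple[float, float]] = []
    pos_of = {int(b): i for i, b in enumerate(occupied)}
    run_start = None
    prev_pos = None
    for b in covered:
        pos = pos_of[int(b)]
        if run_start is None or pos != prev_pos + 1:
            if run_start is not None:
                intervals.append((run_start * width, (prev_pos + 1) * width))
            run_start = pos
        prev_pos = pos
    if run_start is not None:
        intervals.append((run_start * width, (prev_pos + 1) * width))
    return RadialExtentResult(degrees=float(degrees), covered_bins=tuple(intervals))


def extent_difference_outliers(differences) -> OutlierResult:
    """Two-sigma outliers of a difference distribution (sample SD, strict rule)."""
    d = np.asarray(differences, dtype=float)
    if d.size < 3:
        raise ValidationError("outlier detection needs at least 3 values")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    threshold = 2.0 * sd
    idx = tuple(int(i) for i in np.flatnonzero(np.abs(d - mean) > threshold))
    return OutlierResult(indices=idx, mean=mean, sd=sd, threshold=threshold)
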