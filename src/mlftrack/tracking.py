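"""Deterministic streamline propagation for the DTI and CSD models.

Fixed-step Euler integration at half-voxel step size. Model fields (tensor
components, FOD SH coefficients) are interpolated trilinearly at the current
point, and the model quantity (principal eigenvector, FOD peaks) is recomputed
at the interpolated point. Propagation from plain seeds is bidirectional along
the +/- initial direction with the two half-tracks joined; branch seeds (used
by multi-level tracking) propagate unidirectionally.

Termination: leaving the tracking mask, FA below threshold (DTI), no FOD peak
above the amplitude threshold (CSD), angular deviation above threshold, or the
maximum length guard.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum

import numpy as np

from ._sphere import fibonacci_hemisphere
from .fod_model import FODField, PeakSet, SphericalHarmonicBasis, extract_peaks
from .formats_io import (
    BinaryMask,
    Streamline,
    Tractogram,
    ValidationError,
    VolumeGrid,
)
from .tensor_model import TensorField, eigen_from_components, fractional_anisotropy

logger = logging.getLogger(__name__)


class TerminationReason(Enum):
    LEFT_MASK = "left_mask"
    LOW_FA = "low_fa"
    NO_PEAK = "no_peak"
    ANGLE_EXCEEDED = "angle_exceeded"
    MAX_LENGTH = "max_length"
    REACHED_TARGET = "reached_target"


@dataclass(frozen=True)
class TrackingParams:
    """Propagation thresholds; defaults follow the clinical protocol emulated here.

    ``step_size`` of ``None`` resolves to half the smallest voxel dimension.
    """

    step_size: float | None = None  # mm
    angle_threshold: float = 45.0  # degrees
    fa_threshold: float = 0.1  # DTI only
    peak_threshold: float = 0.08  # FOD amplitude, CSD/MLFT only
    seeds_per_voxel: int = 5
    max_levels: int = 2  # MLFT only
    max_length: float = 250.0  # mm
    rng_seed: int = 0

    def __post_init__(self):
        if self.step_size is not None and self.step_size <= 0:
            raise ValidationError("step_size must be positive")
        if not (0.0 < self.angle_threshold <= 90.0):
            raise ValidationError("angle_threshold must lie in (0, 90]")
        if self.seeds_per_voxel < 1:
            raise ValidationError("seeds_per_voxel must be >= 1")
        if self.max_levels < 1:
            raise ValidationError("max_levels must be >= 1")

    def resolve_step(self, grid: VolumeGrid) -> float:
        return (
            self.step_size
            if self.step_size is not None
            else 0.5 * min(grid.voxel_size)
        )


class TrilinearField:
    """Trilinear interpolation of a (X, Y, Z, C) field in world coordinates.

    Values outside the volume count as zero, so fields fade smoothly at the
    mask boundary instead of jumping.
    """

    def __init__(self, values: np.ndarray, grid: VolumeGrid):
        self.values = np.asarray(values, dtype=float)
        self.grid = grid

    def __call__(self, point: np.ndarray) -> np.ndarray:
        v = self.grid.world_to_voxel(point)
        base = np.floor(v).astype(int)
        frac = v - base
        out = np.zeros(self.values.shape[3])
        dims = self.values.shape[:3]
        for corner in range(8):
            off = (corner & 1, (corner >> 1) & 1, (corner >> 2) & 1)
            idx = base + off
            if np.any(idx < 0) or np.any(idx >= dims):
                continue
            w = 1.0
            for a in range(3):
                w *= frac[a] if off[a] else 1.0 - frac[a]
            if w > 0:
                out += w * self.values[idx[0], idx[1], idx[2]]
        return out


@dataclass
class PropagationResult:
    """One propagated pathway with its per-direction termination reasons."""

    streamline: Streamline | None
    reasons: tuple[TerminationReason, ...]


def sample_seeds(
    seed_mask: BinaryMask, seeds_per_voxel: int, rng_seed: int
) -> np.ndarray:
    """Uniform in-plane seed points inside each mask voxel of a single-slice mask.

    The through-plane coordinate of every seed is fixed to the voxel-centre
    plane, so all seeds lie on one slice. The through-plane axis is the
    constant-index axis most aligned with the world superior direction.
    Deterministic given ``rng_seed``.
    """
    vox = np.argwhere(seed_mask.values > 0)
    if len(vox) == 0:
        raise ValidationError("empty seed mask")
    constant = [a for a in range(3) if len(np.unique(vox[:, a])) == 1]
    candidates = constant if constant else [0, 1, 2]
    # of the single-index axes, take the one most aligned with world superior
    affine = seed_mask.grid.affine
    through = max(candidates, key=lambda a: abs(affine[2, a]))
    rng = np.random.default_rng(rng_seed)
    seeds = []
    for v in vox:  # argwhere order is lexicographic, hence deterministic
        offsets = rng.uniform(-0.5, 0.5, size=(seeds_per_voxel, 3))
        offsets[:, through] = 0.0
        seeds.append(v[None, :] + offsets)
    return seed_mask.grid.voxel_to_world(np.concatenate(seeds, axis=0))


def _angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.degrees(np.arccos(np.clip(np.dot(a, b), -1.0, 1.0))))


def _join_halves(
    back: list[np.ndarray], seed: np.ndarray, forward: list[np.ndarray]
) -> np.ndarray | None:
    pts = back[::-1] + [seed] + forward
    if len(pts) < 2:
        return None
    return np.asarray(pts)


class _DtiModel:
    """Direction provider for tensor-based tracking."""

    def __init__(self, tensors: TensorField, params: TrackingParams):
        self.interp = TrilinearField(tensors.components, tensors.grid)
        self.fa_threshold = params.fa_threshold

    def directions(self, point: np.ndarray) -> tuple[PeakSet, TerminationReason]:
        comp = self.interp(point)
        evals, evecs = eigen_from_components(comp)
        fa = float(fractional_anisotropy(evals))
        if fa < self.fa_threshold:
            return PeakSet.empty(), TerminationReason.LOW_FA
        d = evecs[:, 2]
        return (
            PeakSet(directions=d[None, :], amplitudes=np.array([fa])),
            TerminationReason.LOW_FA,
        )


class _CsdModel:
    """Direction provider for FOD-peak tracking."""

    def __init__(self, fods: FODField, params: TrackingParams):
        self.interp = TrilinearField(fods.coeffs, fods.grid)
        self.basis = fods.basis
        self.peak_threshold = params.peak_threshold
        dirs = fibonacci_hemisphere(724)
        self._search = (dirs, self.basis.matrix(dirs))

    def peaks_at(self, point: np.ndarray) -> PeakSet:
        return extract_peaks(
            self.interp(point),
            self.basis,
            amplitude_threshold=self.peak_threshold,
            search_matrix=self._search,
        )

    def directions(self, point: np.ndarray) -> tuple[PeakSet, TerminationReason]:
        return self.peaks_at(point), TerminationReason.NO_PEAK


def _propagate_half(
    start: np.ndarray,
    direction: np.ndarray,
    model,
    tracking_mask: BinaryMask,
    step: float,
    angle_threshold: float,
    max_length: float,
) -> tuple[list[np.ndarray], list[np.ndarray], TerminationReason]:
    """March from ``start`` along ``direction``; returns (points, step_dirs, reason).

    ``points`` excludes the start point. At each step the model's candidate
    axes at the current point are compared (with their antipodes) against the
    previous step direction; the least-deviating one is followed.
    """
    points: list[np.ndarray] = []
    dirs: list[np.ndarray] = []
    pos = np.asarray(start, dtype=float)
    prev = np.asarray(direction, dtype=float)
    length = 0.0
    first = True
    while True:
        peaks, empty_reason = model.directions(pos)
        if len(peaks) == 0:
            return points, dirs, empty_reason
        axes = peaks.directions
        dots = axes @ prev
        best = int(np.argmax(np.abs(dots)))
        d = axes[best] if dots[best] >= 0 else -axes[best]
        if first:
            # the very first step follows the supplied direction's own axis
            d = prev / np.linalg.norm(prev)
            first = False
        dev = _angle_deg(d, prev)
        if dev > angle_threshold:
            return points, dirs, TerminationReason.ANGLE_EXCEEDED
        if length + step > max_length:
            return points, dirs, TerminationReason.MAX_LENGTH
        nxt = pos + step * d
        if not tracking_mask.contains_points(nxt[None, :])[0]:
            return points, dirs, TerminationReason.LEFT_MASK
        points.append(nxt)
        dirs.append(d)
        pos, prev = nxt, d
        length += step


def propagate_dti(
    seed: np.ndarray,
    tensors: TensorField,
    tracking_mask: BinaryMask,
    params: TrackingParams,
) -> PropagationResult:
    """Bidirectional tensor-line propagation from one seed point."""
    seed = np.asarray(seed, dtype=float)
    if not tracking_mask.contains_points(seed[None, :])[0]:
        raise ValidationError("seed lies outside the tracking mask")
    model = _DtiModel(tensors, params)
    step = params.resolve_step(tensors.grid)
    init, reason = model.directions(seed)
    if len(init) == 0:
        return PropagationResult(streamline=None, reasons=(reason, reason))
    d0 = init.directions[0]
    fwd, _, r_fwd = _propagate_half(
        seed, d0, model, tracking_mask, step, params.angle_threshold, params.max_length
    )
    bwd, _, r_bwd = _propagate_half(
        seed, -d0, model, tracking_mask, step, params.angle_threshold, params.max_length
    )
    pts = _join_halves(bwd, seed, fwd)
    if pts is None:
        return PropagationResult(streamline=None, reasons=(r_bwd, r_fwd))
    return PropagationResult(streamline=Streamline(pts), reasons=(r_bwd, r_fwd))


def propagate_csd(
    seed: np.ndarray,
    initial_dir: np.ndarray | None,
    fods: FODField,
    tracking_mask: BinaryMask,
    params: TrackingParams,
    model: "_CsdModel | None" = None,
) -> PropagationResult:
    """FOD-peak propagation: bidirectional from the largest peak at the seed,
    or unidirectional along ``initial_dir`` when given (branch seeds)."""
    seed = np.asarray(seed, dtype=float)
    if not tracking_mask.contains_points(seed[None, :])[0]:
        raise ValidationError("seed lies outside the tracking mask")
    if model is None:
        model = _CsdModel(fods, params)
    step = params.resolve_step(fods.grid)
    if initial_dir is None:
        peaks = model.peaks_at(seed)
        if len(peaks) == 0:
            return PropagationResult(
                streamline=None,
                reasons=(TerminationReason.NO_PEAK, TerminationReason.NO_PEAK),
            )
        d0 = peaks.directions[0]
        fwd, _, r_fwd = _propagate_half(
            seed, d0, model, tracking_mask, step, params.angle_threshold,
            params.max_length,
        )
        bwd, _, r_bwd = _propagate_half(
            seed, -d0, model, tracking_mask, step, params.angle_threshold,
            params.max_length,
        )
        pts = _join_halves(bwd, seed, fwd)
        if pts is None:
            return PropagationResult(streamline=None, reasons=(r_bwd, r_fwd))
        return PropagationResult(streamline=Streamline(pts), reasons=(r_bwd, r_fwd))
    fwd, _, r_fwd = _propagate_half(
        seed, np.asarray(initial_dir, dtype=float), model, tracking_mask, step,
        params.angle_threshold, params.max_length,
    )
    if not fwd:
        return PropagationResult(streamline=None, reasons=(r_fwd,))
    pts = np.vstack([seed[None, :], np.asarray(fwd)])
    return PropagationResult(streamline=Streamline(pts), reasons=(r_fwd,))


@dataclass
class BundleResult:
    """Tractogram plus propagation diagnostics."""

    tractogram: Tractogram
    n_seeds: int
    n_propagated: int
    termination_histogram: dict[str, int]


def streamline_touches(streamline: Streamline, mask: BinaryMask) -> bool:
    return bool(mask.contains_points(streamline.points).any())


def track_bundle(
    algorithm: str,
    model_field,
    seed_mask: BinaryMask,
    tracking_mask: BinaryMask,
    roi_mask: BinaryMask | None,
    params: TrackingParams,
) -> BundleResult:
    """Propagate from all sampled seeds and keep streamlines touching the ROI.

    ``algorithm`` is ``"dti"`` (``model_field`` a :class:`TensorField`) or
    ``"csd"`` (a :class:`FODField`). ROI filtering keeps streamlines with at
    least one point inside ``roi_mask`` (any-point semantics); ``None``
    disables filtering. Deterministic given ``params.rng_seed``.
    """
    if algorithm not in ("dti", "csd"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    grid = tracking_mask.grid
    for m in (seed_mask, roi_mask):
        if m is not None and not m.grid.same_grid(grid):
            raise ValidationError("all masks must share one grid")
    seeds = sample_seeds(seed_mask, params.seeds_per_voxel, params.rng_seed)
    model = (
        _CsdModel(model_field, params) if algorithm == "csd" else None
    )
    kept: list[Streamline] = []
    histogram: Counter = Counter()
    n_propagated = 0
    for seed in seeds:
        if algorithm == "dti":
            result = propagate_dti(seed, model_field, tracking_mask, params)
        else:
            result = propagate_csd(
                seed, None, model_field, tracking_mask, params, model=model
            )
        for r in result.reasons:
            histogram[r.value] += 1
        if result.streamline is None:
            continue
        n_propagated += 1
        if roi_mask is None or streamline_touches(result.streamline, roi_mask):
            kept.append(result.streamline)
    if n_propagated == 0:
        logger.warning("track_bundle(%s): no streamlines propagated", algorithm)
    logger.info(
        "track_bundle(%s): %d seeds, %d propagated, %d kept",
        algorithm,
        len(seeds),
        n_propagated,
        len(kept),
    )
    return BundleResult(
        tractogram=Tractogram(kept, grid),
        n_seeds=len(seeds),
        n_propagated=n_propagated,
        termination_histogram=dict(sorted(histogram.items())),
    )
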