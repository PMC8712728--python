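"""Synthetic branching-bundle phantoms with ground truth.

Emulates the clinical acquisition this toolkit targets (2x2x2 mm voxels, one
b=0 volume plus 32 directions at b=1000 s/mm^2) on a corticospinal-tract-like
geometry: two mirrored trunk-plus-branches systems, one per hemisphere, rising
from a shared single-slice seed region toward an arc-shaped "motor" target
shell in the coronal plane.

Each hemisphere's trunk is a small cross-section of parallel voxel columns.
Only the centre column continues straight to the trunk apex, which lies on the
motor arc; every side column terminates at the branch level, where a straight
branch leaves it at a prescribed angle toward the arc. Pathways followed up a
side column therefore cannot reach the target by going straight — exactly the
situation in which multi-level re-seeding from unused FOD peaks pays off,
mirroring the fanning of the corticospinal tract near the motor cortex, while
the centre column keeps single-direction trackers from returning an empty
reconstruction.

The diffusion signal is a standard multi-tensor forward model
``S(g) = S0 * sum_i f_i * exp(-b g^T D_i g)`` with optional Rician noise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._sphere import fibonacci_hemisphere
from .formats_io import (
    BinaryMask,
    DWIDataset,
    GradientTable,
    ValidationError,
    VolumeGrid,
    write_dwi,
    write_gradient_table,
    write_mask,
)

logger = logging.getLogger(__name__)

#: White-matter-like axially symmetric diffusivities (mm^2/s).
DEFAULT_LAMBDA_PARALLEL = 1.7e-3
DEFAULT_LAMBDA_PERP = 0.2e-3
#: Isotropic diffusivity of the fiber-free background (mm^2/s), CSF/edema-like.
DEFAULT_ISO_DIFFUSIVITY = 2.0e-3


def make_default_gradients(
    n_directions: int = 32, b_value: float = 1000.0
) -> GradientTable:
    """One b=0 volume plus ``n_directions`` quasi-uniform directions at ``b_value``."""
    dirs = fibonacci_hemisphere(n_directions)
    bvals = np.concatenate([[0.0], np.full(n_directions, b_value)])
    bvecs = np.vstack([[0.0, 0.0, 0.0], dirs])
    return GradientTable(bvals=bvals, bvecs=bvecs)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, acquisition and noise description of a branching phantom.

    ``branch_angles`` are measured from the trunk axis in the coronal plane;
    each hemisphere receives one branch per angle (mirrored left/right), fanned
    alternately to the lateral and medial side of the trunk.
    """

    dims: tuple[int, int, int] = (30, 30, 30)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    trunk_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    branch_angles: tuple[float, ...] = (40.0, 70.0)
    branch_level_fraction: float = 0.6
    volume_fractions: tuple[float, ...] | None = None
    lambda_parallel: float = DEFAULT_LAMBDA_PARALLEL
    lambda_perp: float = DEFAULT_LAMBDA_PERP
    iso_diffusivity: float = DEFAULT_ISO_DIFFUSIVITY
    S0: float = 1000.0
    snr: float | None = None
    rng_seed: int = 0
    angular_threshold: float = 45.0
    gradients: GradientTable = field(default_factory=make_default_gradients)

    def __post_init__(self):
        if any(not (0.0 < a <= 90.0) for a in self.branch_angles):
            raise ValidationError("branch angles must lie in (0, 90] degrees")
        if not (0.0 < self.branch_level_fraction < 1.0):
            raise ValidationError("branch_level_fraction must lie in (0, 1)")
        if self.snr is not None and self.snr <= 0:
            raise ValidationError("snr must be positive (or None for noise-free)")
        axis = np.asarray(self.trunk_axis, dtype=float)
        if not np.allclose(axis / np.linalg.norm(axis), [0.0, 0.0, 1.0], atol=1e-9):
            raise ValidationError(
                "only a superior (+z) trunk axis is supported by the geometry builder"
            )
        if self.volume_fractions is not None:
            vf = np.asarray(self.volume_fractions, dtype=float)
            if np.any(vf < 0) or np.any(vf > 1) or abs(vf.sum() - 1.0) > 1e-9:
                raise ValidationError("volume_fractions must lie in [0,1] and sum to 1")

    @property
    def grid(self) -> VolumeGrid:
        affine = np.diag(list(self.voxel_size) + [1.0])
        return VolumeGrid(self.dims, self.voxel_size, affine)


@dataclass
class Branch:
    """One straight branch leaving a trunk column at the branch level."""

    hemisphere: str
    angle: float
    direction: np.ndarray  # unit 3-vector, voxel frame == world frame direction
    junction_voxel: tuple[int, int, int]
    endpoint_voxel: tuple[int, int, int]
    reachable_within_threshold: bool  # angle <= angular threshold


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    fiber_dirs: dict[tuple[int, int, int], np.ndarray]  # voxel -> (m, 3) unit dirs
    fiber_fractions: dict[tuple[int, int, int], np.ndarray]  # voxel -> (m,) weights
    seed_mask: BinaryMask
    target_mask_left: BinaryMask
    target_mask_right: BinaryMask
    motor_mask_left: BinaryMask
    motor_mask_right: BinaryMask
    tracking_mask: BinaryMask
    hemisphere_mask_left: BinaryMask
    hemisphere_mask_right: BinaryMask
    branches: list[Branch]
    seed_plane_world: float  # world coordinate of the seed slice (superior axis)
    arc_center_world: dict[str, np.ndarray]  # hemisphere -> (x, z) world
    arc_radius_mm: float

    @property
    def branch_reachability(self) -> list[bool]:
        return [b.reachable_within_threshold for b in self.branches]


# ---------------------------------------------------------------------------
# signal model
# ---------------------------------------------------------------------------


def simulate_signal(
    dirs: np.ndarray,
    fractions: np.ndarray,
    gradients: GradientTable,
    lambda_parallel: float = DEFAULT_LAMBDA_PARALLEL,
    lambda_perp: float = DEFAULT_LAMBDA_PERP,
    S0: float = 1.0,
) -> np.ndarray:
    """Multi-tensor signal for one voxel, one value per acquisition volume.

    Each fiber population is an axially symmetric tensor with eigenvalues
    (lambda_parallel, lambda_perp, lambda_perp) aligned to its direction, so
    ``g^T D g = lambda_perp + (lambda_parallel - lambda_perp) (g . d)^2``.
    """
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
    fractions = np.atleast_1d(np.asarray(fractions, dtype=float))
    if dirs.size == 0:
        if fractions.size and np.any(fractions != 0):
            raise ValidationError("nonzero fractions with no fiber directions")
        dirs = np.zeros((0, 3))
    if len(dirs) != len(fractions):
        raise ValidationError("one fraction per fiber direction required")
    if fractions.size and abs(fractions.sum() - 1.0) > 1e-9:
        raise ValidationError("fiber fractions must sum to 1")
    if dirs.size and not np.allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-9):
        raise ValidationError("fiber directions must be unit vectors")
    b = gradients.bvals[None, :]
    cos2 = (dirs @ gradients.bvecs.T) ** 2  # (m, n)
    adc = lambda_perp + (lambda_parallel - lambda_perp) * cos2
    signal = S0 * np.einsum("m,mn->n", fractions, np.exp(-b * adc))
    return signal


def isotropic_signal(
    gradients: GradientTable, diffusivity: float, S0: float = 1.0
) -> np.ndarray:
    """Closed-form isotropic voxel signal ``S0 exp(-b d)`` per volume."""
    return S0 * np.exp(-gradients.bvals * diffusivity)


def add_rician_noise(
    signal: np.ndarray, sigma: float, rng_seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Rician (magnitude-MRI) noise: ``sqrt((s + n1)^2 + n2^2)``, n1,n2 ~ N(0, sigma)."""
    if sigma < 0:
        raise ValidationError("noise sigma must be >= 0")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    signal = np.asarray(signal, dtype=float)
    n1 = rng.normal(0.0, sigma, size=signal.shape) if sigma > 0 else 0.0
    n2 = rng.normal(0.0, sigma, size=signal.shape) if sigma > 0 else 0.0
    return np.sqrt((signal + n1) ** 2 + np.square(n2))


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

_SAMPLE_STEP = 0.25  # voxel units along each rasterized segment
_SHELL_HALF_WIDTH = 0.75  # voxel units, radial half thickness of the motor arc
_ARC_MARGIN_DEG = 10.0


_BRANCH_HALF_WIDTH = 0.6  # voxel units, in-plane half thickness of branch chains


def _rasterize_segment(start, end, half_width: float = 0.0):
    """Voxel indices visited by a straight segment, sampled at quarter-voxel steps.

    ``half_width`` > 0 additionally marks voxels offset perpendicular to the
    segment within the coronal plane, so oblique chains are thick enough that
    a pathway running parallel to — but slightly off — the axis stays inside.
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    length = np.linalg.norm(end - start)
    n = max(2, int(np.ceil(length / _SAMPLE_STEP)) + 1)
    t = np.linspace(0.0, 1.0, n)
    pts = start[None, :] + t[:, None] * (end - start)[None, :]
    if half_width > 0:
        u = (end - start) / length
        q = np.array([u[2], 0.0, -u[0]])
        qn = np.linalg.norm(q)
        if qn > 1e-12:
            q /= qn
            pts = np.concatenate(
                [pts, pts + half_width * q, pts - half_width * q], axis=0
            )
    return np.floor(pts + 0.5).astype(int)


def _mask(values: np.ndarray, grid: VolumeGrid) -> BinaryMask:
    return BinaryMask(values=values.astype(np.uint8), grid=grid)


def make_branching_phantom(spec: PhantomSpec) -> tuple[DWIDataset, PhantomTruth]:
    """Build the two-hemisphere trunk+branches phantom and its ground truth."""
    grid = spec.grid
    nx, ny, nz = spec.dims
    cy = ny // 2
    midline = (nx - 1) / 2.0

    z0 = max(2, int(round(0.15 * nz)))  # seed slice
    height = int(round(0.5 * nz))
    z_apex = z0 + height
    z_branch = z0 + int(round(spec.branch_level_fraction * height))
    radius = z_apex - z_branch
    if radius < 2:
        raise ValidationError("branch level too close to the apex for this grid")
    if z_apex + 2 >= nz:
        raise ValidationError("trunk geometry exits the grid superiorly")

    # side-column offsets for the branches: alternate lateral (-) / medial (+),
    # largest angle most lateral
    angles_sorted = sorted(spec.branch_angles, reverse=True)
    offsets = []
    mag = 1
    for i in range(len(angles_sorted)):
        offsets.append(-mag if i % 2 == 0 else mag)
        if i % 2 == 1:
            mag += 1

    max_lat = max(
        (abs(o) + radius * np.sin(np.radians(a)) for a, o in zip(angles_sorted, offsets)),
        default=0.0,
    )
    x_trunk_left = int(np.ceil(max_lat + 1.0))
    needed = max(
        (o + radius * np.sin(np.radians(a)) for a, o in zip(angles_sorted, offsets) if o > 0),
        default=0.0,
    )
    if x_trunk_left - max_lat < 1.0 or x_trunk_left + needed + _SHELL_HALF_WIDTH >= midline:
        raise ValidationError("branch geometry exits the grid or crosses the midline")

    # population accumulators: voxel -> {pop_id: sample count}
    counts: dict[tuple[int, int, int], dict[int, int]] = {}
    pop_dirs: dict[int, np.ndarray] = {}
    branches: list[Branch] = []

    def add_segment(start, end, pop_id, half_width=0.0):
        for vox in map(tuple, _rasterize_segment(start, end, half_width)):
            counts.setdefault(vox, {}).setdefault(pop_id, 0)
            counts[vox][pop_id] += 1

    def build_hemisphere(hemi: str, next_pop: int) -> int:
        mirror = (lambda x: x) if hemi == "left" else (lambda x: (nx - 1) - x)
        x_t = mirror(x_trunk_left)
        trunk_id = next_pop
        next_pop += 1
        pop_dirs[trunk_id] = np.array([0.0, 0.0, 1.0])
        # centre column runs to the apex; side columns stop at the branch level
        add_segment((x_t, cy, z0), (x_t, cy, z_apex), trunk_id)
        sign_flip = 1.0 if hemi == "left" else -1.0
        for angle, off in zip(angles_sorted, offsets):
            x_col = x_trunk_left + off
            add_segment((mirror(x_col), cy, z0), (mirror(x_col), cy, z_branch), trunk_id)
            a = np.radians(angle)
            # branch leaves toward the same side as its column offset; solve the
            # length so the endpoint lands exactly on the arc of `radius` about
            # the trunk centre at the branch level
            s = np.sign(off)
            u = np.array([sign_flip * s * np.sin(a), 0.0, np.cos(a)])
            delta = off  # junction offset from arc centre, left-hemisphere frame
            disc = (delta * s * np.sin(a)) ** 2 - delta**2 + radius**2
            length = -delta * s * np.sin(a) + np.sqrt(disc)
            j = np.array([mirror(x_col), cy, z_branch], dtype=float)
            e = j + length * u
            if not (1.0 <= e[0] <= nx - 2 and 1.0 <= e[2] <= nz - 2):
                raise ValidationError(
                    f"{angle} degree branch exits the grid (endpoint {e})"
                )
            pop_id = next_pop
            next_pop += 1
            pop_dirs[pop_id] = u
            add_segment(j, e, pop_id, half_width=_BRANCH_HALF_WIDTH)
            branches.append(
                Branch(
                    hemisphere=hemi,
                    angle=float(angle),
                    direction=u,
                    junction_voxel=tuple(np.floor(j + 0.5).astype(int)),
                    endpoint_voxel=tuple(np.floor(e + 0.5).astype(int)),
                    reachable_within_threshold=bool(angle <= spec.angular_threshold),
                )
            )
        return next_pop

    next_pop = build_hemisphere("left", 0)
    build_hemisphere("right", next_pop)

    # per-voxel fiber directions and fractions
    fiber_dirs: dict[tuple[int, int, int], np.ndarray] = {}
    fiber_fracs: dict[tuple[int, int, int], np.ndarray] = {}
    for vox, pops in sorted(counts.items()):
        ids = sorted(pops)
        dirs = np.array([pop_dirs[i] for i in ids])
        if spec.volume_fractions is not None and len(ids) == len(spec.volume_fractions):
            fr = np.asarray(spec.volume_fractions, dtype=float)
        else:
            fr = np.array([pops[i] for i in ids], dtype=float)
            fr = fr / fr.sum()
        fiber_dirs[vox] = dirs
        fiber_fracs[vox] = fr

    # masks
    tracking = np.zeros(spec.dims, dtype=np.uint8)
    for vox in fiber_dirs:
        tracking[vox] = 1
    seed = np.zeros(spec.dims, dtype=np.uint8)
    seed[:, :, z0] = tracking[:, :, z0]

    motor = {h: np.zeros(spec.dims, dtype=np.uint8) for h in ("left", "right")}
    arc_center_world = {}
    for hemi in ("left", "right"):
        x_c = x_trunk_left if hemi == "left" else (nx - 1) - x_trunk_left
        hemi_branches = [b for b in branches if b.hemisphere == hemi]
        thetas = [0.0]
        for b in hemi_branches:
            e = np.asarray(b.endpoint_voxel, dtype=float)
            thetas.append(np.degrees(np.arctan2(e[0] - x_c, e[2] - z_branch)))
        lo, hi = min(thetas) - _ARC_MARGIN_DEG, max(thetas) + _ARC_MARGIN_DEG
        xs, zs = np.meshgrid(np.arange(nx), np.arange(nz), indexing="ij")
        dist = np.hypot(xs - x_c, zs - z_branch)
        theta = np.degrees(np.arctan2(xs - x_c, zs - z_branch))
        sel = (np.abs(dist - radius) <= _SHELL_HALF_WIDTH) & (theta >= lo) & (theta <= hi)
        motor[hemi][:, cy, :] = sel.astype(np.uint8)
        arc_center_world[hemi] = grid.voxel_to_world(
            np.array([x_c, cy, z_branch], dtype=float)
        )[[0, 2]]

    hemi_left = np.zeros(spec.dims, dtype=np.uint8)
    hemi_left[: int(np.floor(midline)) + 1, :, :] = 1
    hemi_right = 1 - hemi_left

    # signal
    gradients = spec.gradients
    n_vol = len(gradients)
    signal = np.empty(spec.dims + (n_vol,), dtype=float)
    signal[...] = isotropic_signal(gradients, spec.iso_diffusivity, spec.S0)[
        None, None, None, :
    ]
    for vox, dirs in fiber_dirs.items():
        signal[vox] = simulate_signal(
            dirs,
            fiber_fracs[vox],
            gradients,
            spec.lambda_parallel,
            spec.lambda_perp,
            spec.S0,
        )
    if spec.snr is not None:
        sigma = spec.S0 / spec.snr
        signal = add_rician_noise(signal, sigma, np.random.default_rng(spec.rng_seed))

    dwi = DWIDataset(signal=signal, grid=grid, gradients=gradients)
    truth = PhantomTruth(
        fiber_dirs=fiber_dirs,
        fiber_fractions=fiber_fracs,
        seed_mask=_mask(seed, grid),
        target_mask_left=_mask(motor["left"], grid),
        target_mask_right=_mask(motor["right"], grid),
        motor_mask_left=_mask(motor["left"], grid),
        motor_mask_right=_mask(motor["right"], grid),
        tracking_mask=_mask(tracking, grid),
        hemisphere_mask_left=_mask(hemi_left, grid),
        hemisphere_mask_right=_mask(hemi_right, grid),
        branches=branches,
        seed_plane_world=float(
            grid.voxel_to_world(np.array([0.0, 0.0, float(z0)]))[2]
        ),
        arc_center_world=arc_center_world,
        arc_radius_mm=float(radius * spec.voxel_size[2]),
    )
    logger.info(
        "phantom: %d fiber voxels, %d branches, seed slice z=%d, arc radius %.1f mm",
        len(fiber_dirs),
        len(branches),
        z0,
        truth.arc_radius_mm,
    )
    return dwi, truth


def write_phantom(dwi: DWIDataset, truth: PhantomTruth, outdir: str | Path) -> None:
    """Write dwi.nii.gz + bval/bvec, all masks, truth directions and a branch table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_dwi(dwi, outdir / "dwi.nii.gz")
    write_gradient_table(dwi.gradients, outdir / "dwi.bval", outdir / "dwi.bvec")
    write_mask(truth.seed_mask, outdir / "seed.nii.gz")
    write_mask(truth.target_mask_left, outdir / "target_L.nii.gz")
    write_mask(truth.target_mask_right, outdir / "target_R.nii.gz")
    write_mask(truth.motor_mask_left, outdir / "motor_L.nii.gz")
    write_mask(truth.motor_mask_right, outdir / "motor_R.nii.gz")
    write_mask(truth.tracking_mask, outdir / "tracking.nii.gz")

    k_max = max(len(d) for d in truth.fiber_dirs.values())
    vol = np.zeros(dwi.grid.dims + (3 * k_max,), dtype=np.float32)
    for vox, dirs in truth.fiber_dirs.items():
        vol[vox][: dirs.size] = dirs.ravel()
    import nibabel as nib

    nib.save(nib.Nifti1Image(vol, dwi.grid.affine), str(outdir / "truth_dirs.nii.gz"))

    table = {
        "arc_radius_mm": truth.arc_radius_mm,
        "seed_plane_world": truth.seed_plane_world,
        "branches": [
            {
                "hemisphere": b.hemisphere,
                "angle_deg": b.angle,
                "direction": [float(v) for v in b.direction],
                "junction_voxel": [int(v) for v in b.junction_voxel],
                "endpoint_voxel": [int(v) for v in b.endpoint_voxel],
                "reachable_within_threshold": b.reachable_within_threshold,
            }
            for b in truth.branches
        ],
    }
    (outdir / "truth.json").write_text(json.dumps(table, indent=2, sort_keys=True))
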