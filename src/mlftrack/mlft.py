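"""Multi-level fiber tracking: iterative branch re-seeding from unused FOD peaks.

Level 1 is plain deterministic FOD-peak tracking from the sampled seeds,
partitioned into pathways that reach the target region (kept as level 1) and
pathways that do not. Every point of each failed pathway is then re-examined:
FOD peaks at that point that were not followed during the traversal (and that
do not merely retrace the incoming direction) become new unidirectional branch
seeds. Branch pathways that reach the target are concatenated with the parent
segment up to their branch point and form the next level; failed branch tails
feed the harvest of the level after that. The number of levels is
user-defined (two by default).

Because level 1 equals the baseline FOD tracker's output and later levels only
add pathways, a multi-level reconstruction always covers at least the
baseline's extent. The junction angle between a parent prefix and its branch
tail may exceed the per-step angular threshold — recovering exactly those
high-angulation branchings is the point of the method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fod_model import FODField
from .formats_io import BinaryMask, Streamline, Tractogram, ValidationError
from .tracking import (
    TrackingParams,
    _CsdModel,
    propagate_csd,
    sample_seeds,
    streamline_touches,
)

logger = logging.getLogger(__name__)

#: a harvested peak within this angle (degrees) of the recorded step direction
#: is considered "used" during the parent's traversal
USED_PEAK_TOLERANCE = 1.0
#: peaks within this angle (degrees) of the incoming direction's antipode are
#: not re-seeded (would retrace the parent)
BACKTRACK_TOLERANCE = 10.0
#: branch seeds in one voxel closer than this (degrees) to an earlier one merge
DEDUP_ANGLE = 5.0


@dataclass(frozen=True)
class BranchSeed:
    """A re-seeding point on a failed pathway with an unused peak direction."""

    position: np.ndarray  # world mm, lies on the parent pathway
    initial_dir: np.ndarray  # unit vector, unused FOD peak at position
    parent_id: int  # index into the failed-pathway list of the level
    parent_prefix_end: int  # index of the branch point within the parent


@dataclass
class LevelStreamline:
    """A streamline of a multi-level bundle with branch provenance."""

    streamline: Streamline
    level: int
    parent_id: int | None = None  # id within the *failed* set it branched from
    branch_point_index: int | None = None


@dataclass
class MultiLevelBundle:
    """Streamlines organized by MLFT level; level 1 is the baseline tracker."""

    levels: list[list[LevelStreamline]]
    grid: object
    n_failed_per_level: list[int] = field(default_factory=list)
    n_branch_seeds_per_level: list[int] = field(default_factory=list)
    level1_failed: tuple[Streamline, ...] = ()

    @property
    def merged(self) -> Tractogram:
        return Tractogram(
            [ls.streamline for level in self.levels for ls in level], grid=self.grid
        )

    def level_tractogram(self, level: int) -> Tractogram:
        return Tractogram(
            [ls.streamline for ls in self.levels[level - 1]], grid=self.grid
        )

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def concatenate_branch(
    parent: Streamline, branch_point_index: int, branch_tail: Streamline
) -> Streamline:
    """Parent points [0..index] followed by tail points [1..] (junction deduplicated).

    The tail must start at the parent's branch point. The junction step may
    exceed the per-step angular threshold; that is the method's purpose.
    """
    p = parent.points
    t = branch_tail.points
    if not (0 <= branch_point_index < len(p)):
        raise ValidationError("branch point index outside the parent streamline")
    if np.linalg.norm(t[0] - p[branch_point_index]) > 1e-6:
        raise ValidationError("branch tail does not start at the parent branch point")
    return Streamline(np.vstack([p[: branch_point_index + 1], t[1:]]))


def _step_directions(points: np.ndarray) -> np.ndarray:
    d = np.diff(points, axis=0)
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def harvest_branch_seeds(
    failed: list[tuple[int, np.ndarray]],
    fods: FODField | _CsdModel,
    grid,
    params: TrackingParams,
) -> list[BranchSeed]:
    """Branch seeds from every point of every failed pathway.

    ``failed`` holds ``(pathway_id, points)`` pairs. At each point, FOD peaks
    are extracted; each peak is oriented into the forward hemisphere of the
    incoming direction, then discarded if it matches the direction actually
    followed there (within :data:`USED_PEAK_TOLERANCE`) or retraces the
    incoming direction's antipode (within :data:`BACKTRACK_TOLERANCE`). A
    point with m surviving peaks yields m seeds (duplication rule). Seeds
    falling in one voxel with near-identical directions are merged.
    """
    model = fods if isinstance(fods, _CsdModel) else _CsdModel(fods, params)
    used_cos = np.cos(np.radians(USED_PEAK_TOLERANCE))
    dedup_cos = np.cos(np.radians(DEDUP_ANGLE))
    seeds: list[BranchSeed] = []
    harvested: dict[tuple[int, int, int], list[np.ndarray]] = {}
    for pid, points in failed:
        steps = _step_directions(points)
        for i, point in enumerate(points):
            outgoing = steps[min(i, len(steps) - 1)]
            incoming = steps[max(i - 1, 0)]
            peaks = model.peaks_at(point)
            if len(peaks) == 0:
                continue
            for axis in peaks.directions:
                d = axis if axis @ incoming >= 0 else -axis
                if d @ outgoing > used_cos:
                    continue  # the peak that was followed
                if abs(d @ incoming) > np.cos(np.radians(BACKTRACK_TOLERANCE)):
                    continue  # nearly parallel to the travel axis: would retrace
                vox = tuple(grid.world_to_index(point[None, :])[0])
                prior = harvested.setdefault(vox, [])
                if any(abs(d @ q) > dedup_cos for q in prior):
                    continue
                prior.append(d)
                seeds.append(
                    BranchSeed(
                        position=point,
                        initial_dir=d,
                        parent_id=pid,
                        parent_prefix_end=i,
                    )
                )
    return seeds


def mlft_track(
    fods: FODField,
    seed_mask: BinaryMask,
    target_mask: BinaryMask,
    tracking_mask: BinaryMask,
    params: TrackingParams,
) -> MultiLevelBundle:
    """Multi-level reconstruction of a seed-to-target bundle.

    With ``params.max_levels == 1`` the result is exactly the baseline
    deterministic FOD tracker's reconstruction (same seeds, same parameters).
    """
    if seed_mask.n_voxels == 0 or target_mask.n_voxels == 0:
        raise ValidationError("seed and target masks must be nonempty")
    grid = tracking_mask.grid
    for m in (seed_mask, target_mask):
        if not m.grid.same_grid(grid):
            raise ValidationError("all masks must share one grid")
    model = _CsdModel(fods, params)
    seeds = sample_seeds(seed_mask, params.seeds_per_voxel, params.rng_seed)

    levels: list[list[LevelStreamline]] = [[]]
    # failed frontier: (id, prefix-streamline, tail points to harvest from,
    # offset of the tail within the full pathway)
    frontier: list[tuple[int, Streamline, np.ndarray, int]] = []
    n_failed_per_level: list[int] = []
    n_seeds_per_level: list[int] = [len(seeds)]

    for seed in seeds:
        result = propagate_csd(seed, None, fods, tracking_mask, params, model=model)
        if result.streamline is None:
            continue
        if streamline_touches(result.streamline, target_mask):
            levels[0].append(LevelStreamline(streamline=result.streamline, level=1))
        else:
            frontier.append(
                (len(frontier), result.streamline, result.streamline.points, 0)
            )
    n_failed_per_level.append(len(frontier))
    level1_failed = tuple(s for _, s, _, _ in frontier)
    logger.info(
        "mlft level 1: %d reached target, %d failed", len(levels[0]), len(frontier)
    )

    for level in range(2, params.max_levels + 1):
        if not frontier:
            break
        harvest_input = [(pid, tail) for pid, _, tail, _ in frontier]
        branch_seeds = harvest_branch_seeds(harvest_input, model, grid, params)
        n_seeds_per_level.append(len(branch_seeds))
        new_level: list[LevelStreamline] = []
        new_frontier: list[tuple[int, Streamline, np.ndarray, int]] = []
        for bs in branch_seeds:
            result = propagate_csd(
                bs.position, bs.initial_dir, fods, tracking_mask, params, model=model
            )
            if result.streamline is None:
                continue
            _, parent_full, _, tail_offset = frontier[bs.parent_id]
            branch_index = tail_offset + bs.parent_prefix_end
            full = concatenate_branch(parent_full, branch_index, result.streamline)
            if streamline_touches(result.streamline, target_mask):
                new_level.append(
                    LevelStreamline(
                        streamline=full,
                        level=level,
                        parent_id=bs.parent_id,
                        branch_point_index=branch_index,
                    )
                )
            else:
                new_frontier.append(
                    (
                        len(new_frontier),
                        full,
                        result.streamline.points,
                        branch_index,
                    )
                )
        levels.append(new_level)
        n_failed_per_level.append(len(new_frontier))
        logger.info(
            "mlft level %d: %d branch seeds, %d reached target, %d failed",
            level,
            len(branch_seeds),
            len(new_level),
            len(new_frontier),
        )
        frontier = new_frontier

    return MultiLevelBundle(
        levels=levels,
        grid=grid,
        n_failed_per_level=n_failed_per_level,
        n_branch_seeds_per_level=n_seeds_per_level,
        level1_failed=level1_failed,
    )


def filter_interhemispheric(
    bundle: MultiLevelBundle,
    left_mask: BinaryMask,
    right_mask: BinaryMask,
    seed_plane: float,
    axis: int = 2,
) -> MultiLevelBundle:
    """Remove streamlines that visit both hemispheres superior to the seed plane.

    ``seed_plane`` is the world coordinate of the shared seed slice along
    world axis ``axis`` (superior-inferior by default). Visits at or below the
    plane do not count — the seed region is shared between hemispheres by
    construction.
    """
    if np.any(left_mask.values & right_mask.values):
        raise ValidationError("hemisphere masks must be disjoint")
    half_step = 1e-9
    new_levels = []
    removed = 0
    for level in bundle.levels:
        kept = []
        for ls in level:
            pts = ls.streamline.points
            above = pts[pts[:, axis] > seed_plane + half_step]
            if len(above) and (
                left_mask.contains_points(above).any()
                and right_mask.contains_points(above).any()
            ):
                removed += 1
                continue
            kept.append(ls)
        new_levels.append(kept)
    if removed:
        logger.info("interhemispheric filter removed %d streamline(s)", removed)
    return MultiLevelBundle(
        levels=new_levels,
        grid=bundle.grid,
        n_failed_per_level=bundle.n_failed_per_level,
        n_branch_seeds_per_level=bundle.n_branch_seeds_per_level,
        level1_failed=bundle.level1_failed,
    )
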