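"""Seed sampling and streamline propagation contracts."""

import numpy as np
import pytest

from mlftrack.fod_model import FODField, build_sh_basis
from mlftrack.formats_io import BinaryMask, ValidationError, VolumeGrid
from mlftrack.tensor_model import TensorField
from mlftrack.tracking import (
    TerminationReason,
    TrackingParams,
    propagate_csd,
    propagate_dti,
    sample_seeds,
    streamline_touches,
    track_bundle,
)


def _grid(dims, voxel=2.0):
    return VolumeGrid(dims, (voxel,) * 3, np.diag([voxel] * 3 + [1.0]))


def _mask(values, grid):
    return BinaryMask(values=values.astype(np.uint8), grid=grid)


class TestSampleSeeds:
    def test_five_seeds_per_voxel_on_one_plane(self):
        grid = _grid((5, 5, 5))
        values = np.zeros((5, 5, 5))
        values[2, 2, 1] = 1
        seeds = sample_seeds(_mask(values, grid), 5, rng_seed=0)
        assert len(seeds) == 5
        # through-plane (z) coordinate fixed to the voxel-centre plane
        assert np.allclose(seeds[:, 2], 2.0)
        vox = grid.world_to_voxel(seeds)
        assert np.all(np.abs(vox[:, :2] - 2.0) <= 0.5)

    def test_deterministic_given_seed(self):
        grid = _grid((5, 5, 5))
        values = np.zeros((5, 5, 5))
        values[1:4, 1:4, 2] = 1
        mask = _mask(values, grid)
        assert np.array_equal(
            sample_seeds(mask, 5, rng_seed=9), sample_seeds(mask, 5, rng_seed=9)
        )
        assert not np.array_equal(
            sample_seeds(mask, 5, rng_seed=9), sample_seeds(mask, 5, rng_seed=10)
        )

    def test_ten_voxels_fifty_points_inside_their_voxels(self):
        grid = _grid((12, 5, 5))
        values = np.zeros((12, 5, 5))
        values[1:11, 2, 3] = 1
        seeds = sample_seeds(_mask(values, grid), 5, rng_seed=4)
        assert len(seeds) == 50
        vox = grid.world_to_voxel(seeds)
        source = np.repeat(np.arange(1, 11), 5)
        assert np.all(np.abs(vox[:, 0] - source) <= 0.5)
        assert np.allclose(seeds[:, 2], 3 * 2.0)

    def test_empty_mask_rejected(self):
        grid = _grid((3, 3, 3))
        with pytest.raises(ValidationError):
            sample_seeds(_mask(np.zeros((3, 3, 3)), grid), 5, 0)


def _uniform_tensor_field(grid, principal=(1.0, 0, 0), lam=(1.7e-3, 0.2e-3)):
    e = np.asarray(principal, dtype=float)
    e /= np.linalg.norm(e)
    D = lam[1] * np.eye(3) + (lam[0] - lam[1]) * np.outer(e, e)
    comp = np.array([D[0, 0], D[1, 1], D[2, 2], D[0, 1], D[0, 2], D[1, 2]])
    components = np.broadcast_to(comp, grid.dims + (6,)).copy()
    from mlftrack.tensor_model import fractional_anisotropy

    fa = np.full(grid.dims, float(fractional_anisotropy([lam[0], lam[1], lam[1]])))
    pdir = np.broadcast_to(e, grid.dims + (3,)).copy()
    return TensorField(components=components, fa=fa, principal_dir=pdir, grid=grid)


class TestPropagateDti:
    def test_uniform_field_spans_mask_and_terminates_on_exit(self):
        grid = _grid((20, 5, 5))
        values = np.zeros((20, 5, 5))
        values[:, 2, 2] = 1
        mask = _mask(values, grid)
        field = _uniform_tensor_field(grid)
        params = TrackingParams()
        seed = np.array([10 * 2.0, 2 * 2.0, 2 * 2.0])
        result = propagate_dti(seed, field, mask, params)
        assert result.reasons == (
            TerminationReason.LEFT_MASK,
            TerminationReason.LEFT_MASK,
        )
        pts = result.streamline.points
        assert pts[:, 0].max() - pts[:, 0].min() > 0.8 * 19 * 2.0
        # constant step length
        assert np.allclose(result.streamline.step_lengths(), 1.0, atol=1e-6)

    def test_low_fa_seed_does_not_propagate(self):
        grid = _grid((5, 5, 5))
        values = np.ones((5, 5, 5))
        mask = _mask(values, grid)
        field = _uniform_tensor_field(grid, lam=(0.75e-3, 0.7e-3))  # FA ~ 0.03
        result = propagate_dti(np.array([4.0, 4.0, 4.0]), field, mask, TrackingParams())
        assert result.streamline is None
        assert result.reasons == (
            TerminationReason.LOW_FA,
            TerminationReason.LOW_FA,
        )

    def test_sharp_rotation_terminates_with_angle_exceeded(self):
        # principal direction rotates 60 degrees at the volume midline; a
        # two-voxel step makes the tracker see the jump in a single step
        grid = _grid((20, 5, 5))
        values = np.ones((20, 5, 5))
        mask = _mask(values, grid)
        rot = np.array(
            [np.cos(np.radians(60)), np.sin(np.radians(60)), 0.0]
        )
        left = _uniform_tensor_field(grid, (1.0, 0, 0))
        right = _uniform_tensor_field(grid, rot)
        components = left.components.copy()
        components[10:] = right.components[10:]
        pdir = left.principal_dir.copy()
        pdir[10:] = right.principal_dir[10:]
        field = TensorField(
            components=components, fa=left.fa, principal_dir=pdir, grid=grid
        )
        params = TrackingParams(step_size=4.0)
        result = propagate_dti(np.array([4.0, 4.0, 4.0]), field, mask, params)
        assert TerminationReason.ANGLE_EXCEEDED in result.reasons

    def test_seed_outside_mask_rejected(self):
        grid = _grid((5, 5, 5))
        values = np.zeros((5, 5, 5))
        values[0, 0, 0] = 1
        field = _uniform_tensor_field(grid)
        with pytest.raises(ValidationError):
            propagate_dti(np.array([8.0, 8.0, 8.0]), field, _mask(values, grid), TrackingParams())


def _delta_fod_field(grid, direction, l_max=6):
    """Uniform FOD field: band-limited delta lobe along ``direction``."""
    coeffs = build_sh_basis(l_max, np.asarray(direction)[None, :])[0]
    vol = np.broadcast_to(coeffs, grid.dims + (len(coeffs),)).copy()
    from mlftrack.fod_model import SphericalHarmonicBasis

    return FODField(coeffs=vol, basis=SphericalHarmonicBasis(l_max), grid=grid)


class TestPropagateCsd:
    def test_straight_phantom_trunk_traversed_end_to_end(self, models, params):
        truth = models["truth"]
        grid = models["dwi"].grid
        # seed at the centre-column base (left hemisphere); the centre column
        # is the only one reaching the apex
        seed_vox = None
        apex_z = max(
            vox[2] for vox, d in truth.fiber_dirs.items() if len(d) == 1
        )
        for vox in truth.fiber_dirs:
            if truth.seed_mask.values[vox]:
                col = [v for v in truth.fiber_dirs if v[0] == vox[0] and v[1] == vox[1]]
                if max(v[2] for v in col) == apex_z and vox[0] < 15:
                    seed_vox = vox
                    break
        assert seed_vox is not None
        seed = grid.voxel_to_world(np.array(seed_vox, dtype=float))
        result = propagate_csd(
            seed, None, models["fods"], truth.tracking_mask, params
        )
        idx = grid.world_to_index(result.streamline.points)
        assert idx[:, 2].min() <= seed_vox[2]
        assert idx[:, 2].max() >= apex_z

    def test_junction_prefers_minimal_deviation_not_the_branch(
        self, models, params, branch70_left, branch70_target
    ):
        """At the 70-degree junction the straight peak is chosen; the branch
        (> angular threshold) is never entered by the baseline tracker."""
        truth = models["truth"]
        grid = models["dwi"].grid
        jx = np.array(branch70_left.junction_voxel, dtype=float)
        seed = grid.voxel_to_world(np.array([jx[0], jx[1], 4.0]))
        result = propagate_csd(seed, None, models["fods"], truth.tracking_mask, params)
        assert not streamline_touches(result.streamline, branch70_target)

    def test_best_peak_beyond_threshold_terminates_angle_exceeded(self):
        a = np.radians(50.0)
        grid = _grid((9, 9, 9))
        field = _delta_fod_field(grid, [np.sin(a), 0, np.cos(a)])
        mask = _mask(np.ones((9, 9, 9)), grid)
        result = propagate_csd(
            np.array([8.0, 8.0, 8.0]),
            np.array([0.0, 0.0, 1.0]),
            field,
            mask,
            TrackingParams(),
        )
        assert result.reasons == (TerminationReason.ANGLE_EXCEEDED,)

    def test_no_peak_terminates_on_subthreshold_fod(self):
        grid = _grid((5, 5, 5))
        coeffs = build_sh_basis(6, np.array([[0, 0, 1.0]]))[0] * 0.01  # max ~ 0.02
        vol = np.broadcast_to(coeffs, (5, 5, 5, 28)).copy()
        from mlftrack.fod_model import SphericalHarmonicBasis

        field = FODField(coeffs=vol, basis=SphericalHarmonicBasis(6), grid=grid)
        mask = _mask(np.ones((5, 5, 5)), grid)
        result = propagate_csd(np.array([4.0, 4.0, 4.0]), None, field, mask, TrackingParams())
        assert result.streamline is None
        assert result.reasons == (
            TerminationReason.NO_PEAK,
            TerminationReason.NO_PEAK,
        )


class TestTrackBundle:
    def test_roi_any_point_semantics(self, models, params):
        truth = models["truth"]
        result = track_bundle(
            "csd",
            models["fods"],
            truth.seed_mask,
            truth.tracking_mask,
            truth.motor_mask_left,
            params,
        )
        assert len(result.tractogram) > 0
        for s in result.tractogram:
            assert streamline_touches(s, truth.motor_mask_left)

    def test_unreachable_roi_gives_empty_tractogram(self, models, params):
        truth = models["truth"]
        grid = models["dwi"].grid
        far = np.zeros(grid.dims)
        far[0, 0, -1] = 1
        result = track_bundle(
            "csd",
            models["fods"],
            truth.seed_mask,
            truth.tracking_mask,
            _mask(far, grid),
            params,
        )
        assert len(result.tractogram) == 0

    def test_baseline_never_reaches_high_angle_branch(
        self, csd_left, branch70_target
    ):
        reached = sum(
            streamline_touches(s, branch70_target) for s in csd_left.tractogram
        )
        assert reached == 0

    def test_unknown_algorithm_rejected(self, models, params):
        truth = models["truth"]
        with pytest.raises(ValueError):
            track_bundle(
                "qball",
                models["fods"],
                truth.seed_mask,
                truth.tracking_mask,
                None,
                params,
            )


class TestTrackingInvariants:
    def test_angle_threshold_holds_within_all_segments(self, csd_left, params):
        max_cos_dev = np.cos(np.radians(params.angle_threshold)) - 1e-9
        for s in csd_left.tractogram:
            d = np.diff(s.points, axis=0)
            d /= np.linalg.norm(d, axis=1, keepdims=True)
            dots = np.einsum("ij,ij->i", d[:-1], d[1:])
            assert np.all(dots >= max_cos_dev)

    def test_step_length_invariant(self, csd_left, models, params):
        step = params.resolve_step(models["dwi"].grid)
        for s in csd_left.tractogram:
            assert np.allclose(s.step_lengths(), step, atol=1e-6)

    def test_points_stay_inside_tracking_mask(self, csd_left, models):
        truth = models["truth"]
        for s in csd_left.tractogram:
            assert truth.tracking_mask.contains_points(s.points).all()

    def test_bit_identical_reruns(self, models, params, csd_left):
        truth = models["truth"]
        again = track_bundle(
            "csd",
            models["fods"],
            truth.seed_mask,
            truth.tracking_mask,
            truth.motor_mask_left,
            params,
        )
        assert len(again.tractogram) == len(csd_left.tractogram)
        for a, b in zip(again.tractogram, csd_left.tractogram):
            assert np.array_equal(a.points, b.points)
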