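import math
import random

import numpy as np
import pytest

from tractomics.tracking import (
    OrientationField,
    TrackingParams,
    enumerate_pathway_tasks,
    propagate_streamline,
    sample_step_direction,
    track_pathway,
)
from tractomics.volume import AffineTransform


def uniform_field(shape, direction, fraction=0.8, kappa=math.inf, second=None):
    """Field with one (optionally two) populations everywhere."""
    nx, ny, nz = shape
    directions = np.zeros((nx, ny, nz, 2, 3))
    fractions = np.zeros((nx, ny, nz, 2))
    kappas = np.zeros((nx, ny, nz, 2))
    d = np.asarray(direction, dtype=float)
    directions[..., 0, :] = d / np.linalg.norm(d)
    fractions[..., 0] = fraction
    kappas[..., 0] = kappa
    if second is not None:
        d2, f2 = second
        d2 = np.asarray(d2, dtype=float)
        directions[..., 1, :] = d2 / np.linalg.norm(d2)
        fractions[..., 1] = f2
        kappas[..., 1] = kappa
    return OrientationField(directions, fractions, kappas, AffineTransform.identity())


class TestSampleStepDirection:
    def test_zero_fraction_voxel_terminates(self):
        field = uniform_field((3, 3, 3), (1, 0, 0), fraction=0.0)
        direction, reason = sample_step_direction(
            field, (1, 1, 1), None, random.Random(0)
        )
        assert direction is None
        assert reason == "low-fraction"

    def test_sign_alignment_with_incoming_direction(self):
        field = uniform_field((3, 3, 3), (1, 0, 0))
        direction, reason = sample_step_direction(
            field, (1, 1, 1), (-1.0, 0.0, 0.0), random.Random(0)
        )
        assert reason is None
        assert direction == pytest.approx((-1.0, 0.0, 0.0))

    def test_excessive_turn_terminates(self):
        field = uniform_field((3, 3, 3), (1, 0, 0))
        direction, reason = sample_step_direction(
            field, (1, 1, 1), (0.0, 1.0, 0.0), random.Random(0), curvature_deg=80.0
        )
        assert direction is None
        assert reason == "curvature"

    def test_seed_selection_frequency_follows_fractions(self):
        # binomial oracle: fractions 0.6 / 0.3 give 2:1 selection odds
        field = uniform_field(
            (3, 3, 3), (1, 0, 0), fraction=0.6, second=((0, 1, 0), 0.3)
        )
        rng = random.Random(12345)
        n = 100_000
        hits = 0
        for _ in range(n):
            direction, _ = sample_step_direction(field, (1, 1, 1), None, rng)
            if abs(direction[0]) > 0.5:
                hits += 1
        p = 2 / 3
        se = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se

    def test_propagation_follows_population_parallel_to_heading(self):
        field = uniform_field(
            (3, 3, 3), (1, 0, 0), fraction=0.3, second=((0, 1, 0), 0.6)
        )
        direction, _ = sample_step_direction(
            field, (1, 1, 1), (1.0, 0.0, 0.0), random.Random(0)
        )
        assert direction == pytest.approx((1.0, 0.0, 0.0))

    def test_dispersion_concentrates_with_kappa(self):
        field = uniform_field((3, 3, 3), (1, 0, 0), kappa=200.0)
        rng = random.Random(7)
        dots = []
        for _ in range(2000):
            d, _ = sample_step_direction(field, (1, 1, 1), None, rng)
            dots.append(abs(d[0]))
        # E[1 - |cos theta|] ~ 1/kappa for large kappa
        assert 1 - np.mean(dots) < 3 / 200


class TestPropagateStreamline:
    params = TrackingParams(seed=0)

    def test_zero_fraction_start_gives_single_point(self):
        field = uniform_field((3, 3, 3), (1, 0, 0), fraction=0.0)
        sl = propagate_streamline(field, (1.5, 1.5, 1.5), self.params, random.Random(0))
        assert len(sl) == 1
        assert sl.reason_backward == sl.reason_forward == "low-fraction"

    def test_straight_tube_traversed_end_to_end(self, straight_tube_phantom):
        field = straight_tube_phantom.field
        params = TrackingParams(step_size=0.5, seed=0)
        sl = propagate_streamline(field, (12.0, 5.0, 5.0), params, random.Random(1))
        xs = sl.points[:, 0]
        # geometric oracle: the tube spans x in [2, 22]; with 0.5-voxel
        # steps the point count is about the tube length / step size
        assert xs.max() - xs.min() > 16
        assert len(sl) == pytest.approx((xs.max() - xs.min()) / 0.5, abs=4)

    def test_max_steps_bounds_point_count(self):
        field = uniform_field((40, 5, 5), (1, 0, 0))
        params = TrackingParams(max_steps=3, seed=0)
        sl = propagate_streamline(field, (20.0, 2.5, 2.5), params, random.Random(0))
        assert len(sl) <= 2 * 3 + 1

    def test_start_outside_grid_rejected(self):
        field = uniform_field((3, 3, 3), (1, 0, 0))
        with pytest.raises(ValueError, match="outside grid"):
            propagate_streamline(field, (5.0, 1.0, 1.0), self.params, random.Random(0))


class TestTrackPathway:
    def run_task(self, phantom, seed_name, target_name, params, field=None):
        labels = phantom.labels
        seed_label = labels.registry.by_name(seed_name).label
        target_label = labels.registry.by_name(target_name).label
        return track_pathway(
            field if field is not None else phantom.field,
            labels.roi_voxels(seed_label),
            labels.roi_mask(target_label),
            params,
            seed_name=seed_name,
            target_name=target_name,
        )

    def test_empty_seed_set_is_hard_error(self, straight_tube_phantom):
        with pytest.raises(ValueError, match="empty"):
            track_pathway(
                straight_tube_phantom.field,
                set(),
                np.zeros(straight_tube_phantom.config.shape, dtype=bool),
                TrackingParams(),
            )

    def test_straight_tube_full_retention_and_tube_mask(
        self, straight_tube_phantom
    ):
        params = TrackingParams(samples_per_voxel=5, seed=0)
        result = self.run_task(
            straight_tube_phantom, "seed_left", "target_left", params
        )
        # no dispersion: every in-tube seed launches a retained streamline
        launched_in_tube = sum(
            straight_tube_phantom.point_in_tube(
                "seed_left__target_left", np.array(v) + 0.5
            )
            for v in straight_tube_phantom.labels.roi_voxels(1)
        )
        assert result.retained >= launched_in_tube * params.samples_per_voxel
        # geometric oracle: visited voxels lie inside the tube up to the
        # single voxel layer a terminating streamline records past each
        # tube end before its low-fraction stop
        tube = straight_tube_phantom.tube_mask("seed_left__target_left")
        outside = result.mask & ~tube
        assert outside.sum() <= 0.1 * result.mask.sum()

    def test_disconnected_target_retains_nothing(self, straight_tube_phantom):
        # no tube reaches this far corner: zero retained, zero voxels
        labels = straight_tube_phantom.labels
        target = np.zeros(straight_tube_phantom.config.shape, dtype=bool)
        target[0:2, 8:10, 8:10] = True
        result = track_pathway(
            straight_tube_phantom.field,
            labels.roi_voxels(1),
            target,
            TrackingParams(samples_per_voxel=5, seed=0),
        )
        assert result.retained == 0
        assert result.voxel_count == 0

    def test_visitation_total_at_least_retained(self, straight_tube_phantom):
        result = self.run_task(
            straight_tube_phantom,
            "seed_left",
            "target_left",
            TrackingParams(samples_per_voxel=3, seed=0),
        )
        assert result.counts.sum() >= result.retained

    def test_mask_monotone_in_threshold(self, straight_tube_phantom):
        result = self.run_task(
            straight_tube_phantom,
            "seed_left",
            "target_left",
            TrackingParams(samples_per_voxel=5, seed=0),
        )
        prev = result.mask_at(1)
        for threshold in (2, 4, 8, 16):
            current = result.mask_at(threshold)
            assert not (current & ~prev).any()  # subset
            prev = current

    def test_fixed_seed_rerun_is_identical(self, straight_tube_phantom):
        params = TrackingParams(samples_per_voxel=4, seed=9)
        a = self.run_task(straight_tube_phantom, "seed_left", "target_left", params)
        b = self.run_task(straight_tube_phantom, "seed_left", "target_left", params)
        assert np.array_equal(a.counts, b.counts)
        assert a.retained == b.retained

    def test_crossing_region_transited_by_both_tracts(self, crossing_phantom):
        params = TrackingParams(samples_per_voxel=10, seed=0)
        res_a = self.run_task(crossing_phantom, "seed_a_left", "target_a_left", params)
        res_b = self.run_task(crossing_phantom, "seed_b_left", "target_b_left", params)
        assert res_a.retained / res_a.n_streamlines > 0.5
        assert res_b.retained / res_b.n_streamlines > 0.5
        # dropping the minor population starves the minor tract
        single = crossing_phantom.field.primary_only()
        res_b_single = self.run_task(
            crossing_phantom, "seed_b_left", "target_b_left", params, field=single
        )
        assert res_b_single.retained < res_b.retained
        assert res_b_single.retained / res_b_single.n_streamlines <= 0.5


class TestEnumeratePathwayTasks:
    def test_bilateral_seed_and_six_targets_give_twelve_tasks(
        self, default_bundle
    ):
        registry = default_bundle.phantom.labels.registry
        targets = [
            "amygdala",
            "caudate_nucleus",
            "globus_pallidus",
            "putamen",
            "thalamus",
            "nucleus_accumbens",
        ]
        tasks = enumerate_pathway_tasks(registry, "hippocampus", targets)
        assert len(tasks) == 12
        for seed_name, target_name in tasks:
            assert seed_name.rsplit("_", 1)[1] == target_name.rsplit("_", 1)[1]

    def test_empty_target_list_gives_no_tasks(self, default_bundle):
        registry = default_bundle.phantom.labels.registry
        assert enumerate_pathway_tasks(registry, "hippocampus", []) == []

    def test_midline_target_excluded(self, default_bundle):
        registry = default_bundle.phantom.labels.registry
        tasks = enumerate_pathway_tasks(
            registry, "hippocampus", ["amygdala", "brainstem"]
        )
        assert len(tasks) == 2
        assert all("brainstem" not in t for _, t in tasks)

    def test_unknown_structure_is_hard_error(self, default_bundle):
        registry = default_bundle.phantom.labels.registry
        with pytest.raises(KeyError):
            enumerate_pathway_tasks(registry, "hippocampus", ["cerebellum"])

    def test_midline_seed_rejected(self, default_bundle):
        registry = default_bundle.phantom.labels.registry
        with pytest.raises(ValueError, match="not bilateral"):
            enumerate_pathway_tasks(registry, "brainstem", ["amygdala"])
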