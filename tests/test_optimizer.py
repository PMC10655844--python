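"""Next-best greedy search, ordering, ROI rules and transfer."""

import itertools

import numpy as np
import pytest

import seegrs as sg
from seegrs.optimizer import (PriorityOrder, best_order, electrode_in_roi,
                              exhaustive_best, next_best_search, rs_curves,
                              transfer_configuration)
from seegrs.sensitivity import recordable_matrix


def _toy_problem():
    """10 ROI patches; electrode A records 1-6, B records 5-8, C 7-10.

    Each electrode has two contacts whose |V| exceeds every threshold on
    its patches, so recordability is threshold-independent.
    """
    n_patches = 10
    cover = {0: range(0, 6), 1: range(4, 8), 2: range(6, 10)}
    matrix = np.zeros((6, n_patches))
    for e, patches in cover.items():
        matrix[2 * e, list(patches)] = 1500.0
        matrix[2 * e + 1, list(patches)] = 1500.0
    plf = sg.PatchLeadField(
        matrix=matrix, patch_area_cm2=10.0, moment_density=0.465,
        patch_centers=np.arange(n_patches),
        patch_center_positions=np.zeros((n_patches, 3)))
    electrodes = [np.array([0, 1]), np.array([2, 3]), np.array([4, 5])]
    roi = sg.ROI.from_ids(range(n_patches))
    return plf, electrodes, roi


class TestPriorityOrder:
    def test_must_permute_the_three_thresholds(self):
        with pytest.raises(ValueError):
            PriorityOrder((500.0, 500.0, 200.0))

    def test_parse(self):
        assert PriorityOrder.parse("1000,500,200").thresholds \
            == (1000.0, 500.0, 200.0)


class TestNextBestSearch:
    def test_greedy_sequence_on_toy(self):
        plf, electrodes, roi = _toy_problem()
        config = next_best_search(plf, electrodes, None, roi, seed=0)
        # A first (covers 6), then C (adds 7-10: 4 > B's 2); cost 0 after 2
        assert config.trajectory_ids == [0, 2]
        assert config.costs_by_threshold[500.0] == [4, 0]

    def test_uniquely_covering_electrode_is_selected(self):
        plf, electrodes, roi = _toy_problem()
        # patch 9 is only covered by C
        config = next_best_search(plf, electrodes, None, roi, seed=1)
        assert 2 in config.trajectory_ids

    def test_no_recordable_patches_stops_immediately(self):
        plf, electrodes, roi = _toy_problem()
        silent = sg.PatchLeadField(
            matrix=np.zeros_like(plf.matrix), patch_area_cm2=10.0,
            moment_density=0.465, patch_centers=plf.patch_centers,
            patch_center_positions=plf.patch_center_positions)
        config = next_best_search(silent, electrodes, None, roi, seed=2)
        assert config.trajectory_ids == []

    def test_empty_candidate_set_rejected(self):
        plf, _, roi = _toy_problem()
        with pytest.raises(ValueError):
            next_best_search(plf, [], None, roi)

    def test_collisions_mask_candidates(self):
        plf, electrodes, roi = _toy_problem()
        collision = np.zeros((3, 3), dtype=bool)
        collision[0, 2] = collision[2, 0] = True  # C collides with A
        config = next_best_search(plf, electrodes, collision, roi, seed=3)
        assert config.trajectory_ids == [0, 1]  # falls back to B

    def test_primary_cost_strictly_decreases(self, midscale):
        config = next_best_search(midscale["patch_lf"],
                                  midscale["electrodes"],
                                  midscale["collision"], midscale["roi"],
                                  max_electrodes=8, seed=4)
        primary = config.costs_by_threshold[config.priority.thresholds[0]]
        assert all(b < a for a, b in zip(primary, primary[1:]))

    def test_selected_configuration_never_collides(self, midscale):
        config = next_best_search(midscale["patch_lf"],
                                  midscale["electrodes"],
                                  midscale["collision"], midscale["roi"],
                                  max_electrodes=10, seed=5)
        ids = config.trajectory_ids
        for a, b in itertools.combinations(ids, 2):
            assert not midscale["collision"][a, b]


class TestRsCurves:
    def test_monotone_and_threshold_ordered(self, midscale):
        config = next_best_search(midscale["patch_lf"],
                                  midscale["electrodes"],
                                  midscale["collision"], midscale["roi"],
                                  max_electrodes=8, seed=6)
        report = config.rs_report
        for thr in sg.THRESHOLDS_UV:
            curve = report.rs_by_count[thr]
            assert all(b >= a for a, b in zip(curve, curve[1:]))
        for i in range(len(config)):
            assert report.rs_by_count[200.0][i] \
                >= report.rs_by_count[500.0][i] \
                >= report.rs_by_count[1000.0][i]

    def test_final_rs_matches_recording_sensitivity(self, midscale):
        config = next_best_search(midscale["patch_lf"],
                                  midscale["electrodes"],
                                  midscale["collision"], midscale["roi"],
                                  max_electrodes=6, seed=7)
        report = rs_curves(midscale["patch_lf"], midscale["electrodes"],
                           config, midscale["roi"])
        chosen = [midscale["electrodes"][i] for i in config.trajectory_ids]
        for thr in sg.THRESHOLDS_UV:
            direct = sg.recording_sensitivity(midscale["patch_lf"], chosen,
                                              midscale["roi"], thr)
            assert report.rs_by_count[thr][-1] == pytest.approx(direct)


class TestBestOrder:
    def test_orders_fixed_set_greedily(self):
        plf, electrodes, roi = _toy_problem()
        config = best_order(plf, electrodes, [0, 1, 2], roi, seed=0)
        assert config.trajectory_ids == [0, 2, 1]

    def test_single_electrode(self):
        plf, electrodes, roi = _toy_problem()
        config = best_order(plf, electrodes, [1], roi, seed=0)
        assert config.trajectory_ids == [1]

    def test_ordering_preserves_final_rs(self):
        plf, electrodes, roi = _toy_problem()
        config = best_order(plf, electrodes, [2, 0, 1], roi, seed=0)
        final = config.rs_report.rs_by_count[500.0][-1]
        direct = sg.recording_sensitivity(plf, electrodes, roi, 500.0)
        assert final == pytest.approx(direct)

    def test_empty_set_rejected(self):
        plf, electrodes, roi = _toy_problem()
        with pytest.raises(ValueError):
            best_order(plf, electrodes, [], roi)


class TestGreedyVsExhaustive:
    def _random_instance(self, seed, n_elec=10, n_patches=30):
        rng = np.random.default_rng(seed)
        matrix = np.zeros((2 * n_elec, n_patches))
        for e in range(n_elec):
            covered = rng.random(n_patches) < 0.25
            matrix[2 * e:2 * e + 2, covered] = 1500.0
        plf = sg.PatchLeadField(
            matrix=matrix, patch_area_cm2=10.0, moment_density=0.465,
            patch_centers=np.arange(n_patches),
            patch_center_positions=np.zeros((n_patches, 3)))
        electrodes = [np.array([2 * e, 2 * e + 1]) for e in range(n_elec)]
        roi = sg.ROI.from_ids(range(n_patches))
        return plf, electrodes, roi

    @pytest.mark.parametrize("seed", range(6))
    def test_first_pick_is_exhaustive_best_single(self, seed):
        plf, electrodes, roi = self._random_instance(seed)
        config = next_best_search(plf, electrodes, None, roi, seed=seed)
        rec = recordable_matrix(plf, electrodes, 500.0)
        best_single = rec.sum(axis=1).max()
        assert rec[config.trajectory_ids[0]].sum() == best_single

    @pytest.mark.parametrize("seed", range(4))
    def test_greedy_cost_vs_exhaustive_optimum(self, seed):
        plf, electrodes, roi = self._random_instance(seed, n_elec=12)
        config = next_best_search(plf, electrodes, None, roi,
                                  max_electrodes=3, seed=seed)
        rec = recordable_matrix(plf, electrodes, 500.0)
        _, opt_cost = exhaustive_best(rec, None, min(3, len(config)))
        greedy_cost = config.costs_by_threshold[500.0][
            min(3, len(config)) - 1]
        gap = greedy_cost - opt_cost
        assert gap >= 0, "greedy can never beat the exhaustive optimum"
        # greedy set cover is within (1 - 1/e) of optimal coverage
        n_total = 30
        assert (n_total - greedy_cost) >= (1 - 1 / np.e) * (
            n_total - opt_cost) - 1e-9


class TestElectrodeInRoi:
    def _index(self, head3, roi_ids):
        sub = head3.cortex.submesh(np.asarray(list(roi_ids)))
        return sg.DistanceIndex(sub)

    def test_contacts_on_surface_included(self, head3, midscale):
        roi_idx = self._index(head3, midscale["roi"].element_ids)
        pts = head3.cortex.centroids[list(midscale["roi"].element_ids)[:16]]
        assert electrode_in_roi(pts, roi_idx)

    def test_nearest_contact_too_far(self, head3, midscale):
        roi_idx = self._index(head3, midscale["roi"].element_ids)
        pts = np.tile(np.array([[0.0, 0.0, 200.0]]), (16, 1))
        pts += np.arange(16)[:, None] * [0, 0, 1.0]
        assert not electrode_in_roi(pts, roi_idx)

    def test_half_rule(self):
        # flat ROI triangle at z=0; 1 contact at 2 mm, 6 more within
        # 100 mm, 9 beyond: fails the 8-of-16 half rule
        roi_mesh = sg.SurfaceMesh(
            np.array([[-50, -50, 0], [50, -50, 0], [0, 80, 0.]]),
            np.array([[0, 1, 2]]))
        idx = sg.DistanceIndex(roi_mesh)
        z = np.array([2.0] + [50.0] * 6 + [500.0] * 9)
        pts = np.column_stack([np.zeros(16), np.zeros(16), z])
        assert not electrode_in_roi(pts, idx)
        z = np.array([2.0] + [50.0] * 7 + [500.0] * 8)
        pts = np.column_stack([np.zeros(16), np.zeros(16), z])
        assert electrode_in_roi(pts, idx)


class TestTransfer:
    def test_identity_transfer_no_reduction(self, head3, midscale):
        config = next_best_search(midscale["patch_lf"],
                                  midscale["electrodes"],
                                  midscale["collision"], midscale["roi"],
                                  max_electrodes=6, seed=8)
        curve = config.rs_report.rs_by_count[500.0]
        contact_points = np.stack(
            [midscale["tset"].trajectories[i].contact_points
             for i in config.trajectory_ids])
        res = transfer_configuration(
            curve, contact_points, np.eye(3), np.zeros(3), head3.cortex,
            midscale["roi"], target_sulci=midscale["sulci"], rs_floor=50.0)
        assert res.rs_transferred == pytest.approx(res.rs_matched, abs=1e-9)
        assert res.percent_reduction == pytest.approx(0.0, abs=1e-9)

    def test_n_at_75_rule(self, head3, midscale):
        curve = [40.0, 60.0, 70.0, 76.0, 80.0]
        contact_points = np.stack(
            [midscale["tset"].trajectories[i].contact_points
             for i in range(5)])
        res = transfer_configuration(
            curve, contact_points, np.eye(3), np.zeros(3), head3.cortex,
            midscale["roi"], rs_floor=75.0)
        assert res.n_at_75 == 4
        assert res.rs_matched == pytest.approx(76.0)

    def test_percent_reduction_arithmetic(self):
        # 80% matched vs 60% transferred is a 25% reduction
        assert 100.0 * (80.0 - 60.0) / 80.0 == pytest.approx(25.0)

    def test_scaled_transform_rejected(self, head3, midscale):
        contact_points = np.zeros((1, 16, 3))
        with pytest.raises(ValueError):
            transfer_configuration([80.0], contact_points, 2.0 * np.eye(3),
                                   np.zeros(3), head3.cortex,
                                   midscale["roi"])

    def test_reflection_rejected(self, head3, midscale):
        refl = np.diag([-1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            transfer_configuration([80.0], np.zeros((1, 16, 3)), refl,
                                   np.zeros(3), head3.cortex,
                                   midscale["roi"])

    def test_rotation_moves_rs(self, head3, midscale):
        """A quarter-turn moves the electrodes off the ROI cap, so the
        transferred RS drops and validity may change."""
        config = next_best_search(midscale["patch_lf"],
                                  midscale["electrodes"],
                                  midscale["collision"], midscale["roi"],
                                  max_electrodes=6, seed=9)
        curve = config.rs_report.rs_by_count[500.0]
        contact_points = np.stack(
            [midscale["tset"].trajectories[i].contact_points
             for i in config.trajectory_ids])
        rot = np.array([[1.0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]])  # x-axis 90d
        res = transfer_configuration(
            curve, contact_points, rot, np.zeros(3), head3.cortex,
            midscale["roi"], target_sulci=midscale["sulci"], rs_floor=50.0)
        assert res.rs_transferred < res.rs_matched
        assert res.percent_reduction > 0.0
        assert res.electrode_valid.shape == (res.n_at_75,)
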