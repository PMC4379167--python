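"""Contact maps, event detection, clustering, labelling, crystal RMSD."""

import itertools

import numpy as np
import pytest

from dimerkin.interfaces import (
    ContactMap,
    CrystalDimer,
    InterfaceCluster,
    auto_cluster,
    cluster_interfaces,
    compute_contact_map,
    crystal_rmsd,
    detect_dimer_events,
    format_interface_label,
    interface_dissimilarity,
    label_cluster,
)
from dimerkin.trajectory import BeadTrajectory, ProtomerTopology, TMAssignment, assign_tm_regions


class TestContactMap:
    def test_contact_below_cutoff(self):
        m = compute_contact_map([[0.0, 0, 0]], [[7.0, 0, 0]], None).matrix
        assert m[0, 0] == 1

    def test_no_contact_beyond_cutoff(self):
        m = compute_contact_map([[0.0, 0, 0]], [[9.0, 0, 0]], None).matrix
        assert m[0, 0] == 0

    def test_cutoff_is_strict(self):
        m = compute_contact_map([[0.0, 0, 0]], [[8.0, 0, 0]], None).matrix
        assert m[0, 0] == 0

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(1)
        A = rng.uniform(0, 60, (15, 3))
        B = rng.uniform(0, 60, (12, 3))
        box = np.array([60.0, 60.0, 60.0])
        m = compute_contact_map(A, B, box).matrix
        for i in range(15):
            for j in range(12):
                d = B[j] - A[i]
                d -= box * np.round(d / box)
                assert m[i, j] == (np.linalg.norm(d) < 8.0)

    def test_periodic_wrap_creates_contact(self):
        m = compute_contact_map([[1.0, 0, 0]], [[99.0, 0, 0]], [100.0, 100, 100]).matrix
        assert m[0, 0] == 1  # 2 Å through the boundary

    def test_empty_protomer_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_contact_map(np.empty((0, 3)), [[0.0, 0, 0]], None)


class TestDissimilarity:
    def _map(self, mat):
        return ContactMap(np.asarray(mat, dtype=np.uint8))

    def test_zero_on_identical(self):
        m = self._map(np.eye(4, dtype=int))
        assert interface_dissimilarity(m, m) == 0.0

    def test_two_entry_difference_is_sqrt2(self):
        a = np.zeros((3, 3), dtype=int)
        b = a.copy()
        b[0, 1] = b[2, 0] = 1
        assert interface_dissimilarity(self._map(a), self._map(b)) == pytest.approx(np.sqrt(2))

    def test_transpose_is_zero_in_homodimer_mode(self):
        rng = np.random.default_rng(2)
        m = (rng.random((6, 6)) < 0.3).astype(np.uint8)
        assert interface_dissimilarity(self._map(m), self._map(m.T), homodimer=True) == 0.0
        assert interface_dissimilarity(self._map(m), self._map(m.T)) > 0.0

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(3)
        maps = [self._map((rng.random((5, 5)) < 0.4).astype(np.uint8)) for _ in range(6)]
        for a, b in itertools.combinations(maps, 2):
            assert interface_dissimilarity(a, b) == interface_dissimilarity(b, a)
        for a, b, c in itertools.combinations(maps, 3):
            dab = interface_dissimilarity(a, b)
            dbc = interface_dissimilarity(b, c)
            dac = interface_dissimilarity(a, c)
            assert dac <= dab + dbc + 1e-12

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            interface_dissimilarity(self._map(np.zeros((2, 3))), self._map(np.zeros((3, 3))))


def planted_families(n_per=12, seed=0):
    """Two families of maps with disjoint contact blocks plus bit noise."""
    rng = np.random.default_rng(seed)
    maps = []
    truth = []
    for fam, (rows, cols) in enumerate((((0, 5), (10, 15)), ((10, 15), (0, 5)))):
        base = np.zeros((20, 20), dtype=np.uint8)
        base[rows[0] : rows[1], cols[0] : cols[1]] = 1
        for k in range(n_per):
            m = base.copy()
            i, j = rng.integers(0, 20, 2)
            m[i, j] ^= 1  # one flipped bit of noise
            maps.append(ContactMap(m, observation_id=len(maps)))
            truth.append(fam)
    return maps, truth


class TestClustering:
    def test_identical_maps_collapse_to_one_cluster(self):
        m = np.zeros((4, 4), dtype=np.uint8)
        m[0, 1] = 1
        maps = [ContactMap(m.copy(), observation_id=i) for i in range(5)]
        clusters, assign = cluster_interfaces(maps, k=2, seed=0)
        sizes = sorted(cl.n_members for cl in clusters)
        # one effective cluster: all members equidistant (zero) from it
        assert sizes[-1] == 5 or len(set(assign)) == 1

    def test_planted_partition_recovered(self):
        maps, truth = planted_families()
        clusters, assign = cluster_interfaces(maps, k=2, seed=0)
        a = np.array(assign)
        t = np.array(truth)
        acc = max((a == t).mean(), (a == 1 - t).mean())
        assert acc == 1.0

    def test_objective_nonincreasing(self):
        maps, _ = planted_families(seed=5)
        hist: list[float] = []
        cluster_interfaces(maps, k=3, seed=1, objective_history=hist)
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))

    def test_homodimer_mode_groups_swapped_maps(self):
        rng = np.random.default_rng(4)
        base = (rng.random((10, 10)) < 0.3).astype(np.uint8)
        other = np.zeros_like(base)
        other[9, 0] = other[8, 1] = other[7, 2] = other[6, 3] = 1
        maps = []
        for i in range(6):
            m = base if i % 2 == 0 else base.T
            maps.append(ContactMap(m.copy(), observation_id=i))
        maps.append(ContactMap(other, observation_id=6))
        clusters, assign = cluster_interfaces(maps, k=2, homodimer=True, seed=0)
        assert len({assign[i] for i in range(6)}) == 1
        assert assign[6] != assign[0]

    def test_k_validation(self):
        maps, _ = planted_families(n_per=2)
        with pytest.raises(ValueError):
            cluster_interfaces(maps, k=0)
        with pytest.raises(ValueError):
            cluster_interfaces(maps, k=10)


class TestLabelling:
    def _cluster_from(self, matrices):
        stack = np.stack([m.astype(float) for m in matrices])
        return InterfaceCluster(
            0,
            list(range(len(matrices))),
            stack.mean(axis=0),
            stack.max(axis=2).mean(axis=0),
            stack.max(axis=1).mean(axis=0),
        )

    def test_label_vocabulary(self):
        # TM1: residues 0-9, TM2: 10-19, TM4: 20-29, TM5: 30-39
        tm_map = {r: "TM1" for r in range(10)}
        tm_map |= {r: "TM2" for r in range(10, 20)}
        tm_map |= {r: "TM4" for r in range(20, 30)}
        tm_map |= {r: "TM5" for r in range(30, 40)}
        m = np.zeros((40, 40), dtype=np.uint8)
        m[0:5, 20:26] = 1  # 5 on TM1 (A) vs 6 on TM4 (B)
        m[10:14, 30:33] = 1  # 4 on TM2 (A) vs 3 on TM5 (B)
        cl = self._cluster_from([m])
        assert label_cluster(cl, tm_map) == "TM1,2/TM4,5"

    def test_below_min_involved_excluded(self):
        tm_map = {r: "TM3" for r in range(10)}
        m = np.zeros((10, 10), dtype=np.uint8)
        m[0, 0] = m[1, 1] = 1  # only 2 involved residues on TM3
        cl = self._cluster_from([m])
        assert label_cluster(cl, tm_map) == "-/-"

    def test_marginal_is_member_average(self):
        rng = np.random.default_rng(6)
        mats = [(rng.random((8, 8)) < 0.4).astype(np.uint8) for _ in range(3)]
        maps = [ContactMap(m, observation_id=i) for i, m in enumerate(mats)]
        clusters, _ = cluster_interfaces(maps, k=1, seed=0)
        cl = clusters[0]
        expect_a = np.mean([m.any(axis=1) for m in mats], axis=0)
        expect_b = np.mean([m.any(axis=0) for m in mats], axis=0)
        assert np.allclose(cl.marginal_a, expect_a)
        assert np.allclose(cl.marginal_b, expect_b)
        assert np.allclose(cl.centroid, np.mean(mats, axis=0))

    def test_homodimer_label_canonical_order(self):
        assert format_interface_label({"TM4", "TM5"}, {"TM1", "TM2"}, homodimer=True) == (
            "TM1,2/TM4,5"
        )
        assert format_interface_label({"TM1", "TM2", "H8"}, {"TM1", "TM2", "H8"}) == (
            "TM1,2,H8/TM1,2,H8"
        )

    def test_empty_cluster_rejected(self):
        cl = InterfaceCluster(0, [], np.zeros((2, 2)), np.zeros(2), np.zeros(2))
        with pytest.raises(ValueError, match="empty"):
            label_cluster(cl, {0: "TM1", 1: "TM1"})


def _two_protomer_traj(n_contact_each, n_frames=6, together=range(0, 6)):
    """Two 12-bead protomers; n_contact_each beads placed in cross-contact."""
    n = 12
    tm = TMAssignment(ranges={"TM1": ((0, n - 1),)}, anchors={"TM1": 0})
    tops = [
        ProtomerTopology("x", (0, n - 1), {r: r for r in range(n)}, tm),
        ProtomerTopology("x", (0, n - 1), {r: n + r for r in range(n)}, tm),
    ]
    frames = []
    for f in range(n_frames):
        A = np.column_stack([np.arange(n) * 20.0, np.zeros(n), np.zeros(n)])
        B = A.copy()
        B[:, 1] = 500.0  # far apart by default
        if f in together:
            B[:n_contact_each, 1] = 5.0  # first k beads of B face first k of A
            A_sub = A[:n_contact_each]
            B[:n_contact_each, 0] = A_sub[:, 0]
        frames.append(np.vstack([A, B]))
    return BeadTrajectory(np.stack(frames), np.arange(n_frames) * 1.0, np.array([1000.0, 1000, 100]), tops)


class TestDetection:
    def test_nine_residues_is_no_event(self):
        traj = _two_protomer_traj(9)
        events, _ = detect_dimer_events(traj, min_residues=10, min_persist_frames=2)
        assert events == []

    def test_ten_residues_sustained_is_one_event_at_first_frame(self):
        traj = _two_protomer_traj(10)
        events, maps = detect_dimer_events(traj, min_residues=10, min_persist_frames=2)
        assert len(events) == 1
        assert events[0].time == 0.0
        assert maps[0].matrix.sum() >= 10

    def test_transient_touch_removed_by_persistence_gate(self):
        traj = _two_protomer_traj(10, n_frames=8, together=[3])
        events, _ = detect_dimer_events(traj, min_residues=10, min_persist_frames=2)
        assert events == []

    def test_events_match_generator_log(self, bd_run, bd_detection):
        traj, truth = bd_run
        events, _ = bd_detection
        frame_dt = traj.times[1] - traj.times[0]
        window = 3 * frame_dt
        matchable = [e for e in truth if e.time <= traj.times[-1] - window]
        det_by_pair = {e.pair: e.time for e in events}
        for te in matchable:
            assert te.pair in det_by_pair
            assert abs(det_by_pair[te.pair] - te.time) <= window + frame_dt
        assert len(events) <= len(truth)

    def test_subsampling_stability(self, bd_run):
        traj, _ = bd_run
        events1, _ = detect_dimer_events(traj, min_residues=6, min_persist_frames=4)
        sub = BeadTrajectory(
            traj.positions[::2], traj.times[::2], traj.box[::2], traj.topologies
        )
        events2, _ = detect_dimer_events(sub, min_residues=6, min_persist_frames=2)
        window = 4 * (traj.times[1] - traj.times[0])
        t1 = {e.pair: e.time for e in events1}
        t2 = {e.pair: e.time for e in events2}
        common = set(t1) & set(t2)
        assert len(common) >= max(1, int(0.8 * len(t1)))
        for p in common:
            assert abs(t1[p] - t2[p]) <= 2 * window


class TestRuleLabelRecovery:
    def test_events_receive_generating_rule_label(self, bd_run, bd_detection):
        from tests.conftest import TWO_RULES

        traj, truth = bd_run
        events, maps = bd_detection
        top = traj.topologies[0]
        tm_map = {r - top.residue_range[0]: h for r, h in assign_tm_regions(top).items()}
        clusters, assign = auto_cluster(maps, tm_map, homodimer=True, seed=0)
        truth_by_pair = {e.pair: e.rule_index for e in truth}
        rule_labels = [r.label for r in TWO_RULES]
        hits = sum(
            1
            for ev, a in zip(events, assign)
            if clusters[a].label == rule_labels[truth_by_pair[ev.pair]]
        )
        assert hits / len(events) >= 0.95

    def test_membership_fractions_sum_to_one(self, bd_detection):
        events, maps = bd_detection
        clusters, assign = cluster_interfaces(maps, k=2, homodimer=True, seed=0)
        fracs = np.bincount(assign) / len(assign)
        assert fracs.sum() == pytest.approx(1.0)


class TestCrystalRMSD:
    def _dimer(self, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 8, (20, 3))
        b = rng.normal(0, 8, (20, 3)) + np.array([30.0, 0, 0])
        return a, b

    def test_self_comparison_is_zero(self):
        a, b = self._dimer()
        assert crystal_rmsd(a, b, CrystalDimer("self", a, b)) < 1e-9

    def test_rigid_motion_of_whole_dimer_is_zero(self):
        from scipy.spatial.transform import Rotation

        a, b = self._dimer(1)
        R = Rotation.random(random_state=3).as_matrix()
        t = np.array([5.0, -2.0, 8.0])
        assert crystal_rmsd(a @ R.T + t, b @ R.T + t, CrystalDimer("x", a, b)) < 1e-6

    def test_protomer_order_invariance(self):
        a, b = self._dimer(2)
        c, d = self._dimer(3)
        cry = CrystalDimer("x", c, d)
        assert crystal_rmsd(a, b, cry) == pytest.approx(crystal_rmsd(b, a, cry), abs=1e-9)

    def test_heterodimer_mode_forbids_chain_swap(self):
        a, b = self._dimer(4)
        cry = CrystalDimer("x", b, a)  # chains swapped in the reference
        assert crystal_rmsd(a, b, cry) < 1e-9  # homodimer mode may swap
        assert crystal_rmsd(a, b, cry, heterodimer=True) > 1.0

    def test_length_mismatch_rejected(self):
        a, b = self._dimer(5)
        with pytest.raises(ValueError, match="correspondence"):
            crystal_rmsd(a[:10], b, CrystalDimer("x", a, b))
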