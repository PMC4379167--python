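"""Pair extraction, rate-matrix inference, diffusion profile, Jarzynski PMF."""

import numpy as np
import pytest
from scipy.linalg import expm

from dimerkin.mcmc import McmcSettings
from dimerkin.pairdiff import (
    BinnedPairTrajectory,
    RateMatrixModel,
    build_tridiagonal_generator,
    compute_pair_geometry,
    diffusion_profile,
    extract_pair_trajectories,
    jarzynski_pmf,
    stationary_distribution,
)
from dimerkin.synthetic import (
    KBT_300K,
    SteeringSchedule,
    WorkTrace,
    generate_work_traces,
    simulate_distance_chain,
    simulate_protomer_bd,
)

FAST = McmcSettings(n_samples=3000, burn_in=1500, seed=0)


def symmetric_chain(m, k):
    K = np.zeros((m, m))
    for j in range(m - 1):
        K[j, j + 1] = K[j + 1, j] = k
    np.fill_diagonal(K, -K.sum(axis=1))
    return K


def counts_from_chain(chain, m):
    counts = np.zeros((m, m))
    np.add.at(counts, (chain[:-1], chain[1:]), 1.0)
    return counts


class TestPairExtraction:
    def _traj(self, n_protomers, seed=0, duration=200.0):
        traj, _ = simulate_protomer_bd(
            n_protomers, 700.0, 1.0, 0.0, [], duration, 2.0, seed=seed
        )
        return traj

    def test_two_protomers_nothing_discarded(self):
        traj = self._traj(2)
        geo = compute_pair_geometry(traj, 0, 1)
        assert geo.valid.all()

    def test_planted_third_protomer_splits_segment(self):
        from dimerkin.synthetic import _disc_bead_layout, _render_beads, make_disc_topology
        from dimerkin.trajectory import BeadTrajectory

        layout = _disc_bead_layout(20.0, 5)
        tops = make_disc_topology(3, 5)
        n_frames = 100
        frames = []
        for f in range(n_frames):
            third = [130.0, 100.0] if 50 <= f <= 60 else [400.0, 400.0]
            centers = np.array([[100.0, 100.0], [160.0, 100.0], third])
            frames.append(_render_beads(centers, np.zeros(3), layout))
        traj = BeadTrajectory(
            np.stack(frames), np.arange(n_frames, dtype=float), np.array([800.0, 800.0, 100.0]), tops
        )
        geo = compute_pair_geometry(traj, 0, 1)
        assert not geo.valid[50:61].any()
        assert geo.valid[:50].all() and geo.valid[61:].all()

    def test_distance_range_excludes_close_frames(self):
        traj = self._traj(2, seed=2)
        binned = extract_pair_trajectories(traj, bin_edges=np.arange(30.0, 100.0, 10.0))
        geo = compute_pair_geometry(traj, 0, 1)
        in_range = ((geo.d >= 30.0) & (geo.d <= 90.0)).sum()
        assert sum(len(s) for s in binned.segments) == in_range

    def test_angles_in_range(self):
        traj = self._traj(2, seed=3)
        geo = compute_pair_geometry(traj, 0, 1)
        assert np.all((geo.phi1 >= 0) & (geo.phi1 < 2 * np.pi))
        assert np.all((geo.phi2 >= 0) & (geo.phi2 < 2 * np.pi))


class TestRateMatrixInference:
    def test_empty_counts_rejected(self):
        binned = BinnedPairTrajectory(np.arange(30.0, 70.0, 10.0), 1.0, np.zeros((3, 3)))
        with pytest.raises(ValueError, match="empty"):
            RateMatrixModel(binned)

    def test_disconnected_graph_rejected(self):
        counts = np.zeros((3, 3))
        counts[0, 0] = 5
        counts[2, 2] = 5  # two components never linked
        binned = BinnedPairTrajectory(np.arange(30.0, 70.0, 10.0), 1.0, counts)
        with pytest.raises(ValueError, match="disconnected"):
            RateMatrixModel(binned)

    def test_loglike_matches_hand_computed_three_bin(self):
        N = np.array([[50.0, 5, 0], [4, 80, 6], [0, 7, 40]])
        tau = 2.0
        binned = BinnedPairTrajectory(np.arange(30.0, 70.0, 10.0), tau, N)
        model = RateMatrixModel(binned)
        theta = np.log(np.array([0.05, 0.08, 0.03, 0.06]))
        K = build_tridiagonal_generator(theta[:2], theta[2:])
        expect = float((N * np.log(expm(tau * K))).sum())
        assert model.loglike(theta) == pytest.approx(expect, rel=1e-12)

    def test_uniform_symmetric_chain_closed_form(self):
        K = symmetric_chain(5, 0.07)
        D = diffusion_profile(K, delta_d=10.0)
        assert np.allclose(D, 10.0**2 * 0.07 * 1e-7)

    def test_two_bin_rate_recovery(self):
        K = np.array([[-0.08, 0.08], [0.12, -0.12]])
        chain = simulate_distance_chain(K, 1.0, 60_000, seed=6)
        binned = BinnedPairTrajectory(np.array([30.0, 40.0, 50.0]), 1.0, counts_from_chain(chain, 2))
        res = RateMatrixModel(binned).fit(FAST)
        Km = res.K_mean
        assert abs(Km[0, 1] - 0.08) / 0.08 < 0.05
        assert abs(Km[1, 0] - 0.12) / 0.12 < 0.05

    def test_constant_D_landscape_recovered_flat(self):
        K = symmetric_chain(4, 0.05)
        chain = simulate_distance_chain(K, 1.0, 40_000, seed=2)
        binned = BinnedPairTrajectory(np.arange(30.0, 80.0, 10.0), 1.0, counts_from_chain(chain, 4))
        res = RateMatrixModel(binned).fit(McmcSettings(n_samples=4000, burn_in=2000, seed=7))
        D = res.diffusion_samples().mean(axis=0)
        true_D = 10.0**2 * 0.05 * 1e-7
        assert np.all(np.abs(D / true_D - 1.0) < 0.10)

    def test_detailed_balance_of_posterior_mean(self):
        K = np.zeros((3, 3))
        K[0, 1], K[1, 0], K[1, 2], K[2, 1] = 0.1, 0.05, 0.02, 0.08
        np.fill_diagonal(K, -K.sum(axis=1))
        chain = simulate_distance_chain(K, 1.0, 40_000, seed=8)
        binned = BinnedPairTrajectory(np.arange(30.0, 70.0, 10.0), 1.0, counts_from_chain(chain, 3))
        res = RateMatrixModel(binned).fit(FAST)
        Km, Pm = res.K_mean, res.P_samples.mean(axis=0)
        for j in range(2):
            flux_up = Pm[j] * Km[j, j + 1]
            flux_dn = Pm[j + 1] * Km[j + 1, j]
            assert abs(flux_up - flux_dn) / flux_up < 0.10

    def test_permutation_invariance_of_counts(self):
        # the sufficient statistic is the count matrix: shuffling transition
        # order leaves it unchanged
        chain = simulate_distance_chain(symmetric_chain(3, 0.1), 1.0, 5000, seed=9)
        trans = list(zip(chain[:-1], chain[1:]))
        rng = np.random.default_rng(0)
        rng.shuffle(trans)
        shuffled = np.zeros((3, 3))
        for a, b in trans:
            shuffled[a, b] += 1
        assert np.array_equal(shuffled, counts_from_chain(chain, 3))

    def test_stationary_distribution_birth_death(self):
        K = build_tridiagonal_generator(np.log([0.2, 0.1]), np.log([0.05, 0.4]))
        P = stationary_distribution(K)
        assert P.sum() == pytest.approx(1.0)
        assert np.allclose(P @ K, 0.0, atol=1e-12)


class TestJarzynski:
    def test_identical_traces_give_work_profile_zero_error(self):
        sets = generate_work_traces(5.0, 0.0, 3, 4, seed=0)
        prof = jarzynski_pmf(sets)
        frac = (prof.lam - prof.lam[0]) / (prof.lam[-1] - prof.lam[0])
        assert np.allclose(prof.pmf, 5.0 * frac, atol=1e-9)
        assert np.allclose(prof.error, 0.0)

    def test_gaussian_works_recover_free_energy(self):
        sets = generate_work_traces(10.0, 1.0, 5, 5, seed=3)
        prof = jarzynski_pmf(sets)
        scatter = max(prof.error[-1], 0.2)
        assert abs(prof.pmf[-1] - 10.0) < 3 * scatter

    def test_pmf_never_exceeds_mean_work(self):
        for seed in range(5):
            sets = generate_work_traces(8.0, 2.0, 4, 6, seed=seed)
            prof = jarzynski_pmf(sets)
            W = np.stack([tr.work for s in sets for tr in s])
            assert np.all(prof.pmf <= W.mean(axis=0) - W.mean(axis=0)[0] + 1e-9)

    def test_anchored_at_zero(self):
        sets = generate_work_traces(3.0, 0.5, 2, 3, seed=1)
        prof = jarzynski_pmf(sets)
        assert prof.pmf[0] == 0.0

    def test_inconsistent_schedules_rejected(self):
        s1 = generate_work_traces(1.0, 0.1, 1, 2, seed=0)[0]
        other = SteeringSchedule(lam0=0.0, lam1=1.0)
        s2 = [WorkTrace(other, np.zeros(other.n_points))]
        with pytest.raises(ValueError, match="schedule"):
            jarzynski_pmf([s1, s2])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            jarzynski_pmf([])

    def test_default_schedule_matches_steering_protocol(self):
        sched = SteeringSchedule()
        assert sched.velocity == 0.05  # rad/ns
        assert sched.k_spring == 800.0  # (kcal/mol)/rad^2
        assert sched.lam[0] == 1.2 and sched.lam[-1] == 2.1
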