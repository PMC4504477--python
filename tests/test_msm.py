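"""State decomposition and MSM estimation."""

import itertools

import numpy as np
import pytest

from agomsm import (TrajectoryEnsemble, ago_like_chain, ago_like_emission,
                    emit_features, make_metastable_chain, simulate_chain)
from agomsm.msm import (APMConfig, apm_iterate, apm_split, choose_n_macro,
                        count_transitions, escape_probability, estimate_T,
                        kcenters, lifetime, lifetimes, propagate,
                        spectral_lump)


def labels_ens(*series, dt=1.0):
    return TrajectoryEnsemble([np.asarray(s, dtype=np.int64) for s in series],
                              dt=dt)


class TestKCenters:
    def test_two_separated_clouds_get_one_center_each(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.1, (40, 2))
        b = rng.normal(10.0, 0.1, (40, 2))
        X = np.vstack([a, b])
        labels, centers, radius = kcenters(X, 2, seed=3)
        # brute-force optimum over all center pairs for comparison
        best = min(
            max(np.minimum(np.linalg.norm(X - X[i], axis=1),
                           np.linalg.norm(X - X[j], axis=1)).max(), 0)
            for i, j in itertools.combinations(range(len(X)), 2))
        assert len(set(labels[:40])) == 1 and len(set(labels[40:])) == 1
        assert labels[0] != labels[-1]
        # greedy K-centers is a 2-approximation of the optimal radius
        assert radius <= 2 * best + 1e-12

    def test_k_equals_n_gives_zero_radius(self):
        X = np.arange(10.0)[:, None]
        labels, centers, radius = kcenters(X, 10, seed=0)
        assert radius == 0.0
        assert len(set(labels)) == 10

    def test_radius_non_increasing_in_k(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 3))
        radii = [kcenters(X, k, seed=5)[2] for k in range(1, 15)]
        assert all(r1 >= r2 - 1e-12 for r1, r2 in zip(radii, radii[1:]))

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kcenters(np.zeros((3, 1)), 4)


class TestEscapeAndLifetime:
    def test_hand_enumerated_escape(self):
        # trajectory [i,i,j,j]: two starts in i at t=1, one stays
        ens = labels_ens([0, 0, 1, 1])
        assert escape_probability(ens, 0, 1.0) == pytest.approx(0.5)

    def test_zero_time_and_constant_trajectory(self):
        ens = labels_ens([0, 0, 0, 0], [1, 0, 0, 1])
        assert escape_probability(ens, 0, 0.0) == 0.0
        const = labels_ens([2, 2, 2, 2, 2])
        assert all(escape_probability(const, 2, t, n_states=3) == 0.0
                   for t in (1.0, 2.0, 3.0))

    def test_lifetime_threshold_is_one_minus_inv_e(self):
        from agomsm.msm import ESCAPE_THRESHOLD
        assert ESCAPE_THRESHOLD == pytest.approx(1 - 1 / np.e)
        assert ESCAPE_THRESHOLD == pytest.approx(0.632, abs=5e-4)

    def test_lifetime_matches_two_state_escape_rate(self):
        # absorbing escape with per-step probability a: the escape
        # probability is exactly P(i, n) = 1 - (1-a)^n, so the lifetime is
        # the interpolated crossing of 1 - 1/e
        a = 0.2
        rng = np.random.default_rng(8)
        durations = rng.geometric(a, size=2000)
        series = []
        for d in durations:
            arr = np.ones(40, dtype=np.int64)
            arr[:min(d, 40)] = 0
            series.append(arr)
        ens = TrajectoryEnsemble(series, dt=1.0)
        t_est = lifetime(ens, 0, 30.0, n_states=2)
        # analytic crossing: (1-a)^t = 1/e -> t = -1/ln(1-a)
        t_true = -1.0 / np.log(1 - a)
        assert t_est == pytest.approx(t_true, rel=0.15)

    def test_never_escaping_state_flagged_infinite(self):
        ens = labels_ens([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        assert np.isinf(lifetimes(ens, 2, 3.0)[0])


class TestApmSplit:
    def test_two_macro_hmm_states_nest_within_macrostates(self):
        chain = make_metastable_chain(2, 2, 1.0, 0.005, seed=3, lag_unit=1.0)
        lab = simulate_chain(chain, 4, 5000, seed=4)
        em_centers = np.array([0.0, 1.0, 8.0, 9.0])[:, None]
        from agomsm.synthetic import EmissionModel
        feat = emit_features(lab, EmissionModel(em_centers, 0.3), seed=5)
        assign = apm_split(feat, t0=20.0, seed=6)
        hidden_macro = chain.macro_of_micro[lab.concatenated()]
        purity = []
        for i in range(assign.n_states):
            members = hidden_macro[assign.flat() == i]
            purity.append(np.bincount(members).max() / len(members))
        assert np.mean(purity) > 0.95

    def test_splitting_stops_once_escape_crosses_threshold(self):
        # four fast-mixing, well-separated basins: splitting stops at the
        # basin level because each basin's escape probability saturates at
        # 1 - pi_i = 0.75, above the 1 - 1/e lifetime threshold, while
        # any union of basins never crosses it
        chain = make_metastable_chain(4, 1, 1.0, 0.9, seed=1, lag_unit=1.0,
                                      adjacency="full", target_escape=0.75)
        lab = simulate_chain(chain, 2, 4000, seed=2)
        from agomsm.synthetic import EmissionModel
        centers = np.array([[0.0], [10.0], [20.0], [30.0]])
        feat = emit_features(lab, EmissionModel(centers, 0.3), seed=3)
        assign = apm_split(feat, t0=50.0, seed=0)
        assert assign.n_states == 4
        assert not assign.floor_flagged

    def test_identical_frames_stay_one_state(self):
        feat = TrajectoryEnsemble([np.zeros((50, 1)), np.zeros((30, 1))],
                                  dt=1.0)
        assign = apm_split(feat, t0=5.0, seed=0)
        assert assign.n_states == 1

    def test_post_split_lifetimes_below_t0(self, ago_features):
        t0 = 400.0
        assign = apm_split(ago_features, t0=t0, seed=1)
        life = lifetimes(assign.labels, assign.n_states, t0)
        ok = [life[i] < t0 for i in range(assign.n_states)
              if i not in assign.floor_flagged]
        assert all(ok)


class TestCounting:
    def test_hand_enumerated_counts(self):
        ens = labels_ens([0, 1, 0, 1])
        C1 = count_transitions(ens, 1.0, 2)
        assert np.array_equal(C1, [[0, 2], [1, 0]])
        C2 = count_transitions(ens, 2.0, 2)
        assert np.array_equal(C2, [[1, 0], [0, 1]])

    def test_strided_counting(self):
        ens = labels_ens([0, 0, 1, 1, 0])
        C = count_transitions(ens, 2.0, 2, mode="strided")
        # strided pairs: (0,1) and (1,0)
        assert np.array_equal(C, [[0, 1], [1, 0]])

    def test_lag_longer_than_trajectories_rejected(self):
        ens = labels_ens([0, 1, 0])
        with pytest.raises(ValueError):
            count_transitions(ens, 3.0, 2)

    def test_unvisited_start_state_warns(self):
        ens = labels_ens([0, 0, 0, 1])
        with pytest.warns(RuntimeWarning):
            count_transitions(ens, 1.0, 2)


class TestEstimation:
    def test_two_state_estimate_and_stationary(self, two_state_msm):
        assert np.allclose(two_state_msm.T, [[0.9, 0.1], [0.2, 0.8]])
        assert two_state_msm.pi == pytest.approx([2 / 3, 1 / 3], abs=1e-12)

    def test_symmetric_counts_equal_under_both_modes(self):
        C = np.array([[5, 2], [2, 7]])
        a = estimate_T(C, mode="nonreversible")
        b = estimate_T(C, mode="symmetrized")
        assert np.allclose(a.T, b.T)

    def test_block_diagonal_counts_trimmed_with_warning(self):
        C = np.array([[10, 5, 0], [5, 10, 0], [0, 0, 3]])
        with pytest.warns(RuntimeWarning):
            msm = estimate_T(C)
        assert msm.n_states == 2
        assert not msm.connected
        assert np.array_equal(msm.active, [0, 1])

    def test_element_recovery_within_binomial_error(self, ago_chain):
        lab = simulate_chain(ago_chain, 6, 30000, seed=21)
        C = count_transitions(lab, ago_chain.lag_unit, ago_chain.n_micro)
        msm = estimate_T(C, lag=ago_chain.lag_unit)
        Ttrue = ago_chain.T_true[np.ix_(msm.active, msm.active)]
        rows = C[np.ix_(msm.active, msm.active)].sum(axis=1, keepdims=True)
        se = np.sqrt(np.maximum(Ttrue * (1 - Ttrue), 1e-12) / rows)
        frac_ok = np.mean(np.abs(msm.T - Ttrue) <= 3 * se + 1e-9)
        assert frac_ok >= 0.95


class TestPropagate:
    def test_zero_steps_identity(self, two_state_msm):
        p0 = np.array([0.3, 0.7])
        assert np.array_equal(propagate(two_state_msm, p0, 0), p0)

    def test_stationary_is_fixed_point(self, two_state_msm):
        p = propagate(two_state_msm, two_state_msm.pi, 7)
        assert np.allclose(p, two_state_msm.pi, atol=1e-12)

    def test_hand_squared_matrix(self, two_state_msm):
        p = propagate(two_state_msm, np.array([1.0, 0.0]), 2)
        assert p == pytest.approx([0.83, 0.17], abs=1e-12)

    def test_mass_conserved_every_step(self, two_state_msm):
        p = np.array([0.5, 0.5])
        for _ in range(50):
            p = propagate(two_state_msm, p, 1)
            assert abs(p.sum() - 1.0) < 1e-12

    def test_negative_input_rejected(self, two_state_msm):
        with pytest.raises(ValueError):
            propagate(two_state_msm, np.array([1.2, -0.2]), 1)


class TestSpectralLump:
    def test_exact_blocks_recovered(self):
        T = np.array([[0.9, 0.1, 0, 0], [0.1, 0.9, 0, 0],
                      [0, 0, 0.8, 0.2], [0, 0, 0.2, 0.8]])
        C = (T * 1000).astype(int)
        # keep both blocks by building the MSM directly
        from agomsm.msm import MicrostateMSM, stationary_distribution
        msm = MicrostateMSM(T=T, C=C, lag=1.0,
                            pi=np.full(4, 0.25), active=np.arange(4))
        lump = spectral_lump(msm, 2)
        assert lump.micro_to_macro[0] == lump.micro_to_macro[1]
        assert lump.micro_to_macro[2] == lump.micro_to_macro[3]
        assert lump.micro_to_macro[0] != lump.micro_to_macro[2]

    def test_ground_truth_macrostates_recovered(self, ago_chain):
        lab = simulate_chain(ago_chain, 8, 20000, seed=31)
        C = count_transitions(lab, ago_chain.lag_unit, ago_chain.n_micro)
        msm = estimate_T(C, lag=ago_chain.lag_unit)
        lump = spectral_lump(msm, 7, seed=0)
        truth = ago_chain.macro_of_micro[msm.active]
        # mapping equals ground truth up to relabeling
        pairs = set(zip(lump.micro_to_macro.tolist(), truth.tolist()))
        assert len(pairs) == 7

    def test_single_macrostate(self, two_state_msm):
        lump = spectral_lump(two_state_msm, 1)
        assert np.all(lump.micro_to_macro == 0)
        assert lump.populations == pytest.approx([1.0])

    def test_label_equivariance_under_permutation(self, ago_chain):
        lab = simulate_chain(ago_chain, 8, 20000, seed=31)
        C = count_transitions(lab, ago_chain.lag_unit, ago_chain.n_micro)
        msm = estimate_T(C, lag=ago_chain.lag_unit)
        lump = spectral_lump(msm, 7, seed=0)
        rng = np.random.default_rng(2)
        perm = rng.permutation(msm.n_states)
        from agomsm.msm import MicrostateMSM
        msm_p = MicrostateMSM(T=msm.T[np.ix_(perm, perm)],
                              C=msm.C[np.ix_(perm, perm)], lag=msm.lag,
                              pi=msm.pi[perm], active=np.arange(msm.n_states))
        lump_p = spectral_lump(msm_p, 7, seed=0)
        pairs = set(zip(lump_p.micro_to_macro.tolist(),
                        lump.micro_to_macro[perm].tolist()))
        assert len(pairs) == 7


class TestGapRule:
    def test_clear_gap_detected(self):
        assert choose_n_macro(np.array([900, 700, 500, 380, 150, 120, 20, 19])
                              ) == 7

    def test_two_state_gap(self):
        assert choose_n_macro(np.array([500.0, 5.0, 4.0])) == 2


class TestApmIterate:
    def test_converged_decomposition_is_fixed_point(self, ago_features):
        cfg = APMConfig(t0=400.0, lag=200.0, seed=2, n_macro=7)
        assign, msm, mapping = apm_iterate(ago_features, cfg)
        # one more split+lump round must leave the macro partition alone
        from agomsm.msm import _full_mapping, apm_split
        macro_frames = mapping.map_labels(assign.flat())
        init = macro_frames.copy()
        init[init < 0] = init.max() + 1
        assign2 = apm_split(ago_features, cfg.t0, seed=123, init_labels=init,
                            min_population=cfg.min_population)
        C2 = count_transitions(assign2.labels, cfg.lag, assign2.n_states)
        msm2 = estimate_T(C2, lag=cfg.lag)
        mapping2 = _full_mapping(msm2, 7, assign2.n_states, seed=7)
        macro2 = mapping2.map_labels(assign2.flat())
        agree = np.zeros(7, dtype=bool)
        for m in range(7):
            vals, counts = np.unique(macro2[macro_frames == m],
                                     return_counts=True)
            agree[m] = counts.max() / counts.sum() > 0.97
        assert agree.all()

    def test_macro_populations_recovered(self, ago_chain, ago_features):
        cfg = APMConfig(t0=400.0, lag=200.0, seed=2, n_macro=7)
        _, msm, mapping = apm_iterate(ago_features, cfg)
        est = np.sort(mapping.populations)[::-1]
        true = np.sort(ago_chain.macro_populations())[::-1]
        n_eff = ago_features.n_frames / (
            2 * ago_chain.implied_timescales_true[0] / ago_chain.lag_unit)
        se = np.sqrt(true * (1 - true) / n_eff)
        assert np.all(np.abs(est - true) <= 3 * se)

    def test_default_config_mirrors_reference_settings(self):
        cfg = APMConfig()
        assert cfg.t0 == 20.0
        assert cfg.lag == 20.0
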