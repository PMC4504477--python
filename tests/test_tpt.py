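"""MFPT, synthetic traces, transition times, committors and flux pathways."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agomsm import simulate_chain
from agomsm.msm import (MacrostateMapping, MicrostateMSM, count_transitions,
                        estimate_T, stationary_distribution)
from agomsm.tpt import (FluxNetwork, committors, flux_network,
                        greedy_backtracking_paths, lump_pathways,
                        mean_transition_times, mfpt_macro, mfpt_micro,
                        sample_msm_trajectory, macro_of_rows)
from conftest import mc_hitting_times


def _msm_from_T(T, lag=1.0):
    T = np.asarray(T, dtype=float)
    return MicrostateMSM(T=T, C=(T * 1000).astype(int), lag=lag,
                         pi=stationary_distribution(T),
                         active=np.arange(T.shape[0]))


def _random_connected_msm(n, seed, lag=1.0):
    rng = np.random.default_rng(seed)
    C = rng.integers(1, 50, size=(n, n))
    return estimate_T(C, lag=lag)


class TestMFPT:
    def test_two_state_escape_rate_closed_form(self, two_state_msm):
        # escape probability 0.1 per lag step -> MFPT = lag / 0.1
        res = mfpt_micro(two_state_msm, [1])
        assert res.mfpt[0] == pytest.approx(10.0, abs=1e-10)
        assert res.mfpt[1] == 0.0

    def test_start_inside_final_set_is_zero(self, two_state_msm):
        assert mfpt_micro(two_state_msm, [0, 1]).mfpt.max() == 0.0

    def test_monte_carlo_agreement(self):
        msm = _random_connected_msm(8, seed=10)
        res = mfpt_micro(msm, [7])
        hits = mc_hitting_times(msm.T, start=0, final_set=[7], n_rep=20000,
                                seed=11)
        se = hits.std(ddof=1) / np.sqrt(len(hits))
        assert abs(res.mfpt[0] - hits.mean()) <= 3 * se

    def test_macro_weighted_average(self):
        # doubly stochastic chain: uniform pi; initial microstates have
        # MFPTs 2 and 3 -> uniform-weighted macrostate MFPT 2.5
        T = np.array([[0.5, 0.0, 0.5],
                      [0.25, 0.5, 0.25],
                      [0.25, 0.5, 0.25]])
        msm = _msm_from_T(T)
        assert np.allclose(msm.pi, 1 / 3, atol=1e-10)
        res = mfpt_micro(msm, [2])
        assert res.mfpt[0] == pytest.approx(2.0, abs=1e-12)
        assert res.mfpt[1] == pytest.approx(3.0, abs=1e-12)
        mapping = MacrostateMapping(micro_to_macro=np.array([0, 0, 1]),
                                    n_macro=2,
                                    populations=np.array([2 / 3, 1 / 3]))
        assert mfpt_macro(msm, mapping, 0, 1) == pytest.approx(2.5,
                                                               abs=1e-12)

    def test_single_micro_macrostates_reduce_to_micro(self, two_state_msm):
        mapping = MacrostateMapping(micro_to_macro=np.array([0, 1]),
                                    n_macro=2,
                                    populations=two_state_msm.pi)
        assert mfpt_macro(two_state_msm, mapping, 0, 1) == pytest.approx(
            mfpt_micro(two_state_msm, [1]).mfpt[0])

    def test_macro_mfpt_matches_hitting_time(self, ago_chain):
        lab = simulate_chain(ago_chain, 6, 20000, seed=51)
        C = count_transitions(lab, ago_chain.lag_unit, ago_chain.n_micro)
        msm = estimate_T(C, lag=ago_chain.lag_unit)
        mapping = MacrostateMapping(
            micro_to_macro=ago_chain.macro_of_micro[msm.active],
            n_macro=7,
            populations=np.bincount(ago_chain.macro_of_micro[msm.active],
                                    weights=msm.pi, minlength=7))
        val = mfpt_macro(msm, mapping, 6, 5)
        # Monte-Carlo from pi-weighted starts inside macro 6
        rows = macro_of_rows(msm, mapping)
        init = np.flatnonzero(rows == 6)
        final = np.flatnonzero(rows == 5)
        rng = np.random.default_rng(52)
        w = msm.pi[init] / msm.pi[init].sum()
        all_hits = []
        for i, wi in zip(init, w):
            hits = mc_hitting_times(msm.T, start=int(i), final_set=final,
                                    n_rep=int(round(6000 * wi)) + 100,
                                    seed=int(rng.integers(2 ** 31)))
            all_hits.append((hits, wi))
        mc_mean = sum(h.mean() * wi for h, wi in all_hits) * msm.lag
        mc_se = np.sqrt(sum((h.std(ddof=1) * wi) ** 2 / len(h)
                            for h, wi in all_hits)) * msm.lag
        assert abs(val - mc_mean) <= 3 * mc_se


class TestSampling:
    def test_identity_matrix_gives_constant_trace(self):
        msm = MicrostateMSM(T=np.eye(3), C=np.eye(3, dtype=int), lag=1.0,
                            pi=np.full(3, 1 / 3), active=np.arange(3))
        tr = sample_msm_trajectory(msm, start=2, n_steps=100, seed=0)
        assert np.all(tr.micro == 2)

    def test_long_trace_frequencies_match_pi(self, two_state_msm):
        n = 200_000
        tr = sample_msm_trajectory(two_state_msm, start=0, n_steps=n, seed=1)
        frac = np.mean(tr.micro == 0)
        # effective samples reduced by the relaxation time
        n_eff = n / (2 * two_state_msm.timescales(1)[0])
        se = np.sqrt(two_state_msm.pi[0] * two_state_msm.pi[1] / n_eff)
        assert abs(frac - two_state_msm.pi[0]) <= 3 * se

    def test_invalid_start_rejected(self, two_state_msm):
        with pytest.raises(ValueError):
            sample_msm_trajectory(two_state_msm, start=5, n_steps=10)


class TestTransitionTimes:
    def test_alternating_trace_gives_one_lag(self):
        from agomsm.tpt import SyntheticTrace
        tr = SyntheticTrace(micro=np.array([0, 1] * 20),
                            macro=np.array([0, 1] * 20), dt=2.5)
        mean, n = mean_transition_times([tr], [0], [1])
        assert mean == pytest.approx(2.5)
        assert n == 20

    def test_no_event_flagged_not_zero(self):
        from agomsm.tpt import SyntheticTrace
        tr = SyntheticTrace(micro=np.zeros(10, dtype=int),
                            macro=np.zeros(10, dtype=int), dt=1.0)
        with pytest.warns(RuntimeWarning):
            mean, n = mean_transition_times([tr], [0], [1])
        assert np.isnan(mean) and n == 0

    def test_trace_estimate_consistent_with_mfpt(self, two_state_msm):
        traces = [sample_msm_trajectory(two_state_msm, start=0,
                                        n_steps=100_000, seed=s)
                  for s in range(3)]
        for t in traces:
            t.macro = t.micro
        mean, n = mean_transition_times(traces, [0], [1],
                                        convention="first_entry")
        # from entering state 0, reaching state 1 needs Geom(0.1) steps,
        # i.e. exactly the MFPT of the two-state chain
        expected = two_state_msm.lag / 0.1
        se = expected / np.sqrt(n)  # geometric sd ~ mean
        assert abs(mean - expected) <= 3 * se


class TestCommittors:
    def test_symmetric_intermediate_is_half(self):
        T = np.array([[0.9, 0.1, 0.0],
                      [0.05, 0.9, 0.05],
                      [0.0, 0.1, 0.9]])
        msm = _msm_from_T(T)
        qp, qm = committors(msm, [0], [2])
        assert qp[1] == pytest.approx(0.5, abs=1e-12)

    def test_boundary_conditions_exact(self):
        msm = _random_connected_msm(9, seed=20)
        qp, qm = committors(msm, [0, 1], [7, 8])
        assert np.all(qp[[0, 1]] == 0.0)
        assert np.all(qp[[7, 8]] == 1.0)
        assert np.all(qm[[0, 1]] == 1.0)
        assert np.all(qm[[7, 8]] == 0.0)

    def test_detailed_balance_gives_complementary_committors(self):
        C = np.array([[50, 10, 1, 1], [10, 60, 10, 1],
                      [1, 10, 70, 10], [1, 1, 10, 80]])
        msm = estimate_T(C + C.T, mode="symmetrized")
        qp, qm = committors(msm, [0], [3])
        assert np.allclose(qm, 1 - qp, atol=1e-10)

    def test_monte_carlo_hitting_probability(self):
        msm = _random_connected_msm(6, seed=21)
        qp, _ = committors(msm, [0], [5])
        # empirical probability of reaching 5 before 0 from state 2
        rng = np.random.default_rng(22)
        cum = np.cumsum(msm.T, axis=1)
        n_rep = 20000
        wins = 0
        state = np.full(n_rep, 2)
        alive = np.ones(n_rep, dtype=bool)
        for _ in range(10000):
            if not alive.any():
                break
            r = rng.random(alive.sum())
            nxt = (cum[state[alive]] > r[:, None]).argmax(axis=1)
            state[alive] = nxt
            idx = np.flatnonzero(alive)
            wins += int((nxt == 5).sum())
            alive[idx[(nxt == 0) | (nxt == 5)]] = False
        p = wins / n_rep
        se = np.sqrt(p * (1 - p) / n_rep)
        assert abs(qp[2] - p) <= 3 * se


class TestFlux:
    def test_conservation_at_intermediates(self):
        for seed in range(5):
            msm = _random_connected_msm(7, seed=seed)
            net = flux_network(msm, [0], [6])
            inter = range(1, 6)
            for i in inter:
                influx = net.net[:, i].sum()
                outflux = net.net[i, :].sum()
                assert influx == pytest.approx(outflux, abs=1e-10)

    def test_single_path_chain_total_equals_edge_flux(self):
        T = np.array([[0.8, 0.2, 0.0],
                      [0.1, 0.8, 0.1],
                      [0.0, 0.2, 0.8]])
        msm = _msm_from_T(T)
        net = flux_network(msm, [0], [2])
        hand = msm.pi[1] * net.q_minus[1] * T[1, 2] * net.q_plus[2] \
            - msm.pi[2] * net.q_minus[2] * T[2, 1] * net.q_plus[1]
        assert net.total == pytest.approx(hand, abs=1e-12)

    def test_blocked_cut_gives_zero_flux(self):
        T = np.array([[0.9, 0.1, 0.0],
                      [0.1, 0.9, 0.0],
                      [0.0, 0.0, 1.0]])
        msm = MicrostateMSM(T=T, C=(T * 100).astype(int), lag=1.0,
                            pi=np.array([0.25, 0.25, 0.5]),
                            active=np.arange(3))
        net = flux_network(msm, [0], [2])
        assert net.total == pytest.approx(0.0, abs=1e-12)
        assert greedy_backtracking_paths(net) == []


class TestGreedyBacktracking:
    def _two_parallel_network(self):
        net = np.zeros((4, 4))
        net[0, 1] = net[1, 3] = 0.3
        net[0, 2] = net[2, 3] = 0.1
        return FluxNetwork(q_plus=np.zeros(4), q_minus=np.zeros(4),
                           gross=net.copy(), net=net, total=0.4,
                           source=np.array([0]), sink=np.array([3]))

    def test_parallel_paths_ranked_by_bottleneck(self):
        paths = greedy_backtracking_paths(self._two_parallel_network())
        assert [p.states for p in paths] == [(0, 1, 3), (0, 2, 3)]
        assert paths[0].flux == pytest.approx(0.3)
        assert paths[1].flux == pytest.approx(0.1)

    def test_single_chain_carries_all_flux(self):
        net = np.zeros((3, 3))
        net[0, 1] = net[1, 2] = 0.25
        fn = FluxNetwork(q_plus=np.zeros(3), q_minus=np.zeros(3),
                         gross=net.copy(), net=net, total=0.25,
                         source=np.array([0]), sink=np.array([2]))
        paths = greedy_backtracking_paths(fn)
        assert len(paths) == 1
        assert paths[0].fraction == pytest.approx(1.0)

    @given(seed=st.integers(0, 300))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_property_path_fluxes_sum_to_total(self, seed):
        msm = _random_connected_msm(6, seed=seed)
        net = flux_network(msm, [0], [5])
        paths = greedy_backtracking_paths(net)
        assert sum(p.flux for p in paths) == pytest.approx(net.total,
                                                           abs=1e-9)


class TestLumpPathways:
    def test_merge_and_flux_conservation(self, ago_chain):
        lab = simulate_chain(ago_chain, 6, 20000, seed=61)
        C = count_transitions(lab, ago_chain.lag_unit, ago_chain.n_micro)
        msm = estimate_T(C, lag=ago_chain.lag_unit)
        mapping = MacrostateMapping(
            micro_to_macro=ago_chain.macro_of_micro[msm.active],
            n_macro=7,
            populations=np.bincount(ago_chain.macro_of_micro[msm.active],
                                    weights=msm.pi, minlength=7))
        rows = macro_of_rows(msm, mapping)
        src = np.flatnonzero(rows == 0)  # a closed macrostate
        snk = np.flatnonzero(rows == 6)  # the open macrostate
        net = flux_network(msm, src, snk)
        micro_paths = greedy_backtracking_paths(net, max_paths=200)
        macro_paths = lump_pathways(micro_paths, msm, mapping)
        assert len(macro_paths) <= len(micro_paths)
        assert sum(p.flux for p in macro_paths) == pytest.approx(
            sum(p.flux for p in micro_paths), abs=1e-12)
        # every macro pathway starts at the source and ends at the sink
        for p in macro_paths:
            assert p.states[0] == 0 and p.states[-1] == 6
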