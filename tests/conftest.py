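import numpy as np
import pytest

from agomsm import (TrajectoryEnsemble, ago_like_chain, ago_like_emission,
                    emit_features, estimate_T, simulate_chain,
                    synthetic_crystal_analog)


@pytest.fixture(scope="session")
def two_state_msm():
    """The 2-state chain T = [[0.9, 0.1], [0.2, 0.8]] at unit lag."""
    return estimate_T(np.array([[9, 1], [2, 8]]), lag=1.0)


@pytest.fixture(scope="session")
def ago_chain():
    return ago_like_chain(0)


@pytest.fixture(scope="session")
def ago_labels(ago_chain):
    """Moderate-size label dataset from the Ago-like chain."""
    return simulate_chain(ago_chain, n_traj=8, n_steps=20000, seed=11)


@pytest.fixture(scope="session")
def ago_features(ago_chain, ago_labels):
    emission = ago_like_emission(ago_chain, seed=12)
    return emit_features(ago_labels, emission, seed=13)


@pytest.fixture(scope="session")
def crystal_analog():
    return synthetic_crystal_analog(0)


def mc_hitting_times(T, start, final_set, n_rep, seed, max_steps=100000):
    """Monte-Carlo first-hitting times (in steps) via parallel walkers."""
    rng = np.random.default_rng(seed)
    T = np.asarray(T, dtype=float)
    cum = np.cumsum(T, axis=1)
    final = np.zeros(T.shape[0], dtype=bool)
    final[np.asarray(final_set, dtype=int)] = True
    state = np.full(n_rep, start, dtype=np.int64)
    hit = np.full(n_rep, -1, dtype=np.int64)
    alive = ~final[state]
    hit[~alive] = 0
    for step in range(1, max_steps + 1):
        if not alive.any():
            break
        r = rng.random(alive.sum())
        nxt = (cum[state[alive]] > r[:, None]).argmax(axis=1)
        state[alive] = nxt
        arrived = final[nxt]
        idx = np.flatnonzero(alive)
        hit[idx[arrived]] = step
        alive[idx[arrived]] = False
    if (hit < 0).any():
        raise RuntimeError("walkers did not all reach the final set")
    return hit


@pytest.fixture
def simple_coords_ensemble():
    """Tiny 3-atom coordinate ensemble for featurization tests."""
    ref = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [0.0, 4.0, 0.0]])
    frames = np.stack([ref, ref + 0.1, ref - 0.05])
    return ref, TrajectoryEnsemble([frames], dt=1.0)
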