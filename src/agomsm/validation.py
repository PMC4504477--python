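"""Model-quality checks: implied timescales, residence-probability tests,
split-half cross-validation and trajectory bootstrap.

The residence test compares, for a chosen state, the probability of still
being found in that state after time ``t`` as counted from the
trajectories (the complement of the pair-counting escape probability)
with the MSM return probability ``[T^n]_ii``.  A Markovian decomposition
passes; a lumping that hides internal barriers shows the classic failure
signature of the MSM curve decaying faster than the counted one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ensembles import TrajectoryEnsemble
from .msm import (MicrostateMSM, _steps, count_transitions, escape_profile,
                  estimate_T)

__all__ = [
    "ImpliedTimescaleResult", "ResidenceTestResult", "SplitHalfResult",
    "BootstrapResult", "implied_timescales", "residence_test",
    "split_half_cv", "bootstrap",
]


@dataclass
class ImpliedTimescaleResult:
    """Implied timescales τ_t = -τ/ln λ_k on a grid of lag times.

    ``timescales[i, k]`` is the (k+1)-th slowest timescale at ``lags[i]``
    (ns); NaN rows mark lags where estimation failed (e.g. loss of
    connectivity), ``complex_flagged`` marks lags with complex eigenvalue
    pairs (reported by modulus).
    """

    lags: np.ndarray
    eigenvalues: np.ndarray
    timescales: np.ndarray
    failed: np.ndarray
    complex_flagged: np.ndarray

    def slowest(self) -> np.ndarray:
        return self.timescales[:, 0]


def implied_timescales(labels: TrajectoryEnsemble, lag_grid, k: int = 10,
                       n_states: int | None = None,
                       estimator: str = "nonreversible") -> ImpliedTimescaleResult:
    """Re-count and re-estimate the MSM at every lag and apply
    τ_t = -τ/ln λ_k to the k largest non-unit eigenvalue moduli."""
    if n_states is None:
        n_states = int(max(s.max() for s in labels)) + 1
    lag_grid = np.asarray(lag_grid, dtype=float)
    n_lag = len(lag_grid)
    eig = np.full((n_lag, k), np.nan, dtype=complex)
    ts = np.full((n_lag, k), np.nan)
    failed = np.zeros(n_lag, dtype=bool)
    cflag = np.zeros(n_lag, dtype=bool)
    for i, lag in enumerate(lag_grid):
        _steps(lag, labels.dt)  # validates multiples early
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                C = count_transitions(labels, lag, n_states)
                msm = estimate_T(C, lag=lag, mode=estimator)
        except ValueError:
            failed[i] = True
            continue
        lam = msm.eigenvalues()[1:k + 1]
        m = len(lam)
        eig[i, :m] = lam
        if np.any(np.abs(np.imag(lam)) > 1e-10):
            cflag[i] = True
        mod = np.abs(lam)
        with np.errstate(divide="ignore"):
            t = np.where(mod >= 1.0 - 1e-12, np.inf, -lag / np.log(mod))
        t[mod <= 0] = 0.0
        ts[i, :m] = t
    return ImpliedTimescaleResult(lags=lag_grid, eigenvalues=eig,
                                  timescales=ts, failed=failed,
                                  complex_flagged=cflag)


@dataclass
class ResidenceTestResult:
    """Counted vs MSM-predicted stay probability for one state."""

    state: int
    times: np.ndarray
    p_counted: np.ndarray
    p_msm: np.ndarray
    se: np.ndarray
    fraction_within: float
    msm_faster: bool

    @property
    def passed(self) -> bool:
        return self.fraction_within >= 0.95


def residence_test(msm: MicrostateMSM, labels: TrajectoryEnsemble,
                   state: int, n_points: int = 10) -> ResidenceTestResult:
    """Residence-probability test on the grid ``t = 0, τ, ..., n_points τ``.

    The counted curve is the complement of the pair-counting escape
    probability; the MSM curve is the return probability ``[T^n]_ii``.
    The standard error of the counted curve uses an effective start count
    of ``starts / m`` (windows of length ``m`` saving intervals overlap
    ``m`` sliding starts).
    """
    rows = np.flatnonzero(msm.active == state)
    if len(rows) == 0:
        raise ValueError(f"state {state} is not in the connected set")
    row = int(rows[0])
    m_lag = _steps(msm.lag, labels.dt)
    n_states = int(max(s.max() for s in labels)) + 1
    max_steps = n_points * m_lag
    if max_steps >= int(labels.lengths.min()):
        n_points = (int(labels.lengths.min()) - 1) // m_lag
        max_steps = n_points * m_lag
        warnings.warn("residence grid shortened to fit trajectory span",
                      RuntimeWarning)
    P, starts = escape_profile(labels, n_states, max_steps)

    times = np.arange(n_points + 1) * msm.lag
    p_cnt = np.empty(n_points + 1)
    se = np.zeros(n_points + 1)
    p_msm = np.empty(n_points + 1)
    Tn = np.eye(msm.n_states)
    for n in range(n_points + 1):
        m = n * m_lag
        p = 1.0 - P[state, m]
        p_cnt[n] = p
        if n > 0:
            n_eff = max(1.0, starts[state, m] / m)
            se[n] = np.sqrt(max(p * (1 - p), 1e-12) / n_eff)
        p_msm[n] = Tn[row, row]
        Tn = Tn @ msm.T
    diff = p_msm - p_cnt
    within = np.abs(diff) <= 3 * np.maximum(se, 1e-12)
    within[0] = np.isclose(p_msm[0], 1.0) and np.isclose(p_cnt[0], 1.0)
    # systematic fast bias: significantly-fast points dominate
    n_fast = int(np.count_nonzero(diff[1:] < -3 * se[1:]))
    n_slow = int(np.count_nonzero(diff[1:] > 3 * se[1:]))
    faster = n_fast >= max(3, 0.2 * n_points) and n_fast > 2 * n_slow
    return ResidenceTestResult(state=state, times=times, p_counted=p_cnt,
                               p_msm=p_msm, se=se,
                               fraction_within=float(within.mean()),
                               msm_faster=bool(faster))


@dataclass
class SplitHalfResult:
    """Paired estimates from two disjoint halves of the dataset."""

    estimate_a: float
    estimate_b: float
    ratio: float
    flagged: bool

    @property
    def consistent(self) -> bool:
        return not self.flagged and 0.5 <= self.ratio <= 2.0


def split_half_cv(ens: TrajectoryEnsemble, statistic, partition=None
                  ) -> SplitHalfResult:
    """Run ``statistic`` on two disjoint halves of the trajectory set.

    ``statistic`` maps a :class:`TrajectoryEnsemble` to a scalar (e.g. an
    MFPT through the full pipeline).  Trajectories are split even/odd by
    index unless an explicit ``partition=(idx_a, idx_b)`` is given.  A
    half on which the statistic fails (e.g. loss of connectivity) flags
    the result instead of fabricating a number.
    """
    if ens.n_trajectories < 2:
        raise ValueError("split-half needs at least two trajectories")
    if partition is None:
        idx = np.arange(ens.n_trajectories)
        partition = (idx[::2], idx[1::2])
    a, b = partition
    try:
        est_a = float(statistic(ens.subset(a)))
        est_b = float(statistic(ens.subset(b)))
    except (ValueError, np.linalg.LinAlgError) as err:
        warnings.warn(f"split-half statistic failed on a half: {err}",
                      RuntimeWarning)
        return SplitHalfResult(np.nan, np.nan, np.nan, flagged=True)
    ratio = est_a / est_b if est_b != 0 else np.inf
    return SplitHalfResult(est_a, est_b, ratio, flagged=False)


@dataclass
class BootstrapResult:
    """Trajectory-bootstrap mean and spread of a statistic."""

    mean: float
    std: float
    values: np.ndarray
    n_failed: int


def bootstrap(ens: TrajectoryEnsemble, statistic, n_boot: int | None = None,
              seed: int = 0) -> BootstrapResult:
    """Resample whole trajectories with replacement (N draws per replicate,
    N = trajectory count) and report the spread of ``statistic``.

    ``n_boot`` defaults to the trajectory count, the N-for-N convention.
    Replicates on which the statistic fails are dropped and counted.
    """
    N = ens.n_trajectories
    if n_boot is None:
        n_boot = N
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    rng = np.random.default_rng(seed)
    vals, failed = [], 0
    for _ in range(n_boot):
        draw = rng.integers(N, size=N)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vals.append(float(statistic(ens.subset(draw))))
        except (ValueError, np.linalg.LinAlgError):
            failed += 1
    if len(vals) < 2:
        raise ValueError("too few successful bootstrap replicates")
    vals = np.array(vals)
    return BootstrapResult(mean=float(vals.mean()),
                           std=float(vals.std(ddof=1)),
                           values=vals, n_failed=failed)
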