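"""APM state decomposition and Markov-state-model estimation.

The decomposition follows the residence-time-bounded scheme: (1) split
conformations geometrically with greedy K-centers, (2) keep splitting any
microstate whose lifetime — the time at which its escape probability
reaches 1 - 1/e — meets or exceeds the residence threshold ``t0``,
(3) lump kinetically related microstates into macrostates by spectral
clustering of the transition matrix, and (4) iterate re-splitting within
macrostates and re-lumping until the macrostate mapping is stable.

Escape probabilities are pair counts over all sliding-window frame pairs
``(k s, k s + t)`` within each trajectory: ``P(i, t)`` is one minus the
fraction of pairs that start and end in state ``i`` among those starting
in ``i``.  Transition counting uses the same sliding-window convention by
default (a strided variant is available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .ensembles import TrajectoryEnsemble

ESCAPE_THRESHOLD = 1.0 - 1.0 / np.e  # lifetime definition P(i, t_i) = 1 - 1/e

__all__ = [
    "APMConfig", "MicrostateAssignment", "MicrostateMSM", "MacrostateMapping",
    "kcenters", "escape_probability", "escape_profile", "lifetime",
    "lifetimes", "apm_split", "count_transitions", "estimate_T", "propagate",
    "spectral_lump", "choose_n_macro", "apm_iterate",
]


@dataclass
class APMConfig:
    """Configuration of the APM decomposition.

    Times are in nanoseconds.  ``t0`` is the maximum allowed microstate
    residence time; ``lag`` the MSM lag time.  ``n_macro=None`` selects
    the macrostate count at the largest implied-timescale gap.
    """

    t0: float = 20.0
    lag: float = 20.0
    n_macro: int | None = None
    max_iter: int = 10
    seed: int = 0
    min_population: int = 10
    estimator: str = "nonreversible"
    max_states: int = 500
    its_rank: int = 10

    def __post_init__(self) -> None:
        if self.t0 <= 0 or self.lag <= 0:
            raise ValueError("t0 and lag must be positive")


@dataclass
class MicrostateAssignment:
    """Per-frame microstate labels plus floor-flagged state ids."""

    labels: TrajectoryEnsemble
    n_states: int
    floor_flagged: frozenset = frozenset()

    def populations(self) -> np.ndarray:
        return np.bincount(self.labels.concatenated(), minlength=self.n_states)

    def flat(self) -> np.ndarray:
        return self.labels.concatenated()


@dataclass
class MicrostateMSM:
    """Estimated microstate MSM restricted to its largest connected set.

    ``active`` maps the rows of ``T`` back to the microstate ids of the
    assignment the count matrix was built from.
    """

    T: np.ndarray
    C: np.ndarray
    lag: float
    pi: np.ndarray
    active: np.ndarray
    connected: bool = True

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if not np.allclose(self.T.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(self.pi < -1e-12) or abs(self.pi.sum() - 1.0) > 1e-10:
            raise ValueError("invalid stationary distribution")
        if not np.allclose(self.pi @ self.T, self.pi, atol=1e-8):
            raise ValueError("pi is not stationary within 1e-8")

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    def eigenvalues(self, k: int | None = None) -> np.ndarray:
        lam = np.linalg.eigvals(self.T)
        lam = lam[np.argsort(-np.abs(lam))]
        return lam if k is None else lam[:k]

    def timescales(self, k: int | None = None) -> np.ndarray:
        """Implied timescales -lag/ln|λ| of the non-unit eigenvalues."""
        lam = np.abs(self.eigenvalues())[1:]
        if k is not None:
            lam = lam[:k]
        out = np.full(lam.shape, np.inf)
        ok = (lam > 0) & (lam < 1.0 - 1e-12)
        out[ok] = -self.lag / np.log(lam[ok])
        out[lam <= 0] = 0.0
        return out


@dataclass
class MacrostateMapping:
    """Surjective microstate-to-macrostate map with aggregated populations.

    ``micro_to_macro`` is indexed by assignment microstate id; entries of
    ``-1`` mark microstates outside the connected set of the MSM.
    """

    micro_to_macro: np.ndarray
    n_macro: int
    populations: np.ndarray

    def __post_init__(self) -> None:
        self.micro_to_macro = np.asarray(self.micro_to_macro, dtype=int)
        active = self.micro_to_macro[self.micro_to_macro >= 0]
        if len(np.unique(active)) != self.n_macro:
            raise ValueError("mapping is not surjective onto macrostates")
        if abs(self.populations.sum() - 1.0) > 1e-8:
            raise ValueError("macrostate populations must sum to 1")

    def members(self, macro: int) -> np.ndarray:
        return np.flatnonzero(self.micro_to_macro == macro)

    def map_labels(self, labels: np.ndarray) -> np.ndarray:
        return self.micro_to_macro[labels]


# ---------------------------------------------------------------------------
# geometric clustering
# ---------------------------------------------------------------------------

def kcenters(features: np.ndarray, k: int, seed: int = 0):
    """Greedy max-min K-centers clustering.

    The first center is a frame drawn from the seeded RNG; every further
    center is the frame farthest from its nearest existing center (ties
    broken toward the lowest frame index).  Returns ``(labels,
    center_indices, covering_radius)``.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if k < 1 or k > n:
        raise ValueError("need 1 <= k <= n_frames")
    rng = np.random.default_rng(seed)
    centers = [int(rng.integers(n))]
    d = np.linalg.norm(X - X[centers[0]], axis=1)
    labels = np.zeros(n, dtype=np.int64)
    for j in range(1, k):
        c = int(np.argmax(d))
        centers.append(c)
        dc = np.linalg.norm(X - X[c], axis=1)
        closer = dc < d
        d[closer] = dc[closer]
        labels[closer] = j
    return labels, np.array(centers), float(d.max())


# ---------------------------------------------------------------------------
# residence statistics
# ---------------------------------------------------------------------------

def _steps(t: float, dt: float) -> int:
    m = t / dt
    if abs(m - round(m)) > 1e-9:
        raise ValueError(f"time {t} is not a multiple of the saving interval {dt}")
    return int(round(m))


def escape_profile(labels: TrajectoryEnsemble, n_states: int,
                   max_steps: int) -> tuple[np.ndarray, np.ndarray]:
    """Escape probabilities for all states on the grid ``t = 0..max_steps``.

    Returns ``(P, starts)`` where ``P[i, m]`` is the escape probability of
    state ``i`` after ``m`` saving intervals and ``starts[i, m]`` the
    number of sliding-window start frames the estimate is based on.
    ``P`` is NaN where a state has no valid start frame.
    """
    if max_steps < 0:
        raise ValueError("max_steps must be non-negative")
    if max_steps >= int(labels.lengths.min()):
        raise ValueError("max_steps exceeds the shortest trajectory span")
    P = np.zeros((n_states, max_steps + 1))
    starts = np.zeros((n_states, max_steps + 1), dtype=np.int64)
    starts[:, 0] = np.bincount(labels.concatenated(), minlength=n_states)
    for m in range(1, max_steps + 1):
        num = np.zeros(n_states, dtype=np.int64)
        den = np.zeros(n_states, dtype=np.int64)
        for s in labels:
            a, b = s[:-m], s[m:]
            den += np.bincount(a, minlength=n_states)
            same = a == b
            if same.any():
                num += np.bincount(a[same], minlength=n_states)
        starts[:, m] = den
        with np.errstate(invalid="ignore", divide="ignore"):
            P[:, m] = 1.0 - num / den
        P[den == 0, m] = np.nan
    return P, starts


def escape_probability(labels: TrajectoryEnsemble, state: int, t: float,
                       n_states: int | None = None) -> float:
    """Escape probability of one state after time ``t`` (pair counting)."""
    if n_states is None:
        n_states = int(max(s.max() for s in labels)) + 1
    m = _steps(t, labels.dt)
    P, _ = escape_profile(labels, n_states, m)
    val = P[state, m]
    if np.isnan(val):
        raise ValueError(f"state {state} never observed at valid start times")
    return float(val)


def _lifetime_from_profile(P_row: np.ndarray, dt: float) -> float:
    """First crossing of the 1 - 1/e threshold, linearly interpolated."""
    thr = ESCAPE_THRESHOLD
    finite = np.nan_to_num(P_row, nan=-1.0)
    above = np.flatnonzero(finite >= thr)
    if len(above) == 0:
        return np.inf
    k = int(above[0])
    if k == 0:
        return 0.0
    p0, p1 = finite[k - 1], finite[k]
    if p1 <= p0:
        return k * dt
    frac = (thr - p0) / (p1 - p0)
    return (k - 1 + frac) * dt


def lifetimes(labels: TrajectoryEnsemble, n_states: int,
              t_max: float) -> np.ndarray:
    """Residence lifetimes of all states; ``inf`` where the escape
    probability never reaches 1 - 1/e within ``t_max``."""
    m = _steps(t_max, labels.dt)
    if m < 1:
        raise ValueError("t_max must cover at least one saving interval")
    P, _ = escape_profile(labels, n_states, m)
    return np.array([_lifetime_from_profile(P[i], labels.dt)
                     for i in range(n_states)])


def lifetime(labels: TrajectoryEnsemble, state: int, t_max: float,
             n_states: int | None = None) -> float:
    if n_states is None:
        n_states = int(max(s.max() for s in labels)) + 1
    return float(lifetimes(labels, n_states, t_max)[state])


# ---------------------------------------------------------------------------
# residence-time-bounded splitting
# ---------------------------------------------------------------------------

def _compact_labels(flat: np.ndarray) -> tuple[np.ndarray, int]:
    uniq, inv = np.unique(flat, return_inverse=True)
    return inv.astype(np.int64), len(uniq)


def apm_split(features: TrajectoryEnsemble, t0: float, seed: int = 0, *,
              init_labels: np.ndarray | None = None,
              min_population: int = 10,
              max_states: int = 500,
              max_rounds: int = 60) -> MicrostateAssignment:
    """Recursive binary K-centers splitting bounded by residence time.

    Any state whose lifetime is ``>= t0`` is split in two (K-centers on
    its own frames) until all states relax below ``t0`` or hit the
    minimum-population floor, in which case they are flagged rather than
    split.  ``init_labels`` seeds the decomposition (e.g. one label per
    current macrostate during APM iteration); by default the whole
    dataset starts as a single state.
    """
    if features.is_discrete:
        raise ValueError("apm_split expects continuous features")
    dt = features.dt
    if t0 <= dt:
        raise ValueError("t0 must exceed the saving interval")
    X = features.concatenated()
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if init_labels is None:
        flat = np.zeros(n, dtype=np.int64)
    else:
        flat = np.asarray(init_labels, dtype=np.int64).copy()
        if flat.shape != (n,):
            raise ValueError("init_labels must have one entry per frame")
    flat, n_states = _compact_labels(flat)
    rng = np.random.default_rng(seed)
    m0 = min(_steps(t0, dt), int(features.lengths.min()) - 1)
    flagged: set[int] = set()
    force_first = init_labels is None  # step (1): always split once

    for _ in range(max_rounds):
        ens = TrajectoryEnsemble(
            [lab for lab in _relabel_series(features, flat)], dt=dt)
        life = lifetimes(ens, n_states, m0 * dt)
        pops = np.bincount(flat, minlength=n_states)
        to_split = []
        for i in range(n_states):
            if i in flagged:
                continue
            needs = life[i] >= t0 or (force_first and n_states == 1)
            if not needs:
                continue
            if pops[i] < 2 * min_population or n_states >= max_states:
                flagged.add(i)
                continue
            to_split.append(i)
        force_first = False
        if not to_split:
            break
        for i in to_split:
            idx = np.flatnonzero(flat == i)
            sub, _, _ = kcenters(X[idx], 2, seed=int(rng.integers(2 ** 31)))
            if sub.max() == 0:  # all frames identical: nothing to split
                flagged.add(i)
                continue
            flat[idx[sub == 1]] = n_states
            if len(idx[sub == 1]) < min_population:
                flagged.add(n_states)
            if len(idx) - (sub == 1).sum() < min_population:
                flagged.add(i)
            n_states += 1
    else:
        warnings.warn("apm_split reached max_rounds before all states "
                      "relaxed below t0", RuntimeWarning)

    flat, n_states = _compact_labels(flat)
    labels = TrajectoryEnsemble(list(_relabel_series(features, flat)), dt=dt,
                                meta=dict(features.meta))
    # recompute flagged ids on the compacted labelling
    life = lifetimes(labels, n_states, m0 * dt)
    pops = np.bincount(flat, minlength=n_states)
    flag = frozenset(int(i) for i in range(n_states)
                     if life[i] >= t0 and pops[i] < 2 * min_population)
    return MicrostateAssignment(labels=labels, n_states=n_states,
                                floor_flagged=flag)


def _relabel_series(template: TrajectoryEnsemble, flat: np.ndarray):
    i = 0
    for n in template.lengths:
        yield flat[i:i + n]
        i += n


# ---------------------------------------------------------------------------
# counting and estimation
# ---------------------------------------------------------------------------

def count_transitions(labels: TrajectoryEnsemble, lag: float,
                      n_states: int | None = None,
                      mode: str = "sliding") -> np.ndarray:
    """Transition count matrix at the given lag time.

    ``mode='sliding'`` counts every frame pair ``(t, t + lag)`` within a
    trajectory; ``mode='strided'`` counts non-overlapping pairs only.
    """
    if n_states is None:
        n_states = int(max(s.max() for s in labels)) + 1
    m = _steps(lag, labels.dt)
    if m < 1:
        raise ValueError("lag must be at least one saving interval")
    if m >= int(labels.lengths.max()):
        raise ValueError("lag exceeds every trajectory span")
    C = np.zeros((n_states, n_states), dtype=np.int64)
    for s in labels:
        if m >= len(s):
            continue
        a, b = s[:-m], s[m:]
        if mode == "strided":
            a, b = a[::m], b[::m]
        elif mode != "sliding":
            raise ValueError("mode must be 'sliding' or 'strided'")
        np.add.at(C, (a, b), 1)
    if np.any(C.sum(axis=1) == 0):
        warnings.warn("count matrix has all-zero rows (unvisited start states)",
                      RuntimeWarning)
    return C


def _largest_scc(C: np.ndarray) -> np.ndarray:
    graph = csr_matrix((C > 0).astype(np.int8))
    n_comp, comp = connected_components(graph, directed=True,
                                        connection="strong")
    if n_comp == 1:
        return np.arange(C.shape[0])
    weight = np.bincount(comp, weights=C.sum(axis=1), minlength=n_comp)
    return np.flatnonzero(comp == int(np.argmax(weight)))


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Leading left eigenvector of a row-stochastic matrix, renormalized."""
    w, v = scipy.linalg.eig(T.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def estimate_T(C: np.ndarray, lag: float = 1.0,
               mode: str = "nonreversible") -> MicrostateMSM:
    """Maximum-likelihood transition matrix from a count matrix.

    ``mode='nonreversible'`` row-normalizes the counts; ``'symmetrized'``
    row-normalizes ``(C + C^T)/2``, which enforces detailed balance by
    construction.  Counts are first restricted to the largest strongly
    connected component; dropped states are reported via a warning.
    """
    C = np.asarray(C)
    active = _largest_scc(C)
    connected = len(active) == C.shape[0]
    if not connected:
        warnings.warn(f"restricting to largest connected set "
                      f"({len(active)}/{C.shape[0]} states)", RuntimeWarning)
    Csub = C[np.ix_(active, active)].astype(float)
    if mode == "symmetrized":
        Csub = 0.5 * (Csub + Csub.T)
    elif mode != "nonreversible":
        raise ValueError("mode must be 'nonreversible' or 'symmetrized'")
    rows = Csub.sum(axis=1)
    if np.any(rows == 0):
        raise ValueError("zero row in count matrix after trimming")
    T = Csub / rows[:, None]
    pi = stationary_distribution(T)
    return MicrostateMSM(T=T, C=C[np.ix_(active, active)], lag=lag, pi=pi,
                         active=active, connected=connected)


def propagate(msm: MicrostateMSM, p0: np.ndarray, n: int) -> np.ndarray:
    """Population vector after ``n`` lag steps, ``p(n τ) = p(0) T^n``."""
    p = np.asarray(p0, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative entries in p0")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("p0 must sum to 1")
    for _ in range(n):
        p = p @ msm.T
    return p


# ---------------------------------------------------------------------------
# kinetic lumping
# ---------------------------------------------------------------------------

def spectral_lump(msm: MicrostateMSM, n_macro: int, seed: int = 0, *,
                  imag_tol: float = 0.05) -> MacrostateMapping:
    """Lump microstates by spectral clustering of the transition matrix.

    Microstates are clustered with seeded multi-restart k-means on the
    rows of the top ``n_macro`` right eigenvectors, weighting samples by
    the stationary distribution.
    """
    from sklearn.cluster import KMeans

    if not 1 <= n_macro <= msm.n_states:
        raise ValueError("n_macro out of range")
    w, v = scipy.linalg.eig(msm.T)
    order = np.argsort(-np.abs(w))
    w, v = w[order], v[:, order]
    top_w, top_v = w[:n_macro], v[:, :n_macro]
    rel_imag = np.abs(np.imag(top_w)) / np.maximum(1e-12, np.abs(top_w))
    if np.any(rel_imag > imag_tol):
        raise ValueError("dominant eigenvalues are complex beyond tolerance; "
                         "kinetic lumping is not well defined")
    if np.any(rel_imag > 1e-8):
        warnings.warn("complex eigenvalue pair among dominant modes; "
                      "clustering on real parts", RuntimeWarning)
    psi = np.real(top_v)
    psi /= np.linalg.norm(psi, axis=0)
    if n_macro == 1:
        labels = np.zeros(msm.n_states, dtype=int)
    else:
        km = KMeans(n_clusters=n_macro, n_init=10, random_state=seed)
        labels = km.fit_predict(psi, sample_weight=msm.pi)
    # deterministic macro numbering: by descending population
    pops = np.bincount(labels, weights=msm.pi, minlength=n_macro)
    order = np.argsort(-pops, kind="stable")
    rank = np.empty(n_macro, dtype=int)
    rank[order] = np.arange(n_macro)
    labels = rank[labels]
    pops = pops[order]
    return MacrostateMapping(micro_to_macro=labels, n_macro=n_macro,
                             populations=pops)


def choose_n_macro(timescales: np.ndarray, max_macro: int = 12) -> int:
    """Macrostate count at the largest gap in the implied-timescale spectrum.

    A gap between the ``k``-th and ``(k+1)``-th slowest timescales means
    ``k`` slow relaxations, i.e. ``k + 1`` metastable states.
    """
    ts = np.asarray(timescales, dtype=float)
    ts = ts[np.isfinite(ts) & (ts > 0)]
    kmax = min(max_macro - 1, len(ts) - 1)
    if kmax < 1:
        return 2
    ratios = ts[:kmax] / ts[1:kmax + 1]
    return int(np.argmax(ratios)) + 2


def apm_iterate(features: TrajectoryEnsemble, config: APMConfig
                ) -> tuple[MicrostateAssignment, MicrostateMSM, MacrostateMapping]:
    """Full APM loop: split, estimate, lump, then re-split within
    macrostates and re-lump until the frame-level macrostate labelling is
    a fixed point (or ``config.max_iter`` is reached, with a warning)."""
    rng = np.random.default_rng(config.seed)
    assign = apm_split(features, config.t0, seed=int(rng.integers(2 ** 31)),
                       min_population=config.min_population,
                       max_states=config.max_states)
    prev_macro_frames = None
    best = None
    for _ in range(config.max_iter):
        C = count_transitions(assign.labels, config.lag, assign.n_states)
        msm = estimate_T(C, lag=config.lag, mode=config.estimator)
        n_macro = config.n_macro or choose_n_macro(
            msm.timescales(config.its_rank))
        mapping = _full_mapping(msm, n_macro, assign.n_states,
                                seed=int(rng.integers(2 ** 31)))
        macro_frames = mapping.map_labels(assign.flat())
        best = (assign, msm, mapping)
        if prev_macro_frames is not None and \
                _same_partition(macro_frames, prev_macro_frames):
            return best
        prev_macro_frames = macro_frames
        # re-split within current macrostates
        init = macro_frames.copy()
        init[init < 0] = init.max() + 1  # park disconnected frames together
        assign = apm_split(features, config.t0,
                           seed=int(rng.integers(2 ** 31)),
                           init_labels=init,
                           min_population=config.min_population,
                           max_states=config.max_states)
    warnings.warn("APM iteration did not reach a fixed point; returning the "
                  "last decomposition", RuntimeWarning)
    return best


def _full_mapping(msm: MicrostateMSM, n_macro: int, n_states: int,
                  seed: int = 0) -> MacrostateMapping:
    lump = spectral_lump(msm, n_macro, seed=seed)
    full = np.full(n_states, -1, dtype=int)
    full[msm.active] = lump.micro_to_macro
    return MacrostateMapping(micro_to_macro=full, n_macro=n_macro,
                             populations=lump.populations)


def _same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True if two labelings induce the same partition (up to renaming)."""
    pair = a.astype(np.int64) * (b.max() + 2) + b
    return len(np.unique(pair)) == max(len(np.unique(a)), len(np.unique(b)))
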