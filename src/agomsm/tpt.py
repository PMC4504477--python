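"""Kinetics on an estimated MSM: mean first passage times, synthetic
long trajectories, inter-macrostate transition times, and transition-path
theory flux decomposition.

MFPTs solve the linear system ``X_i = Σ_j T_ij (τ + X_j)`` with ``X`` fixed
to zero on the final set.  Macrostate-level MFPTs average the microstate
values over the initial macrostate, weighted by the equilibrium populations
renormalized within that macrostate.  Net reactive flux between a source
and a sink set is decomposed into pathways by repeatedly removing the
widest (maximum-bottleneck) path — the greedy backtracking scheme.
Internal times are in ns; reporting helpers convert to μs.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import numpy as np

from .msm import MacrostateMapping, MicrostateMSM

__all__ = [
    "MFPTResult", "FluxNetwork", "SyntheticTrace", "Pathway",
    "mfpt_micro", "mfpt_macro", "sample_msm_trajectory",
    "mean_transition_times", "committors", "flux_network",
    "greedy_backtracking_paths", "lump_pathways", "macro_of_rows",
]

NS_PER_US = 1000.0


def macro_of_rows(msm: MicrostateMSM, mapping: MacrostateMapping) -> np.ndarray:
    """Macrostate label of each row of the (connected-set) MSM."""
    return mapping.micro_to_macro[msm.active]


@dataclass
class MFPTResult:
    """Per-microstate mean first passage times to a final set (ns)."""

    mfpt: np.ndarray
    final_set: np.ndarray
    lag: float

    def in_microseconds(self) -> np.ndarray:
        return self.mfpt / NS_PER_US


def mfpt_micro(msm: MicrostateMSM, final_set) -> MFPTResult:
    """Solve the first-passage linear system toward ``final_set`` (row ids)."""
    final = np.unique(np.asarray(final_set, dtype=int))
    if final.size == 0:
        raise ValueError("final set must be non-empty")
    if final.min() < 0 or final.max() >= msm.n_states:
        raise ValueError("final set references unknown states")
    n = msm.n_states
    rest = np.setdiff1d(np.arange(n), final)
    x = np.zeros(n)
    if rest.size:
        A = np.eye(rest.size) - msm.T[np.ix_(rest, rest)]
        try:
            sol = np.linalg.solve(A, np.full(rest.size, msm.lag))
        except np.linalg.LinAlgError as err:
            raise ValueError(f"singular first-passage system: {err}") from err
        if np.any(sol < -1e-9) or not np.all(np.isfinite(sol)):
            raise ValueError("first-passage system is ill-posed "
                             "(absorbing trap outside the final set?)")
        x[rest] = sol
    return MFPTResult(mfpt=x, final_set=final, lag=msm.lag)


def mfpt_macro(msm: MicrostateMSM, mapping: MacrostateMapping,
               init_macro: int, final_macro: int) -> float:
    """Population-weighted macrostate MFPT (ns).

    MFPTs are set to zero on every microstate of the final macrostate,
    solved for all others, and averaged over the initial macrostate's
    microstates with weights π renormalized within that macrostate.
    """
    if init_macro == final_macro:
        raise ValueError("initial and final macrostates must differ")
    rows = macro_of_rows(msm, mapping)
    final = np.flatnonzero(rows == final_macro)
    init = np.flatnonzero(rows == init_macro)
    if final.size == 0 or init.size == 0:
        raise ValueError("empty macrostate")
    res = mfpt_micro(msm, final)
    w = msm.pi[init]
    return float(np.average(res.mfpt[init], weights=w / w.sum()))


@dataclass
class SyntheticTrace:
    """Microstate label sequence sampled from the transition matrix."""

    micro: np.ndarray
    macro: np.ndarray | None
    dt: float  # time per step = MSM lag (ns)

    @property
    def n_steps(self) -> int:
        return len(self.micro)


def sample_msm_trajectory(msm: MicrostateMSM, start: int, n_steps: int,
                          seed: int = 0,
                          mapping: MacrostateMapping | None = None
                          ) -> SyntheticTrace:
    """Propagate a synthetic trajectory by categorical sampling per row.

    Each step advances one lag time; the macrostate sequence (if a mapping
    is given) simply maps every visited microstate to its macrostate.
    """
    from .synthetic import _sample_path

    if not 0 <= start < msm.n_states:
        raise ValueError("invalid start state")
    if not np.allclose(msm.T.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix rows do not sum to 1")
    rng = np.random.default_rng(seed)
    micro = _sample_path(msm.T, start, n_steps, rng)
    macro = None
    if mapping is not None:
        macro = macro_of_rows(msm, mapping)[micro]
    return SyntheticTrace(micro=micro, macro=macro, dt=msm.lag)


def mean_transition_times(traces, groupA, groupB,
                          convention: str = "last_exit") -> tuple[float, int]:
    """Average time from macrostate group A to first entry into group B.

    ``convention='last_exit'`` measures from the last frame in A before
    the arrival in B; ``'first_entry'`` from the first frame in A after
    the previous completed event.  Returns ``(mean_time_ns, n_events)``;
    with no event the mean is NaN and a warning is issued, never zero.
    """
    if convention not in ("last_exit", "first_entry"):
        raise ValueError("convention must be 'last_exit' or 'first_entry'")
    A = set(int(a) for a in groupA)
    B = set(int(b) for b in groupB)
    if A & B:
        raise ValueError("groups must be disjoint")
    dts = {t.dt for t in traces}
    if len(dts) != 1:
        raise ValueError("traces must share one lag time")
    dt = dts.pop()
    durations = []
    for tr in traces:
        seq = tr.macro if tr.macro is not None else tr.micro
        last_a = first_a = None
        for t, s in enumerate(seq):
            s = int(s)
            if s in A:
                last_a = t
                if first_a is None:
                    first_a = t
            elif s in B and last_a is not None:
                ref = last_a if convention == "last_exit" else first_a
                durations.append((t - ref) * dt)
                last_a = first_a = None
    if not durations:
        warnings.warn("no A->B transition event observed", RuntimeWarning)
        return np.nan, 0
    return float(np.mean(durations)), len(durations)


def committors(msm: MicrostateMSM, source, sink) -> tuple[np.ndarray, np.ndarray]:
    """Forward and backward committors between two disjoint state sets.

    The forward committor is harmonic on intermediates with boundary
    values 0 on the source and 1 on the sink; the backward committor is
    the committor toward the source on the time-reversed chain (equal to
    ``1 - q+`` under detailed balance).
    """
    source = np.unique(np.asarray(source, dtype=int))
    sink = np.unique(np.asarray(sink, dtype=int))
    if source.size == 0 or sink.size == 0:
        raise ValueError("source and sink must be non-empty")
    if np.intersect1d(source, sink).size:
        raise ValueError("source and sink must be disjoint")

    def _solve(T, zero_set, one_set):
        n = T.shape[0]
        q = np.zeros(n)
        q[one_set] = 1.0
        inter = np.setdiff1d(np.arange(n), np.union1d(zero_set, one_set))
        if inter.size:
            A = np.eye(inter.size) - T[np.ix_(inter, inter)]
            b = T[np.ix_(inter, one_set)].sum(axis=1)
            try:
                q[inter] = np.linalg.solve(A, b)
            except np.linalg.LinAlgError as err:
                raise ValueError(
                    f"intermediates disconnected from boundary: {err}") from err
        return q

    q_plus = _solve(msm.T, source, sink)
    T_rev = (msm.pi[None, :] * msm.T.T) / msm.pi[:, None]
    q_minus = _solve(T_rev, sink, source)
    if np.any(q_plus < -1e-10) or np.any(q_plus > 1 + 1e-10):
        raise ValueError("forward committor out of [0, 1]")
    return np.clip(q_plus, 0, 1), np.clip(q_minus, 0, 1)


@dataclass
class FluxNetwork:
    """TPT flux between a source and sink set of MSM states.

    ``gross[i, j] = π_i q⁻_i T_ij q⁺_j`` for i ≠ j; ``net`` keeps only the
    positive part of the antisymmetrized gross flux; ``total`` is the net
    flow across the source boundary (per lag time).
    """

    q_plus: np.ndarray
    q_minus: np.ndarray
    gross: np.ndarray
    net: np.ndarray
    total: float
    source: np.ndarray
    sink: np.ndarray


def flux_network(msm: MicrostateMSM, source, sink,
                 q_plus: np.ndarray | None = None,
                 q_minus: np.ndarray | None = None) -> FluxNetwork:
    """Reactive flux decomposition for the given source and sink sets."""
    source = np.unique(np.asarray(source, dtype=int))
    sink = np.unique(np.asarray(sink, dtype=int))
    if q_plus is None or q_minus is None:
        q_plus, q_minus = committors(msm, source, sink)
    f = (msm.pi * q_minus)[:, None] * msm.T * q_plus[None, :]
    np.fill_diagonal(f, 0.0)
    net = np.maximum(f - f.T, 0.0)
    not_src = np.setdiff1d(np.arange(msm.n_states), source)
    total = float(f[np.ix_(source, not_src)].sum()
                  - f[np.ix_(not_src, source)].sum())
    return FluxNetwork(q_plus=q_plus, q_minus=q_minus, gross=f, net=net,
                       total=total, source=source, sink=sink)


@dataclass
class Pathway:
    """One source-to-sink pathway and the flux it carries."""

    states: tuple
    flux: float
    fraction: float


def _widest_path(net: np.ndarray, source, sink, tol: float):
    """Maximum-bottleneck path via a max-min variant of Dijkstra.

    Ties in the bottleneck width are broken toward lexicographically
    smaller state sequences (lower node ids popped first).
    """
    n = net.shape[0]
    width = np.full(n, -np.inf)
    parent = np.full(n, -1)
    heap = []
    for s in source:
        width[s] = np.inf
        heapq.heappush(heap, (-np.inf, int(s)))
    visited = np.zeros(n, dtype=bool)
    sink_set = set(int(s) for s in sink)
    while heap:
        negw, u = heapq.heappop(heap)
        if visited[u]:
            continue
        visited[u] = True
        if u in sink_set:
            path = [u]
            while parent[path[-1]] >= 0:
                path.append(int(parent[path[-1]]))
            return list(reversed(path)), float(width[u])
        for v in np.flatnonzero(net[u] > tol):
            w = min(width[u], net[u, v])
            if w > width[v] and not visited[v]:
                width[v] = w
                parent[v] = u
                heapq.heappush(heap, (-w, int(v)))
    return None, 0.0


def greedy_backtracking_paths(net: FluxNetwork, max_paths: int | None = None,
                              tol: float = 1e-12) -> list[Pathway]:
    """Decompose the net flux into bottleneck-ranked pathways.

    Repeatedly extracts the widest source-to-sink path, records it with
    its bottleneck flux, and subtracts that flux along the path until the
    flux is exhausted (or ``max_paths`` is reached).
    """
    residual = net.net.copy()
    if np.any(residual < -1e-10):
        raise ValueError("negative net flux entries")
    total = net.total
    out: list[Pathway] = []
    cutoff = max(tol, abs(total) * tol)
    while max_paths is None or len(out) < max_paths:
        path, bottleneck = _widest_path(residual, net.source, net.sink, cutoff)
        if path is None or bottleneck <= cutoff:
            break
        for a, b in zip(path[:-1], path[1:]):
            residual[a, b] -= bottleneck
        frac = bottleneck / total if total > 0 else np.nan
        out.append(Pathway(states=tuple(path), flux=bottleneck, fraction=frac))
    return out


def lump_pathways(paths: list[Pathway], msm: MicrostateMSM,
                  mapping: MacrostateMapping) -> list[Pathway]:
    """Collapse microstate pathways to ranked macrostate pathways.

    Each microstate sequence is mapped to its macrostate sequence,
    consecutive repeats are collapsed, and fluxes of identical macrostate
    sequences are summed; total flux is preserved.
    """
    rows = macro_of_rows(msm, mapping)
    agg: dict[tuple, float] = {}
    frac: dict[tuple, float] = {}
    for p in paths:
        seq = rows[list(p.states)]
        collapsed = tuple(int(s) for i, s in enumerate(seq)
                          if i == 0 or s != seq[i - 1])
        agg[collapsed] = agg.get(collapsed, 0.0) + p.flux
        frac[collapsed] = frac.get(collapsed, 0.0) + p.fraction
    ranked = sorted(agg.items(), key=lambda kv: -kv[1])
    return [Pathway(states=k, flux=v, fraction=frac[k]) for k, v in ranked]
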