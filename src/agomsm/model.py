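"""Model/Results facade over the APM + MSM machinery.

``MarkovStateModel`` is built from data — either continuous feature
trajectories (the APM decomposition is run during :meth:`fit`) or
pre-assigned discrete microstate labels — and ``fit()`` returns an
:class:`MSMResults` carrying the estimated transition matrix, stationary
and macrostate populations, diagnostics, kinetics, and a ``summary()``
table.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from . import msm as _msm
from . import tpt as _tpt
from . import validation as _val
from .ensembles import TrajectoryEnsemble

__all__ = ["MarkovStateModel", "MSMResults"]


class MarkovStateModel:
    """Markov state model of metastable conformational dynamics.

    Parameters
    ----------
    data
        A :class:`TrajectoryEnsemble`; discrete integer series are taken
        as microstate labels, float series as clustering features (the
        APM split/lump loop then defines the microstates).
    lag
        MSM lag time in ns (must be a multiple of the saving interval).
    t0
        Maximum microstate residence time in ns (APM threshold); only
        used when fitting from features.
    n_macro
        Macrostate count; ``None`` selects it at the largest
        implied-timescale gap.
    estimator
        ``'nonreversible'`` (row-normalized counts) or ``'symmetrized'``.
    """

    def __init__(self, data: TrajectoryEnsemble, *, lag: float,
                 t0: float | None = None, n_macro: int | None = None,
                 estimator: str = "nonreversible", seed: int = 0,
                 min_population: int = 10, max_iter: int = 10):
        if not isinstance(data, TrajectoryEnsemble):
            raise TypeError("data must be a TrajectoryEnsemble")
        self.data = data
        self.lag = float(lag)
        self.t0 = float(t0) if t0 is not None else None
        self.n_macro = n_macro
        self.estimator = estimator
        self.seed = int(seed)
        self.min_population = int(min_population)
        self.max_iter = int(max_iter)

    @classmethod
    def from_features(cls, features: TrajectoryEnsemble, *, lag: float,
                      t0: float, **kw) -> "MarkovStateModel":
        if features.is_discrete:
            raise ValueError("expected continuous features")
        return cls(features, lag=lag, t0=t0, **kw)

    @classmethod
    def from_labels(cls, labels: TrajectoryEnsemble, *, lag: float,
                    **kw) -> "MarkovStateModel":
        if not labels.is_discrete:
            raise ValueError("expected discrete labels")
        return cls(labels, lag=lag, **kw)

    def fit(self) -> "MSMResults":
        if self.data.is_discrete:
            n_states = int(max(s.max() for s in self.data)) + 1
            assign = _msm.MicrostateAssignment(labels=self.data,
                                               n_states=n_states)
            C = _msm.count_transitions(self.data, self.lag, n_states)
            micro = _msm.estimate_T(C, lag=self.lag, mode=self.estimator)
            n_macro = self.n_macro or _msm.choose_n_macro(micro.timescales(10))
            mapping = _msm._full_mapping(micro, n_macro, n_states,
                                         seed=self.seed)
        else:
            if self.t0 is None:
                raise ValueError("t0 is required when fitting from features")
            config = _msm.APMConfig(t0=self.t0, lag=self.lag,
                                    n_macro=self.n_macro,
                                    max_iter=self.max_iter, seed=self.seed,
                                    min_population=self.min_population,
                                    estimator=self.estimator)
            assign, micro, mapping = _msm.apm_iterate(self.data, config)
        return MSMResults(self, assign, micro, mapping)


class MSMResults:
    """Fitted MSM: estimates, diagnostics, kinetics and sampling."""

    def __init__(self, model: MarkovStateModel,
                 assignment: _msm.MicrostateAssignment,
                 micro: _msm.MicrostateMSM,
                 mapping: _msm.MacrostateMapping):
        self.model = model
        self.assignment = assignment
        self.micro = micro
        self.mapping = mapping

    # -- estimates ---------------------------------------------------------
    @property
    def transition_matrix(self) -> np.ndarray:
        return self.micro.T

    @property
    def stationary_distribution(self) -> np.ndarray:
        return self.micro.pi

    @property
    def lag(self) -> float:
        return self.micro.lag

    @property
    def n_microstates(self) -> int:
        return self.micro.n_states

    @property
    def n_macrostates(self) -> int:
        return self.mapping.n_macro

    @property
    def macro_populations(self) -> np.ndarray:
        return self.mapping.populations

    def timescales(self, k: int | None = None) -> np.ndarray:
        return self.micro.timescales(k)

    def macro_labels(self) -> TrajectoryEnsemble:
        """Per-frame macrostate labels (−1 outside the connected set)."""
        flat = self.mapping.map_labels(self.assignment.flat())
        return TrajectoryEnsemble(self.assignment.labels.split_frames(flat),
                                  dt=self.assignment.labels.dt)

    # -- diagnostics -------------------------------------------------------
    def implied_timescales(self, lag_grid, k: int = 10
                           ) -> _val.ImpliedTimescaleResult:
        return _val.implied_timescales(self.assignment.labels, lag_grid, k,
                                       n_states=self.assignment.n_states,
                                       estimator=self.model.estimator)

    def residence_test(self, state: int, n_points: int = 10
                       ) -> _val.ResidenceTestResult:
        return _val.residence_test(self.micro, self.assignment.labels,
                                   state, n_points)

    # -- kinetics ----------------------------------------------------------
    def mfpt(self, init_macro: int, final_macro: int,
             units: str = "us") -> float:
        val = _tpt.mfpt_macro(self.micro, self.mapping, init_macro,
                              final_macro)
        return val / _tpt.NS_PER_US if units == "us" else val

    def mfpt_matrix(self, units: str = "us") -> pd.DataFrame:
        n = self.n_macrostates
        M = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    M[i, j] = self.mfpt(i, j, units=units)
        names = [f"macro{m}" for m in range(n)]
        return pd.DataFrame(M, index=names, columns=names)

    def committors(self, source_macros, sink_macros):
        rows = _tpt.macro_of_rows(self.micro, self.mapping)
        src = np.flatnonzero(np.isin(rows, list(source_macros)))
        snk = np.flatnonzero(np.isin(rows, list(sink_macros)))
        return _tpt.committors(self.micro, src, snk)

    def flux(self, source_macros, sink_macros) -> _tpt.FluxNetwork:
        rows = _tpt.macro_of_rows(self.micro, self.mapping)
        src = np.flatnonzero(np.isin(rows, list(source_macros)))
        snk = np.flatnonzero(np.isin(rows, list(sink_macros)))
        return _tpt.flux_network(self.micro, src, snk)

    def pathways(self, source_macros, sink_macros,
                 max_paths: int | None = None, lumped: bool = True):
        net = self.flux(source_macros, sink_macros)
        paths = _tpt.greedy_backtracking_paths(net, max_paths)
        if lumped:
            return _tpt.lump_pathways(paths, self.micro, self.mapping)
        return paths

    def sample(self, start: int, n_steps: int, seed: int = 0
               ) -> _tpt.SyntheticTrace:
        return _tpt.sample_msm_trajectory(self.micro, start, n_steps,
                                          seed=seed, mapping=self.mapping)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        buf = io.StringIO()
        w = buf.write
        w("Markov State Model Results\n")
        w("=" * 60 + "\n")
        w(f"{'Trajectories:':<28}{self.assignment.labels.n_trajectories}\n")
        w(f"{'Frames:':<28}{self.assignment.labels.n_frames}\n")
        w(f"{'Lag time (ns):':<28}{self.lag:g}\n")
        if self.model.t0 is not None:
            w(f"{'Residence threshold t0 (ns):':<28}{self.model.t0:g}\n")
        w(f"{'Microstates (connected):':<28}"
          f"{self.n_microstates} of {self.assignment.n_states}\n")
        w(f"{'Macrostates:':<28}{self.n_macrostates}\n")
        w(f"{'Estimator:':<28}{self.model.estimator}\n")
        w("-" * 60 + "\n")
        w("Macrostate populations\n")
        for m, p in enumerate(self.macro_populations):
            w(f"  macro{m:<3} {p * 100:7.1f} %   "
              f"({len(self.mapping.members(m))} microstates)\n")
        w("-" * 60 + "\n")
        w("Slowest implied timescales (ns)\n")
        ts = self.timescales(min(6, self.n_microstates - 1))
        for k, t in enumerate(ts, start=2):
            w(f"  t{k - 1:<3} {t:12.1f}\n")
        w("=" * 60 + "\n")
        return buf.getvalue()
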