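"""Trajectory ensemble container shared by the generator, featurizer and MSM code.

An ensemble is a list of time-ordered series that share one saving interval.
Series may hold discrete microstate labels (integer dtype) or continuous
feature vectors (float, shape ``(T_j, d)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np


@dataclass
class TrajectoryEnsemble:
    """A set of time-ordered series with a common saving interval.

    Parameters
    ----------
    series
        One array per trajectory.  Discrete ensembles store 1-D integer
        label arrays; continuous ensembles store ``(T_j, d)`` float arrays.
    dt
        Saving interval between consecutive frames, in nanoseconds.
    meta
        Free-form provenance (seed, generator parameters, selections).
    """

    series: list[np.ndarray]
    dt: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("saving interval dt must be positive")
        if not self.series:
            raise ValueError("ensemble must contain at least one trajectory")
        self.series = [np.asarray(s) for s in self.series]
        for s in self.series:
            if len(s) < 2:
                raise ValueError("every trajectory needs at least 2 frames")
        if any(np.issubdtype(s.dtype, np.floating) and not np.all(np.isfinite(s))
               for s in self.series):
            raise ValueError("non-finite values in trajectory data")

    @property
    def n_trajectories(self) -> int:
        return len(self.series)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(s) for s in self.series])

    @property
    def n_frames(self) -> int:
        return int(self.lengths.sum())

    @property
    def is_discrete(self) -> bool:
        return all(np.issubdtype(s.dtype, np.integer) for s in self.series)

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.series)

    def concatenated(self) -> np.ndarray:
        """All frames stacked along the time axis (trajectory order)."""
        return np.concatenate(self.series, axis=0)

    def split_frames(self, flat: np.ndarray) -> list[np.ndarray]:
        """Inverse of :meth:`concatenated` for per-frame quantities."""
        if len(flat) != self.n_frames:
            raise ValueError("length mismatch with ensemble frame count")
        out, i = [], 0
        for n in self.lengths:
            out.append(flat[i:i + n])
            i += n
        return out

    def subset(self, indices) -> "TrajectoryEnsemble":
        """Ensemble restricted to the given trajectory indices (with repeats)."""
        return TrajectoryEnsemble([self.series[i] for i in indices],
                                  dt=self.dt, meta=dict(self.meta))
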