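"""Order parameters and clustering features from coordinate trajectories.

Frames are least-squares superposed on a reference selection (the rigid
PIWI-core Cα atoms in the original analysis), after which the package's
order parameters are computed: the concatenated-Cα feature vectors the
state decomposition clusters on, the PAZ–PIWI-loop centre-of-mass
distance, the major-PIWI-loop angle, and per-residue RMSF.

Coordinate ensembles are :class:`~agomsm.ensembles.TrajectoryEnsemble`
objects whose series have shape ``(T_j, n_atoms, 3)`` (Å), sharing one
topology table.  Structures and topologies are read from PDB with
biotite; XTC/DCD trajectories load through mdtraj when available.
Feature tables can also be supplied directly as delimited text, bypassing
coordinates entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensembles import TrajectoryEnsemble

__all__ = [
    "AtomSelection", "atomic_mass", "topology_from_atom_array", "load_pdb",
    "load_trajectory", "kabsch", "superpose", "build_features",
    "com_distance", "angle_at_vertex", "major_loop_angle", "rmsf",
]

# standard atomic masses (u); pseudo-atoms of unknown element get unit mass
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
           "S": 32.06, "NA": 22.990, "MG": 24.305, "K": 39.098, "CL": 35.45}

# default residue spans, on the crystal numbering of the reference entry:
# minor PIWI loop P601-P609, major PIWI loop V818-D838
MINOR_LOOP = range(601, 610)
MAJOR_LOOP = range(818, 839)


def atomic_mass(element: str) -> float:
    return _MASSES.get(str(element).upper(), 1.0)


@dataclass
class AtomSelection:
    """Named selection over a topology table.

    ``res_ids`` is any iterable of residue ids (``None`` selects all);
    ``atom_names`` restricts atom names (e.g. ``("CA",)``); ``stride``
    keeps every n-th *residue* of the selection, counted from its first
    residue (the convention used for the sparse PAZ-L1L2 Cα picks).
    """

    res_ids: object = None
    atom_names: tuple | None = None
    stride: int = 1
    label: str = ""

    def resolve(self, topology: pd.DataFrame) -> np.ndarray:
        mask = np.ones(len(topology), dtype=bool)
        if self.res_ids is not None:
            wanted = np.unique(np.fromiter(self.res_ids, dtype=int))
            if self.stride > 1:
                wanted = wanted[::self.stride]
            mask &= topology["res_id"].isin(wanted).to_numpy()
        elif self.stride > 1:
            wanted = np.unique(topology["res_id"].to_numpy())[::self.stride]
            mask &= topology["res_id"].isin(wanted).to_numpy()
        if self.atom_names is not None:
            mask &= topology["atom_name"].isin(self.atom_names).to_numpy()
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"selection {self.label or self!r} matches no atom")
        return idx


def topology_from_atom_array(arr) -> pd.DataFrame:
    """Topology table (res_id, atom_name, element, mass, chain) from a
    biotite ``AtomArray``."""
    return pd.DataFrame({
        "chain_id": arr.chain_id,
        "res_id": arr.res_id.astype(int),
        "res_name": arr.res_name,
        "atom_name": arr.atom_name,
        "element": arr.element,
        "mass": [atomic_mass(e) for e in arr.element],
    })


def load_pdb(path) -> tuple[np.ndarray, pd.DataFrame]:
    """Read a PDB file into ``(coords, topology)`` (first model)."""
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(path))
    arr = f.get_structure(model=1)
    return np.asarray(arr.coord, dtype=float), topology_from_atom_array(arr)


def load_trajectory(path, topology_path) -> TrajectoryEnsemble:
    """Read an XTC/DCD trajectory through mdtraj (coordinates in Å)."""
    import mdtraj as md

    traj = md.load(str(path), top=str(topology_path))
    coords = np.asarray(traj.xyz, dtype=float) * 10.0  # nm -> Å
    top = pd.DataFrame({
        "chain_id": [a.residue.chain.index for a in traj.topology.atoms],
        "res_id": [a.residue.resSeq for a in traj.topology.atoms],
        "res_name": [a.residue.name for a in traj.topology.atoms],
        "atom_name": [a.name for a in traj.topology.atoms],
        "element": [a.element.symbol if a.element else "X"
                    for a in traj.topology.atoms],
        "mass": [a.element.mass if a.element else 1.0
                 for a in traj.topology.atoms],
    })
    dt = float(traj.timestep) / 1000.0 if traj.n_frames > 1 else 1.0  # ps->ns
    return TrajectoryEnsemble([coords], dt=max(dt, 1e-9),
                              meta={"topology": top, "source": str(path)})


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, reference: np.ndarray,
           weights: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rigid rotation/translation mapping ``mobile`` onto
    ``reference`` in the least-squares sense.  Returns ``(R, t)`` so that
    ``mobile @ R.T + t`` is the fitted structure."""
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if weights is None:
        weights = np.ones(len(P))
    w = weights / weights.sum()
    pc = (w[:, None] * P).sum(axis=0)
    qc = (w[:, None] * Q).sum(axis=0)
    H = (w[:, None] * (P - pc)).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def superpose(frames: TrajectoryEnsemble, reference: np.ndarray,
              fit_indices: np.ndarray) -> TrajectoryEnsemble:
    """Rigid-body fit every frame onto the reference over the fit atoms.

    The transform minimizing the RMSD of the fit selection is applied to
    all atoms of the frame.  Superposition is idempotent.
    """
    reference = np.asarray(reference, dtype=float)
    fit_indices = np.asarray(fit_indices, dtype=int)
    ref_sel = reference[fit_indices]
    out = []
    for series in frames:
        fitted = np.empty_like(series)
        for i, frame in enumerate(series):
            R, t = kabsch(frame[fit_indices], ref_sel)
            fitted[i] = frame @ R.T + t
        out.append(fitted)
    return TrajectoryEnsemble(out, dt=frames.dt,
                              meta={**frames.meta, "superposed": True})


def selection_rmsd(coords: np.ndarray, reference: np.ndarray,
                   indices: np.ndarray) -> float:
    d = coords[indices] - reference[indices]
    return float(np.sqrt((d ** 2).sum(axis=1).mean()))


# ---------------------------------------------------------------------------
# order parameters
# ---------------------------------------------------------------------------

def build_features(frames: TrajectoryEnsemble, loop_indices: np.ndarray,
                   paz_indices: np.ndarray) -> TrajectoryEnsemble:
    """Concatenated Cartesian coordinates of the selected atoms.

    The pairwise Euclidean distance between two feature rows equals the
    (non-refit) coordinate distance over the selected atoms, which is the
    metric the state decomposition clusters on.  The PIWI-loop selection
    and the strided PAZ-L1L2 selection are concatenated as-is — the
    stride alone balances the two regions' contributions.
    """
    loop_indices = np.asarray(loop_indices, dtype=int)
    paz_indices = np.asarray(paz_indices, dtype=int)
    if loop_indices.size == 0 or paz_indices.size == 0:
        raise ValueError("empty selection")
    sel = np.concatenate([loop_indices, paz_indices])
    out = [series[:, sel, :].reshape(len(series), -1) for series in frames]
    return TrajectoryEnsemble(out, dt=frames.dt,
                              meta={**frames.meta,
                                    "n_loop_atoms": int(loop_indices.size),
                                    "n_paz_atoms": int(paz_indices.size)})


def com_distance(frame: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray,
                 masses: np.ndarray) -> float:
    """Distance between the mass-weighted centroids of two atom groups (Å)."""
    idx_a = np.asarray(idx_a, dtype=int)
    idx_b = np.asarray(idx_b, dtype=int)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("both groups must be non-empty")
    ma, mb = masses[idx_a], masses[idx_b]
    if ma.sum() <= 0 or mb.sum() <= 0:
        raise ValueError("zero total mass in a group")
    ca = (ma[:, None] * frame[idx_a]).sum(axis=0) / ma.sum()
    cb = (mb[:, None] * frame[idx_b]).sum(axis=0) / mb.sum()
    return float(np.linalg.norm(ca - cb))


def angle_at_vertex(a: np.ndarray, vertex: np.ndarray, c: np.ndarray) -> float:
    """Planar angle a-vertex-c in degrees, in [0, 180]."""
    u = np.asarray(a, dtype=float) - vertex
    v = np.asarray(c, dtype=float) - vertex
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError("degenerate geometry: zero-length vector")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def major_loop_angle(frame: np.ndarray, topology: pd.DataFrame,
                     core_selection: AtomSelection,
                     tip_residue: int = 823,
                     anchor_residues: tuple = (818, 838)) -> float:
    """Angle describing the major-PIWI-loop orientation.

    Measured at the centre of mass of the rigid core selection, between
    the vector to the loop-tip Cα (D823 by default) and the vector to the
    centre of mass of the loop-anchor Cα atoms (V818/D838 by default).
    The three defining points are configurable — the construction is a
    documented convention, not uniquely fixed by the original figure.
    """
    masses = topology["mass"].to_numpy()
    core_idx = core_selection.resolve(topology)
    m = masses[core_idx]
    vertex = (m[:, None] * frame[core_idx]).sum(axis=0) / m.sum()
    ca = (topology["atom_name"] == "CA").to_numpy()
    tip_idx = np.flatnonzero(ca & (topology["res_id"] == tip_residue).to_numpy())
    if tip_idx.size == 0:
        raise ValueError(f"tip residue {tip_residue} has no CA atom")
    anchor_idx = np.flatnonzero(
        ca & topology["res_id"].isin(anchor_residues).to_numpy())
    if anchor_idx.size == 0:
        raise ValueError("anchor residues not found")
    anchor = frame[anchor_idx].mean(axis=0)
    return angle_at_vertex(frame[tip_idx[0]], vertex, anchor)


def rmsf(frames: TrajectoryEnsemble, indices: np.ndarray,
         topology: pd.DataFrame) -> pd.Series:
    """Per-residue root-mean-square fluctuation about the time average (Å).

    Frames must already be superposed; per-atom RMSFs are averaged within
    each residue of the selection.
    """
    indices = np.asarray(indices, dtype=int)
    X = np.concatenate([s[:, indices, :] for s in frames], axis=0)
    if X.shape[0] < 2:
        raise ValueError("RMSF needs at least two frames")
    mean = X.mean(axis=0)
    per_atom = np.sqrt(((X - mean) ** 2).sum(axis=2).mean(axis=0))
    res = topology.iloc[indices]["res_id"].to_numpy()
    return pd.Series(per_atom).groupby(res).mean().rename("rmsf")
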