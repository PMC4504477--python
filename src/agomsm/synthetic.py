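"""Ground-truth-known synthetic inputs for the MSM and docking-metric pipeline.

Two families of fixtures are generated here:

* metastable discrete Markov chains with state-conditional Gaussian feature
  emissions, standing in for the (undeposited) apo-Argonaute MD dataset.
  The default "Ago-like" chain has seven macrostates — five closed, one
  partially open, one open — whose stationary populations and 1-D
  centre-of-mass-distance emissions mimic the opening coordinate of hAgo2
  (closed basins near 10–22 Å, partially open near 27 Å, open near 40 Å,
  tail reaching ~46 Å);

* toy protein/RNA coordinate sets with an exactly known native-contact
  list, standing in for a protein–miRNA crystal complex.  The default
  crystal analog carries 48 residue–nucleotide contacts, 43 involving the
  5' half of the RNA and 5 the 3' half.  These complexes are synthetic:
  pseudo-atom geometry only, no force-field realism.

Chains are built under detailed balance, ``T_ij = Δ c_ij π_j`` with a
symmetric connectivity ``c``, so the stationary vector is controlled
exactly and all eigenvalues are real.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .ensembles import TrajectoryEnsemble

__all__ = [
    "GroundTruthChain",
    "EmissionModel",
    "ToyComplex",
    "make_metastable_chain",
    "ago_like_chain",
    "ago_like_emission",
    "simulate_chain",
    "emit_features",
    "make_toy_complex",
    "perturb_pose",
    "synthetic_crystal_analog",
    "FIVE_PRIME_NUCS",
    "THREE_PRIME_NUCS",
]

# Default macrostate layout of the Ago-like chain: five closed states, one
# partially open, one open.  Populations follow the reported equilibrium
# populations of the seven-macrostate decomposition (open 19.0 %, partially
# open 55.8 %, remainder shared among the closed states); emission centers
# are PAZ-PIWI-loop c.o.m. distances in Å.
AGO_MACRO_NAMES = ("closed1", "closed2", "closed3", "closed4", "closed5",
                   "partial", "open")
AGO_MACRO_WEIGHTS = (0.080, 0.060, 0.048, 0.036, 0.028, 0.558, 0.190)
AGO_MACRO_CENTERS = (10.0, 13.0, 16.0, 19.0, 22.0, 27.0, 40.0)


@dataclass
class GroundTruthChain:
    """A block-metastable Markov chain with known stationary vector.

    ``implied_timescales_true`` holds the analytic relaxation timescales
    ``-lag_unit / ln λ_k`` for the non-unit eigenvalues of ``T_true``
    (``inf`` for disconnected/degenerate modes).
    """

    T_true: np.ndarray
    macro_of_micro: np.ndarray
    pi_true: np.ndarray
    lag_unit: float = 20.0  # ns per chain step
    macro_weights: np.ndarray | None = None
    implied_timescales_true: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.T_true = np.asarray(self.T_true, dtype=float)
        self.macro_of_micro = np.asarray(self.macro_of_micro, dtype=int)
        self.pi_true = np.asarray(self.pi_true, dtype=float)
        n = self.T_true.shape[0]
        if self.T_true.shape != (n, n):
            raise ValueError("T_true must be square")
        if not np.allclose(self.T_true.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("rows of T_true must sum to 1 within 1e-12")
        if np.any(self.T_true < 0):
            raise ValueError("negative transition probability")
        if not np.allclose(self.pi_true @ self.T_true, self.pi_true, atol=1e-10):
            raise ValueError("pi_true is not stationary within 1e-10")
        if self.implied_timescales_true is None:
            self.implied_timescales_true = _analytic_timescales(
                self.T_true, self.lag_unit)

    @property
    def n_micro(self) -> int:
        return self.T_true.shape[0]

    @property
    def n_macro(self) -> int:
        return int(self.macro_of_micro.max()) + 1

    def macro_populations(self) -> np.ndarray:
        return np.bincount(self.macro_of_micro, weights=self.pi_true,
                           minlength=self.n_macro)

    def metastability_gap(self) -> float:
        """Mean intra-macrostate off-diagonal probability over mean inter."""
        same = self.macro_of_micro[:, None] == self.macro_of_micro[None, :]
        off = ~np.eye(self.n_micro, dtype=bool)
        intra = self.T_true[same & off]
        inter = self.T_true[~same]
        if intra.size == 0:  # single-microstate macrostates: undefined
            return np.nan
        if inter.size == 0 or inter.mean() == 0:
            return np.inf
        return float(intra.mean() / inter.mean())


def _analytic_timescales(T: np.ndarray, lag: float) -> np.ndarray:
    """Implied timescales from the eigenvalues of a transition matrix."""
    lam = np.linalg.eigvals(T)
    lam = np.sort(np.abs(lam))[::-1][1:]  # drop the unit eigenvalue
    out = np.full(lam.shape, np.inf)
    ok = lam < 1.0 - 1e-12
    pos = ok & (lam > 0)
    out[pos] = -lag / np.log(lam[pos])
    out[~ok] = np.inf
    out[lam <= 0] = 0.0
    return out


def make_metastable_chain(n_macro: int,
                          micro_per_macro: int,
                          intra_rate: float,
                          inter_rate: float,
                          seed: int,
                          *,
                          macro_weights=None,
                          adjacency: str = "chain",
                          nonadjacent_factor: float = 0.1,
                          target_escape: float = 0.5,
                          lag_unit: float = 20.0) -> GroundTruthChain:
    """Build a block-structured, row-stochastic metastable chain.

    Connectivity weights are ``intra_rate`` within a macrostate and
    ``inter_rate`` between macrostates (``adjacency='chain'`` restricts
    full inter-macrostate weight to neighbours along the macrostate order,
    scaling the rest by ``nonadjacent_factor``; ``'full'`` treats all
    macrostate pairs alike).  ``macro_weights`` fixes the stationary
    macrostate populations exactly; by default they are uniform.
    ``target_escape`` sets the largest single-state escape probability per
    step, i.e. the overall speed of the chain.
    """
    if not (0 <= inter_rate < intra_rate <= 1):
        raise ValueError("need 0 <= inter_rate < intra_rate <= 1")
    if n_macro < 2 or micro_per_macro < 1:
        raise ValueError("need n_macro >= 2 and micro_per_macro >= 1")
    if not 0 < target_escape < 1:
        raise ValueError("target_escape must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = n_macro * micro_per_macro
    macro = np.repeat(np.arange(n_macro), micro_per_macro)

    if macro_weights is None:
        macro_weights = np.full(n_macro, 1.0 / n_macro)
    macro_weights = np.asarray(macro_weights, dtype=float)
    if macro_weights.shape != (n_macro,) or np.any(macro_weights <= 0):
        raise ValueError("macro_weights must be positive, one per macrostate")
    macro_weights = macro_weights / macro_weights.sum()

    # stationary vector: macrostate mass split heterogeneously over members
    pi = np.empty(n)
    for a in range(n_macro):
        w = rng.uniform(0.6, 1.4, micro_per_macro)
        pi[macro == a] = macro_weights[a] * w / w.sum()

    # symmetric connectivity c_ij -> detailed-balance T
    scale = np.where(macro[:, None] == macro[None, :], intra_rate, inter_rate)
    if adjacency == "chain":
        far = np.abs(macro[:, None] - macro[None, :]) > 1
        scale = np.where(far, inter_rate * nonadjacent_factor, scale)
    elif adjacency != "full":
        raise ValueError("adjacency must be 'chain' or 'full'")
    u = rng.uniform(0.8, 1.2, (n, n))
    c = np.triu(u, 1)
    c = c + c.T
    c *= scale

    K = c * pi[None, :]              # off-diagonal transition weights
    np.fill_diagonal(K, 0.0)
    escape = K.sum(axis=1)
    if escape.max() == 0:
        raise ValueError("chain has no transitions at all")
    delta = target_escape / escape.max()
    T = K * delta
    np.fill_diagonal(T, 1.0 - T.sum(axis=1))
    if np.any(np.diag(T) < 0) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
        raise RuntimeError("constructed matrix is not row-stochastic")

    chain = GroundTruthChain(T_true=T, macro_of_micro=macro, pi_true=pi,
                             lag_unit=lag_unit, macro_weights=macro_weights)
    gap = chain.metastability_gap()
    if inter_rate > 0 and np.isfinite(gap) and gap <= 1.0:
        raise RuntimeError("requested rates produce no metastability gap")
    return chain


def ago_like_chain(seed: int = 0, *, micro_per_macro: int = 5,
                   intra_rate: float = 1.0, inter_rate: float = 0.012,
                   lag_unit: float = 20.0) -> GroundTruthChain:
    """The default seven-macrostate, 35-microstate Ago-like chain.

    Macrostates are ordered along the opening coordinate (five closed,
    partially open, open) with the reported equilibrium populations; the
    slowest relaxation sits at a few hundred lag steps so that it is
    resolvable from the default synthetic dataset.
    """
    return make_metastable_chain(
        n_macro=7, micro_per_macro=micro_per_macro,
        intra_rate=intra_rate, inter_rate=inter_rate, seed=seed,
        macro_weights=AGO_MACRO_WEIGHTS, adjacency="chain",
        lag_unit=lag_unit)


@dataclass
class EmissionModel:
    """State-conditional isotropic Gaussian emissions.

    ``centers`` has one row per microstate (Å); ``noise_sd`` is the
    isotropic standard deviation (Å).
    """

    centers: np.ndarray
    noise_sd: float

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim == 1:
            self.centers = self.centers[:, None]
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("non-finite emission center")

    @property
    def n_states(self) -> int:
        return self.centers.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.centers.shape[1]


def ago_like_emission(chain: GroundTruthChain, seed: int = 0, *,
                      macro_centers=AGO_MACRO_CENTERS,
                      jitter: float = 0.5,
                      noise_sd: float = 0.4) -> EmissionModel:
    """1-D c.o.m.-distance-like emissions for an Ago-like chain.

    Each microstate's center is its macrostate center plus a small seeded
    jitter; macrostate centers must be separated by at least 3×noise_sd.
    """
    macro_centers = np.asarray(macro_centers, dtype=float)
    if macro_centers.shape != (chain.n_macro,):
        raise ValueError("one center per macrostate required")
    gaps = np.abs(np.diff(np.sort(macro_centers)))
    if np.any(gaps < 3 * noise_sd):
        raise ValueError("macrostate centers closer than 3 x noise_sd")
    rng = np.random.default_rng(seed)
    centers = macro_centers[chain.macro_of_micro] + \
        rng.uniform(-jitter, jitter, chain.n_micro)
    return EmissionModel(centers=centers[:, None], noise_sd=noise_sd)


def _sample_path(T: np.ndarray, start: int, n_steps: int,
                 rng: np.random.Generator) -> np.ndarray:
    cum = [row.cumsum().tolist() for row in T]
    r = rng.random(n_steps - 1)
    out = np.empty(n_steps, dtype=np.int64)
    out[0] = s = int(start)
    for k in range(n_steps - 1):
        s = bisect.bisect_right(cum[s], r[k])
        out[k + 1] = s
    return out


def simulate_chain(chain: GroundTruthChain, n_traj: int, n_steps: int,
                   start_states=None, seed: int = 0) -> TrajectoryEnsemble:
    """Sample discrete label trajectories from the rows of ``T_true``.

    ``start_states`` is one microstate per trajectory; by default starts
    are drawn from the stationary distribution.  The saving interval of
    the returned ensemble equals ``chain.lag_unit``.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    rng = np.random.default_rng(seed)
    if start_states is None:
        start_states = rng.choice(chain.n_micro, size=n_traj, p=chain.pi_true)
    start_states = np.asarray(start_states, dtype=int)
    if start_states.shape != (n_traj,):
        raise ValueError("need one start state per trajectory")
    if np.any(start_states < 0) or np.any(start_states >= chain.n_micro):
        raise ValueError("start state out of range")
    series = [_sample_path(chain.T_true, s, n_steps, rng) for s in start_states]
    return TrajectoryEnsemble(series, dt=chain.lag_unit,
                              meta={"seed": int(seed), "kind": "labels"})


def emit_features(labels: TrajectoryEnsemble, emission: EmissionModel,
                  seed: int = 0) -> TrajectoryEnsemble:
    """Continuous features: per-frame emission center plus Gaussian noise."""
    if not labels.is_discrete:
        raise ValueError("emit_features expects a discrete label ensemble")
    hi = max(int(s.max()) for s in labels)
    if hi >= emission.n_states:
        raise ValueError("label without an emission center")
    rng = np.random.default_rng(seed)
    series = []
    for s in labels:
        noise = rng.normal(0.0, emission.noise_sd, (len(s), emission.feature_dim))
        series.append(emission.centers[s] + noise)
    return TrajectoryEnsemble(series, dt=labels.dt,
                              meta={**labels.meta, "kind": "features",
                                    "noise_sd": emission.noise_sd})


# ---------------------------------------------------------------------------
# toy protein/RNA complexes
# ---------------------------------------------------------------------------

# atom-name pool for RNA contact pseudo-atoms; the first two realise
# phosphate oxygens so that some contacts double as salt bridges
_RNA_ATOM_POOL = ("OP1", "OP2", "C1'", "C2'", "C3'", "C4'", "C5'",
                  "N1", "N3", "O2", "O4'", "N7")
_RNA_RES_NAMES = ("U", "A", "G", "C")

FIVE_PRIME_NUCS = frozenset(range(1, 11))
THREE_PRIME_NUCS = frozenset(range(11, 21))


@dataclass
class AtomTable:
    """Plain-array atom records for one molecule of a toy complex."""

    res_ids: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    res_names: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    def copy(self) -> "AtomTable":
        return AtomTable(self.res_ids.copy(), self.atom_names.copy(),
                         self.elements.copy(), self.res_names.copy(),
                         self.coords.copy())


@dataclass
class ToyComplex:
    """Synthetic pseudo-atom protein/RNA complex with known native contacts.

    One CA plus one NZ pseudo-atom per protein residue and a P/O5' backbone
    plus per-contact pseudo-atoms per nucleotide — just enough geometry to
    exercise any-heavy-atom 4 Å contact logic, per-terminus bookkeeping and
    salt-bridge detection.  Not a physical model.
    """

    protein: AtomTable
    rna: AtomTable
    native_contacts: frozenset

    def copy(self) -> "ToyComplex":
        return ToyComplex(self.protein.copy(), self.rna.copy(),
                          frozenset(self.native_contacts))

    def translate_rna(self, vec) -> "ToyComplex":
        out = self.copy()
        out.rna.coords = out.rna.coords + np.asarray(vec, dtype=float)
        return out

    def transform(self, rotation: np.ndarray, translation) -> "ToyComplex":
        """Rigid motion applied to the whole complex."""
        out = self.copy()
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        out.protein.coords = out.protein.coords @ R.T + t
        out.rna.coords = out.rna.coords @ R.T + t
        return out

    def to_atom_array(self):
        """Biotite ``AtomArray`` view (chain A = protein, chain B = RNA)."""
        import biotite.structure as struc

        n = len(self.protein.res_ids) + len(self.rna.res_ids)
        arr = struc.AtomArray(n)
        arr.coord = np.concatenate([self.protein.coords, self.rna.coords])
        arr.chain_id = np.concatenate(
            [np.full(len(self.protein.res_ids), "A"),
             np.full(len(self.rna.res_ids), "B")])
        arr.res_id = np.concatenate([self.protein.res_ids, self.rna.res_ids])
        arr.res_name = np.concatenate(
            [self.protein.res_names, self.rna.res_names]).astype(str)
        arr.atom_name = np.concatenate(
            [self.protein.atom_names, self.rna.atom_names]).astype(str)
        arr.element = np.concatenate(
            [self.protein.elements, self.rna.elements]).astype(str)
        arr.hetero = np.zeros(n, dtype=bool)
        return arr


def _build_complex(residue_ids, nucleotide_ids, contacts) -> ToyComplex:
    residue_ids = list(residue_ids)
    nucleotide_ids = list(nucleotide_ids)
    res_x = {r: 10.0 * i for i, r in enumerate(residue_ids)}
    nuc_x = {u: 10.0 * j for j, u in enumerate(nucleotide_ids)}

    p_res, p_name, p_elem, p_resn, p_xyz = [], [], [], [], []
    for r in residue_ids:
        p_res += [r, r]
        p_name += ["CA", "NZ"]
        p_elem += ["C", "N"]
        p_resn += ["LYS", "LYS"]
        p_xyz += [(res_x[r], 0.0, 0.0), (res_x[r], 1.2, 0.0)]

    per_nuc = {u: [] for u in nucleotide_ids}
    for (r, u) in sorted(contacts):
        per_nuc[u].append(r)

    r_res, r_name, r_elem, r_resn, r_xyz = [], [], [], [], []
    for j, u in enumerate(nucleotide_ids):
        resn = _RNA_RES_NAMES[j % 4] if u != 1 else "U"
        r_res += [u, u]
        r_name += ["P", "O5'"]
        r_elem += ["P", "O"]
        r_resn += [resn, resn]
        r_xyz += [(nuc_x[u], 30.0, 0.0), (nuc_x[u], 31.0, 0.0)]
        for k, r in enumerate(per_nuc[u]):
            name = (_RNA_ATOM_POOL[k] if k < len(_RNA_ATOM_POOL)
                    else f"C{k + 10}")
            r_res.append(u)
            r_name.append(name)
            r_elem.append(name[0])
            r_resn.append(resn)
            # 3.4 A above the residue's NZ: inside the 4 A cutoff for this
            # residue, >= 9 A from every other residue's atoms
            r_xyz.append((res_x[r] + 0.1 * (j % 5), 1.2 + 3.4, 0.0))

    def _table(res, name, elem, resn, xyz):
        return AtomTable(np.array(res, dtype=int), np.array(name, dtype=object),
                         np.array(elem, dtype=object), np.array(resn, dtype=object),
                         np.array(xyz, dtype=float))

    return ToyComplex(_table(p_res, p_name, p_elem, p_resn, p_xyz),
                      _table(r_res, r_name, r_elem, r_resn, r_xyz),
                      frozenset(contacts))


def make_toy_complex(n_residues: int, n_nucleotides: int, n_contacts: int,
                     seed: int = 0, *, contact_plan=None) -> ToyComplex:
    """Toy complex with exactly ``n_contacts`` residue–nucleotide contacts.

    Under 4 Å any-heavy-atom extraction exactly the planned pairs are in
    contact; every other residue–nucleotide pair is at least 5 Å apart.
    ``contact_plan`` fixes the pairs explicitly; otherwise they are drawn
    without replacement from the seeded RNG.
    """
    if n_residues < 1 or n_nucleotides < 1:
        raise ValueError("need at least one residue and one nucleotide")
    if n_contacts > n_residues * n_nucleotides:
        raise ValueError("more contacts requested than available pairs")
    residue_ids = list(range(1, n_residues + 1))
    nucleotide_ids = list(range(1, n_nucleotides + 1))
    if contact_plan is None:
        rng = np.random.default_rng(seed)
        flat = rng.choice(n_residues * n_nucleotides, size=n_contacts,
                          replace=False)
        contact_plan = [(residue_ids[i // n_nucleotides],
                         nucleotide_ids[i % n_nucleotides]) for i in flat]
    contacts = set(map(tuple, contact_plan))
    if len(contacts) != n_contacts:
        raise ValueError("contact plan contains duplicates or wrong count")
    for (r, u) in contacts:
        if r not in residue_ids or u not in nucleotide_ids:
            raise ValueError("contact plan references unknown residue/nucleotide")
    return _build_complex(residue_ids, nucleotide_ids, contacts)


def perturb_pose(complex_: ToyComplex, keep_contacts, displacement: float = 20.0,
                 seed: int = 0) -> ToyComplex:
    """Pose preserving exactly ``keep_contacts`` under 4 Å extraction.

    RNA pseudo-atoms realising the broken contacts are displaced away from
    the interface by at least 10 Å; preserved contact atoms receive a tiny
    seeded jitter (< 0.2 Å) so the pose is never byte-identical to the
    native complex.
    """
    keep = frozenset(map(tuple, keep_contacts))
    if not keep <= complex_.native_contacts:
        raise ValueError("keep_contacts must be a subset of native contacts")
    if displacement <= 0:
        raise ValueError("displacement must be positive")
    shift = max(displacement, 10.0)
    rng = np.random.default_rng(seed)
    out = complex_.copy()

    prot_nz = {r: complex_.protein.coords[
        (complex_.protein.res_ids == r) & (complex_.protein.atom_names == "NZ")][0]
        for r in np.unique(complex_.protein.res_ids)}
    for i in range(len(out.rna.res_ids)):
        if out.rna.atom_names[i] in ("P", "O5'"):
            continue
        u = int(out.rna.res_ids[i])
        # which residue does this pseudo-atom realise a contact with?
        d = np.linalg.norm(np.stack(list(prot_nz.values())) - out.rna.coords[i],
                           axis=1)
        r = int(list(prot_nz.keys())[int(np.argmin(d))])
        if (r, u) in keep:
            out.rna.coords[i] += rng.uniform(-0.1, 0.1, 3)
        else:
            out.rna.coords[i, 1] += shift
    return ToyComplex(out.protein, out.rna, keep)


def synthetic_crystal_analog(seed: int = 0) -> ToyComplex:
    """Synthetic stand-in for a protein–miRNA crystal complex.

    60 residues and 20 nucleotides with 48 native contacts distributed as
    in the reference complex this package emulates: 43 contacts on the 5'
    half of the RNA (nucleotides 1–10) and 5 on the 3' half (11–20).
    This is a generated fixture, not crystallographic data.
    """
    rng = np.random.default_rng(seed)
    n_res = 60
    five = sorted(FIVE_PRIME_NUCS)
    three = sorted(THREE_PRIME_NUCS)

    def draw(nucs, count):
        all_pairs = [(r, u) for r in range(1, n_res + 1) for u in nucs]
        idx = rng.choice(len(all_pairs), size=count, replace=False)
        return [all_pairs[i] for i in idx]

    plan = draw(five, 43) + draw(three, 5)
    return make_toy_complex(n_res, 20, 48, seed=seed, contact_plan=plan)
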