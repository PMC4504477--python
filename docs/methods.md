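# Methods

## The model

The package treats conformational dynamics as a discrete-state,
discrete-time Markov chain.  Conformations are grouped into microstates
and the dynamics are summarized by the transition probability matrix
`T(τ)` at lag time `τ`; populations propagate by the first-order master
equation `p(nτ) = p(0) Tⁿ(τ)`.  The model is useful when `τ` exceeds the
intra-state relaxation time, which is exactly what the state
decomposition enforces.

### APM state decomposition

The residence-time criterion uses the escape probability

```
P(i, t) = 1 − [Σ_j Σ_k δ(m_j(ks) − i) δ(m_j(ks + t) − i)] /
              [Σ_j Σ_k δ(m_j(ks) − i)]
```

counted over all sliding-window frame pairs `(ks, ks + t)` within each
trajectory (`s` = saving interval, `m_j(t)` = state label).  The
lifetime `t_i` is the first crossing of `P(i, t_i) = 1 − 1/e`, linearly
interpolated between grid points (grid spacing = `s`); states that never
cross within the grid are treated as infinitely long-lived.  Note that
by this pair-counting definition `P(i, t)` saturates at `1 − π_i`, so a
state holding more than `1/e` of the equilibrium population can never
relax — such states are always split further, which is the intended
behaviour for a metastability-bounded decomposition.

The decomposition loop is: (1) binary K-centers split of all frames
(greedy max-min; first center drawn from the seed, ties broken toward
the lowest frame index); (2) recursive binary re-splitting of every
state with `t_i ≥ t0`; (3) spectral lumping of the microstates into
macrostates — seeded multi-restart k-means on the rows of the top
`n_macro` right eigenvectors of `T`, samples weighted by the stationary
distribution; (4) re-splitting within the current macrostates and
re-lumping until the frame-level macrostate partition is unchanged
(`max_iter` bound with a warning otherwise).  A minimum-population floor
(default 10 frames) stops pathological splitting; floor-limited states
are flagged and exempted from the lifetime requirement.  The macrostate
count is either fixed or chosen at the largest ratio gap in the
implied-timescale spectrum (`k` slow modes ⇒ `k + 1` macrostates).

### Estimation, validation, kinetics

Transition counts are sliding-window by default (every frame is a start
point, matching the escape-probability convention); a strided variant
exists.  Counts are restricted to the largest strongly connected
component before row-normalization (`nonreversible` default) or
symmetrization (`(C + Cᵀ)/2`, detailed balance by construction).  The
stationary vector is the leading left eigenvector, renormalized.

Validation follows standard practice: implied timescales
`τ_t = −τ/ln λ_k` re-estimated per lag (complex eigenvalue pairs are
reported by modulus with a warning); the residence test compares the
counted stay probability `1 − P(i, t)` with the MSM return probability
`[Tⁿ]_ii` — the return probability is used deliberately because it is
the exact model-side counterpart of the pair-counting estimator.  The
counted curve's standard error uses an effective start count
`starts/m` at `t = m·s`, since sliding windows of length `t` overlap
`m` starts; a decomposition that hides internal barriers shows the
characteristic failure of the MSM curve decaying significantly faster
than the counted one (flagged when significantly-fast grid points are
frequent and dominate).  Split-half cross-validation partitions whole
trajectories (even/odd by default) and re-runs a user-supplied statistic
on each half; the bootstrap resamples N trajectories with replacement,
N times per replicate, with N replicates by default, and reports the
replicate standard deviation (failed replicates are dropped and
counted).

MFPTs solve `X_if = Σ_j T_ij (τ + X_jf)` with `X = 0` on the final set;
macrostate MFPTs set `X = 0` on all microstates of the final macrostate
and average over the initial macrostate's microstates weighted by the
stationary populations renormalized within it.  Times are internal in
ns and reported in μs.  TPT committors solve the harmonic boundary-value
problem; the backward committor is computed on the time-reversed chain
so nonreversible estimates remain valid (it reduces to `1 − q⁺` under
detailed balance).  Gross flux `f_ij = π_i q⁻_i T_ij q⁺_j` is
antisymmetrized to net flux and decomposed by repeatedly removing the
widest (maximum-bottleneck) source-to-sink path — lexicographic
tie-breaking, flux subtracted along the path — until the boundary flux
is exhausted; microstate pathways lump to macrostate pathways by mapping
and collapsing consecutive repeats, preserving total flux.
Inter-macrostate transition times from sampled traces are measured, per
event, either from the last frame in the source group before arrival
("last_exit", the transit time, default) or from the first entry into
the source group ("first_entry", the waiting time that matches the
MFPT); the convention is explicit because the two differ substantially.

### Structural metrics

Contacts are residue–nucleotide pairs with any heavy-atom distance
strictly below 4 Å (hydrogens ignored; a pair at exactly 4.0 Å is out).
`f_nat` counts *preserved native* contacts over the native total, the
CAPRI reading that keeps the fraction in [0, 1]; a raw-count mode is
available.  Docking success requires ≥ 2 preserved native contacts at
each RNA terminus.  Interface RMSD superposes (Kabsch) the backbone
atoms of reference residues/nucleotides having any heavy atom within
10 Å of the partner, and evaluates the RMSD on those same atoms — the
10 Å interface definition is the package's convention.  Salt bridges are
basic side-chain nitrogens (Lys NZ, Arg NH1/NH2/NE) within 4 Å of
phosphate oxygens (OP1/OP2, O1P/O2P).  The 5' pocket distance is the
minimum heavy-atom distance between nucleotide U1 and the pocket
residue set K533/Q545/K566/K570/R812 (crystal numbering; configurable).

### Featurization

Frames are least-squares superposed on a reference selection (PIWI-core
Cα in the original analysis); clustering features are the concatenated
Cartesian coordinates of the PIWI-loop Cα atoms plus every 3rd Cα of
the PAZ-L1L2 selection, so pairwise frame distance is plain Euclidean
distance and the stride alone balances the two regions.  The stride
phase starts at the first residue of the selection.  The major-loop
angle is measured at the centre of mass of the rigid core between the
vector to the loop-tip Cα (D823 by default) and the vector to the
centre of mass of the loop anchors (V818/D838); the original figure
describes intent rather than exact geometry, so all three points are
configurable and this construction is a documented convention.  Mass
weighting uses standard atomic masses, unit mass for unknown
pseudo-atoms; frames with non-finite coordinates are rejected.

## Synthetic data: what it emulates and what it does not

No MD dataset is available, so the generator defines the study
conditions.  The default "Ago-like" chain has 7 macrostates × 5
microstates ordered along the opening coordinate (five closed, one
partially open, one open), built under detailed balance
(`T_ij = Δ c_ij π_j`, `c` symmetric) so that the stationary vector is
exact by construction: macrostate populations 19.0 % (open), 55.8 %
(partially open) and 25.2 % shared unevenly over the closed states — the
equilibrium split the analysis is meant to recover.  Emissions are 1-D
state-conditional Gaussians on the c.o.m.-distance axis: closed centers
at 10–22 Å, partially open near 27 Å, open near 40 Å (tails reaching
~46 Å), noise σ = 0.4 Å with a ±0.5 Å per-microstate jitter.  The noise
is small enough that adjacent basins (3 Å apart) overlap only mildly
(< 1 % boundary misassignment), which is what makes a 1-D
discretization recoverable at all.

Timescales are deliberately scaled down: one chain step is 20 ns (the
production lag of the original analysis), inter-macrostate connectivity
0.012 relative to intra, giving a slowest relaxation of ~750 steps
(~15 μs) and closed↔open MFPTs of tens of μs.  At the default problem
size (10 × 100,000 steps) this yields thousands of slow-transition
events, so populations and the slowest timescale are estimable to a few
percent; at the original paper's sub-sampled regime (~8 μs of MD for
tens-of-μs MFPTs) they would not be.  Consequently, passing tests show
that the pipeline recovers a known metastable generative process from
finite data; they do not show that ~8 μs of real MD suffices for hAgo2,
nor anything about force-field accuracy, the realism of 1-D features,
or memory effects absent from a generator that is Markovian by
construction.

The default analysis settings on this synthetic data are `t0 = 400 ns`
(20 steps: above the intra-macrostate relaxation of a few steps, far
below macrostate residence) and production lag 200 ns (10 steps), the
point where the implied-timescale curves have levelled off — the same
lag-selection procedure as the original analysis, applied at this
generator's scale.  `APMConfig` defaults (`t0 = 20 ns`, `lag = 20 ns`)
mirror the reference MD settings for data saved every 20 ps.

Toy complexes are pseudo-atom constructions: one CA + NZ per residue
(10 Å spacing), P/O5' backbone plus one pseudo-atom per planned contact
per nucleotide, placed 3.4 Å from the contacted residue's NZ and ≥ 9 Å
from every other residue, so the 4 Å extractor recovers exactly the
planned contact list and all other pairs are ≥ 5 Å apart.  The first
two contact atoms of each nucleotide are phosphate oxygens, so a subset
of contacts double as salt bridges.  The crystal-analog fixture (60
residues, 20 nucleotides) plans 48 contacts, 43 on the 5' half
(nucleotides 1–10) and 5 on the 3' half — the published contact
bookkeeping of the reference binary complex — and is labelled synthetic
throughout: it shares no geometry with the real crystal structure.

## Numerical choices

- Stationary vectors: dense left eigendecomposition, eigenvalue nearest
  1, absolute value, renormalized.
- Lumping tolerates relative imaginary parts up to 0.05 in the dominant
  eigenvalues (warning above 1e-8), clustering on real parts; beyond
  that it errors rather than guessing.
- K-centers: first center drawn from the seed, ties to the lowest frame
  index — bit-reproducible decompositions under fixed seeds.
- Macrostates are numbered by descending population, making labels
  comparable across refits of the same dataset.
- MFPT/committor systems use dense `numpy.linalg.solve`; singular
  systems (absorbing traps outside the final set, intermediates cut off
  from the sink) raise instead of returning garbage.
- Greedy backtracking stops at a residual flux of `total × 1e-12`.
- Degenerate inputs error loudly: empty selections, zero-mass groups,
  collinear angle geometry, empty native contact sets, non-finite
  coordinates, lags that are not multiples of the saving interval.

## Known limitations

- The 1-D feature space of the default synthetic conditions understates
  the discretization difficulty of real high-dimensional MD data; at
  short lags the slow eigenvalues are biased low (classic
  discretization error), which is why the production lag sits where the
  implied timescales level off.
- No reversible maximum-likelihood estimator with detailed-balance
  constraints (only the symmetrized estimator), no Bayesian/HMM
  estimation, no TICA — out of scope by design.
- Contact granularity is residue–nucleotide; atom–atom counting is not
  exposed (the `q` totals would differ).
- `escape_profile` is O(frames × grid) per round; adequate to ~10⁶
  frames × tens of grid points, not tuned beyond that.
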