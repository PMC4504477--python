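# agomsm

Markov state model (MSM) analysis of the opening dynamics of human
Argonaute-2 (hAgo2) and the kinetics of miRNA loading, packaged as a
tested, reusable pipeline for structural bioinformatics users who work
with MD trajectory ensembles and protein–RNA docking poses.

Apo hAgo2 interconverts among closed, partially open and open
conformations of its miRNA binding groove; the open state — with a large
centre-of-mass (c.o.m.) distance between the PAZ domain and the PIWI
loops — is the one that can geometrically admit a miRNA, which then
drives structural re-arrangement toward the bound complex
(conformational selection followed by induced fit).  This package
implements the quantitative machinery behind that picture:

- **APM state decomposition** — residence-time-bounded splitting:
  geometric K-centers clustering is refined until every microstate's
  escape probability `P(i,t)` (sliding-window pair counting) reaches
  `1 − 1/e` before the residence threshold `t0`, then microstates are
  lumped into metastable macrostates by spectral clustering of the
  transition matrix `T(τ)`, iterating re-splitting and re-lumping to a
  fixed point.
- **MSM estimation and validation** — maximum-likelihood `T(τ)` on the
  largest strongly connected set, first-order propagation
  `p(nτ) = p(0) Tⁿ(τ)`, implied timescales `τ_t = −τ/ln λ_k`,
  residence-probability tests and trajectory bootstrap (N-for-N with
  replacement).
- **Kinetics** — mean first passage times from the linear system
  `X_if = Σ_j T_ij (τ + X_jf)` with `X_ff = 0`, population-weighted
  macrostate MFPTs, synthetic long trajectories sampled from `T`, and
  transition-path-theory committors/flux with greedy-backtracking
  (widest-path) pathway decomposition.
- **Docking-pose metrics** — native-contact extraction at a strict 4 Å
  heavy-atom cutoff, `f_nat = q_pose/q_crystal`, the per-terminus
  success rule (≥ 2 preserved native contacts at each miRNA terminus),
  interface RMSD (CAPRI-style 10 Å interface), salt-bridge retention and
  the 5'-nucleotide pocket distance.
- **Synthetic ground truth** — seven-macrostate metastable chains with
  Gaussian c.o.m.-distance emissions and toy protein/RNA complexes with
  an exactly known contact list, so every stage is testable end to end
  without external data.

## Worked example

Fit the model to the default synthetic conditions (10 trajectories of
100,000 steps at a 20 ns saving interval, 35 hidden microstates in 7
macrostates):

```python
from agomsm import (MarkovStateModel, ago_like_chain, ago_like_emission,
                    emit_features, simulate_chain)

chain = ago_like_chain(seed=0)                      # ground truth
labels = simulate_chain(chain, n_traj=10, n_steps=100_000, seed=1)
features = emit_features(labels, ago_like_emission(chain, seed=2), seed=3)

res = MarkovStateModel.from_features(features, lag=200.0, t0=400.0,
                                     seed=4).fit()
print(res.summary())
```

```
Markov State Model Results
============================================================
Trajectories:               10
Frames:                     1000000
Lag time (ns):              200
Residence threshold t0 (ns):400
Microstates (connected):    38 of 38
Macrostates:                7
Estimator:                  nonreversible
------------------------------------------------------------
Macrostate populations
  macro0      56.7 %   (7 microstates)
  macro1      18.8 %   (6 microstates)
  ...
```

Macrostates are numbered by descending population, so `macro0` is the
partially open state (true population 55.8 %) and `macro1` the open
state (true population 19.0 %); the fit recovers both within sampling
error, along with the macrostate count (7, from the gap between the 6th
and 7th implied timescales).  Kinetics hang off the results object:

```python
res.mfpt(1, 0, units="us")        # open -> partially open: 3.7 us
res.pathways([2, 3, 4, 5, 6], [1])  # closed -> open flux pathways;
                                     # the top one carries ~47% of flux
```

The command line mirrors the library (`agomsm run`, `simulate`, `build`,
`dockeval`); `agomsm build --t0 20 --lag 20` applies the reference
settings of a 20 ns residence threshold and 20 ns lag to MD-style
feature tables saved every 20 ps.

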