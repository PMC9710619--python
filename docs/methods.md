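# Methods

## Model

`netdiffuse` models signal transduction as discrete diffusion on an
undirected protein–protein interaction (PPI) subgraph connecting
cell-surface receptors, intracellular transducers and transcription
factors (TFs).  For one sample, each edge (i, j) carries a diffusivity

w_ij = (α E_i)(α E_j),

where E is the sample's normalized expression of the genes coding for
the two proteins and α is a dataset-wide scale (below).  One unit of
signal is placed on a source receptor, S(0) = e_source, and propagated
synchronously: the flux on edge (i, j) at step t is
F_{i→j} = (S_i − S_j)·w_ij, and each node adds the sum of its incident
fluxes, S(t+1) = S(t) − L_w S(t) with L_w the weighted graph Laplacian.
Both forms are identical; the Laplacian form is what the sparse engine
iterates.  The connectivity readout for a (receptor, TF) pair is **t50**:
the smallest t at which the TF's signal reaches 50% of its maximum over
the simulated horizon.  Small t50 means strong connectivity.

Assumptions worth stating plainly: the network is undirected and static;
expression of a gene is a proxy for the abundance, hence conductance, of
its protein at every interface; diffusion is linear (no saturation,
synthesis or degradation); and all samples share one network topology —
only the edge weights are patient-specific.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| confidence threshold | 0.6 (strict >) | — | PPI edges below this are noise-dominated |
| horizon T | 2000 | timesteps | long enough for near-equilibration on these graphs |
| t50 fraction | 0.5 | — | half-maximum crossing, first-crossing tie-break (≥) |
| expression floor ε | 1e−6 | normalized units | keeps low-expression nodes conductive, network connected |
| hub threshold | 50 | edges (strict >) | definition of a hub gene |
| TF selection α | 0.05 | — | empirical-p cutoff |
| permutations | 1000 | — | resolution 1/(N+1) ≈ 0.001 for TF empirical p-values |

### Normalization and the stability scale α

The method that produced the expression matrix is deliberately not
assumed.  Normalization divides the whole genes × samples matrix by its
single global maximum and floors at ε, so values lie in [ε, 1] and
between-sample differences are preserved (a per-sample divisor would
erase exactly the signal the method feeds on).  It follows that the t50
matrix is invariant to rescaling the entire input matrix by any positive
constant.

An explicit update S(t+1) = (I − L_w)S(t) diverges when a weighted degree
exceeds 1 and oscillates above 1/2, so one global α is calibrated once
per dataset: with raw weighted degree d_i(s) = Σ_j E_i E_j,
α = min(1, sqrt(0.5 / max_{i,s} d_i(s))).  Every weighted degree is then
≤ 0.5, making I − L_w symmetric w.r.t. the counting measure, doubly
stochastic, entrywise non-negative and positive semi-definite: mass is
conserved exactly, signals stay in [0, 1], and the dynamics relax
monotonically without oscillation.  Because α is shared across samples,
t50 values are comparable between patients; per-sample calibration would
confound connectivity with overall expression level.

### t50 extraction

The maximum is taken over the *observed* trajectory, not the theoretical
equilibrium 1/N, so the statistic is well-defined on any graph including
disconnected ones.  If a TF never receives signal (different component
from the source) the pair is a missing value (`NA` on disk), excluded
pairwise downstream rather than imputed.  t50 is an integer timestep;
crossing uses ≥ with the first crossing winning ties.

## Statistics

**Comparison designs.**  Three named comparisons are built from sample
metadata: inflamed (patients before treatment plus resistant patients
after treatment) vs non-inflamed (controls plus responders after
treatment); resistant vs responder before treatment; and male vs female
before treatment as a negative control, which is an ordinary design, not
a special case.

**Moderated t.**  Per pair, a two-group comparison with pooled variance
s²_g on d_g = n_a + n_b − 2 degrees of freedom (per-feature d_g, since
missing t50 values are handled pairwise-complete with ≥ 2 values required
per group).  Variances are shrunk towards a prior:
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), with (d₀, s₀²) estimated by
closed-form moment matching of log s²_g to a scaled-F distribution
(digamma/trigamma equations, Newton inversion of the trigamma).  The
moderated t = Δ/(s̃_g·√(1/n_a + 1/n_b)) is referred to a t distribution
with d_g + d₀ df.  d₀ = 0 recovers the ordinary pooled t; d₀ = ∞ fixes
the variance at s₀².  The implementation is cross-checked against
Bioconductor limma to ~1e−13 in the test-suite.  Zero-variance features
are excluded from hyperparameter estimation and assigned s̃² = s₀².
Multiple testing uses Benjamini–Hochberg step-up (via statsmodels),
oracle-tested against a from-scratch enumeration.

**AUC.**  Per pair, the rank-sum AUC with mid-rank ties, reported
orientation-normalized to ≥ 0.5 with the flip direction recorded, since a
discriminating pair is interesting whichever group is slower.

**PCA/PLS.**  PCA is an SVD of the column-centered matrix; PLS is the
NIPALS algorithm (scikit-learn `PLSRegression`) against a two-group
indicator.

## Procrustes comparison

Both spaces are column-centered and reduced to top-k principal-component
scores (k defaults to min(n−1, 20, p, q)); the source scores are mapped
onto the target scores by the least-squares similarity transform
(orthogonal rotation + isotropic scaling; translation vanishes after
centering), and the result is explained_fraction = 1 − RSS/TSS of the
target scores.  This is the vegan-style `procrustes` convention, and the
implementation agrees with R vegan to 1e−9 in the test-suite.  Both
directions are computed in the report; note that with isotropic scaling
the normalized statistic is symmetric when the same k is used in both
directions (1 − (Σσ)²/(‖X‖²‖Y‖²)), so the two directions differ only
through dimension-dependent k truncation.  The statistic is invariant to
positive rescaling of either space.  Covariate tables (immune-cell
infiltration, proliferation scores) are validated and centered but
estimated upstream.

## TF selection by permutation

Given a TF→target weight table, a TF's observed score is the sum of its
edge weights.  The null shuffles the (target, weight) rows jointly
against the fixed TF column: each TF keeps its edge count and the global
weight multiset is preserved exactly, but which weights a TF receives is
randomized.  The empirical p-value uses the +1/(N+1) estimator, so p ≥
1/(N+1) and is never zero; selection is p < α.  Shuffling only the target
labels (leaving weights attached to their TF rows) would leave every
observed score unchanged and make the null degenerate, so the joint
shuffle is the meaningful reading of randomizing TF–target assignment.

## Synthetic data

The generator emulates a role-annotated signalling dataset: a layered
receptor → transducer → TF graph in which receptor i carries a guaranteed
path REC_i — SIG_{i mod K} — TF_{(i mod K) mod M}, plus independent extra
edges between adjacent layers with probability `edge_prob` (chain and
star variants exist for closed-form tests).  Expression is iid lognormal
(σ = 0.25 by default — moderate microarray-like intensity skew,
non-negative by construction), and the "resistant" group is created by
multiplying chosen transducer genes by `effect_multiplier` (default 0.3,
a strong knockdown).  Planting the effect on a *transducer* rather than a
receptor or TF is deliberate: the group difference is routed through the
network and appears in connectivity space, the mechanism the method is
designed to detect.

The reference scenario is 15 receptors × 18 transducers × 15 TFs at
edge_prob 0.1 with 12 samples per group.  These sizes were chosen so the
feature space is large enough (225 pairs) for rank-percentile screening
to be meaningful while one fit takes well under a second; the designated
pair (REC01, TF01) is doubly hit — both its receptor-side and TF-side
edges pass through the knocked-down SIG01.

What the generator does **not** emulate: probe-level noise and
normalization artefacts, correlated co-expression modules, hub-dominated
scale-free topology, batch effects, or any relation between expression
and network confidence.  Passing the synthetic recovery tests therefore
demonstrates that the machinery is correct and sensitive to routed
perturbations under clean conditions, not that the biomarker generalizes
to real cohorts.

## Numerical choices and degenerate inputs

- Deterministic lexicographic node ordering everywhere; adjacency and all
  results are bit-reproducible for a given seed.
- Synchronous (Jacobi) update, matching the simultaneous flux-sum
  definition; no sequential sweeping.
- Mass conservation is asserted at the horizon (|ΣS − 1| < 1e−9) on every
  run, not only in tests.
- Duplicate interaction rows keep the maximum confidence; duplicate
  expression rows for one gene are collapsed by mean at read time with a
  logged count.
- Role genes left without any retained edge are dropped with a warning —
  they can never carry flux — rather than kept as isolated nodes.
- Floats are serialized at 17 significant digits; TSV round-trips are
  exact, and every CLI run writes a manifest (command, parameters, seed,
  versions) sufficient to reproduce its outputs bit-for-bit.
- Problem sizes in the test-suite and acceptance script (toy graphs of
  3–48 nodes, 100-graph sweeps, 10–20 seed replicates) are chosen to keep
  a full run in tens of seconds while still exercising every code path at
  the full 2000-step horizon.

## Known limitations

- Two-group designs only; covariate-adjusted (multi-factor) moderated
  models are out of scope.
- The diffusion is purely conservative: no source/sink terms, so the
  equilibrium on a connected graph is always uniform and only the
  *kinetics* (t50) carry information.
- Expression-to-conductance weighting squares the influence of a gene
  that sits on both endpoints of short paths; hub genes therefore get
  large leverage, which is exactly why the hub-gene Procrustes comparison
  is part of the standard report.
- The TF-selection permutation assumes exchangeable weights across a TF's
  targets under the null; strong target-set size effects are preserved
  (edge counts are fixed) but weight heteroscedasticity across targets is
  not modelled.
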