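# netdiffuse

Network-diffusion connectivity biomarkers for drug-response prediction
from gene expression.

In chronic inflammatory disease (the motivating setting is anti-TNF
therapy in ulcerative colitis), the difference between patients who
respond to a biologic and patients who resist it is often not visible in
single-gene differential expression: the same receptors and transcription
factors (TFs) are present, but the *signal-transduction paths between
them* carry different strength.  `netdiffuse` turns that idea into a
feature space:

1. **Network assembly.** A confidence-scored protein–protein interaction
   list is filtered (confidence strictly > 0.6 by default) and reduced to
   the subgraph induced on three role sets: cell-surface **receptors**,
   intracellular **signal transducers**, and **TFs**.  Key TFs can be
   selected beforehand from a TF→target regulatory-weight table by a
   permutation test on each TF's summed edge weight
   (empirical *p* = (1 + #{null ≥ observed}) / (1 + N)).
2. **Patient-specific diffusion.** For each sample, every network edge
   (i, j) gets the weight *w*<sub>ij</sub> = (αE<sub>i</sub>)(αE<sub>j</sub>)
   built from the sample's normalized expression E.  One unit of signal is
   placed on a receptor and spread by discrete Fick's-law diffusion,
   *F*<sub>i→j</sub> = (S<sub>i</sub> − S<sub>j</sub>)·w<sub>ij</sub>,
   S<sub>i</sub>(t+1) = S<sub>i</sub>(t) + Σ<sub>j</sub> F<sub>j→i</sub> —
   equivalently S(t+1) = (I − L<sub>w</sub>)S(t) with the weighted graph
   Laplacian L<sub>w</sub> — for 2000 timesteps.  The single global scale α
   caps every weighted degree at 0.5, so the update matrix is doubly
   stochastic: mass is conserved and signals stay in [0, 1].
3. **t50 features.** Connectivity of a (receptor, TF) pair is *t50*: the
   first timestep at which the TF's signal reaches 50% of its maximum over
   the horizon.  Stacking all pairs gives a samples × (receptors × TFs)
   matrix — e.g. 83 receptors × 58 TFs = 4814 features.
4. **Screening.** Group comparisons (inflamed vs non-inflamed, resistant
   vs responder, male vs female as a negative control) are tested per pair
   with an empirical-Bayes moderated t (limma-style variance shrinkage),
   BH-FDR corrected, and screened by rank-based AUC; PCA/PLS give
   exploratory scores, and Procrustes rotation quantifies how much of the
   t50 space is a linear shadow of the expression space (or of hub-gene
   expression, or of global covariates such as immune-cell infiltration).

## Worked example

```python
from netdiffuse import DiffusionConnectivity, SyntheticSpec
from netdiffuse.synthetic import make_expression, make_toy_network

spec = SyntheticSpec(rng_seed=0)          # 0.3x knockdown of SIG01, 12 vs 12
network, roles = make_toy_network(spec)
expression, metadata = make_expression(spec, network, roles)

model = DiffusionConnectivity(expression, network, roles, metadata=metadata)
results = model.fit()
print(results.summary())

diff = results.differential("resistant_vs_responder")
roc = results.auc_screen("resistant_vs_responder")
top = diff.nsmallest(3, "p_value")[["delta", "moderated_t", "adj_p_value"]]
top["auc"] = roc.loc[top.index, "auc"]
print(top.round(4))
```

prints

```
Network diffusion connectivity (t50) results
==============================================
samples:            24
receptors x TFs:    15 x 15 = 225 pairs
network:            48 nodes, 81 edges
horizon (steps):    2000
weight scale alpha: 0.456182
missing t50 cells:  0
t50 range:          [3, 170] steps, median 30

                 delta  moderated_t  adj_p_value     auc
receptor tf
REC01    TF01   9.7500       7.9283       0.0000  0.9931
REC14    TF01  13.1667       7.3729       0.0000  1.0000
         TF06   9.0833       4.9047       0.0041  0.9340
```

The synthetic dataset knocks the transducer SIG01 down to 0.3× in the
resistant group.  SIG01 is the path carrier between REC01 and TF01, and
the screen recovers exactly that: diffusion to TF01 takes ~10 timesteps
longer in resistant samples (positive `delta` = slower, i.e. weaker
connectivity), the moderated t is large, and the pair separates the
groups almost perfectly by AUC.

The same stages are available from the shell:

```sh
netdiffuse simulate --seed 0 --outdir run/sim
netdiffuse diffuse --expression run/sim/expression.tsv --edges run/sim/edges.tsv \
    --receptors run/sim/receptors.txt --tfs run/sim/tfs.txt \
    --transducers run/sim/transducers.txt --outdir run/diff
netdiffuse stats --t50 run/diff/t50.tsv --metadata run/sim/metadata.tsv \
    --comparison resistant_vs_responder --outdir run/stats
netdiffuse roc --t50 run/diff/t50.tsv --metadata run/sim/metadata.tsv \
    --comparison resistant_vs_responder --outdir run/roc
```

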