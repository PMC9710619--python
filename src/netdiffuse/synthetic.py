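"""Synthetic role-annotated networks and expression with planted effects.

Generates the layered receptor → transducer → TF toy networks and
lognormal expression matrices used throughout the test-suite and the
acceptance checks.  A "resistant" group is created by multiplying the
expression of chosen transducer genes by ``effect_multiplier`` < 1 — a
knockdown that weakens every edge through those transducers and therefore
slows diffusion along the routed receptor–TF paths, emulating a perturbed
signal-transduction pathway rather than a direct receptor/TF change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .diffusion import ExpressionMatrix
from .network import GeneRoleSets, SignalingNetwork, assemble_network, InteractionRecord, BuilderConfig

TOPOLOGIES = ("layered-random", "chain", "star")


def _receptor(i: int) -> str:
    return f"REC{i + 1:02d}"


def _transducer(i: int) -> str:
    return f"SIG{i + 1:02d}"


def _tf(i: int) -> str:
    return f"TF{i + 1:02d}"


@dataclass
class SyntheticSpec:
    """Study-condition parameters for one synthetic dataset.

    Defaults encode the reference scenario used in the recovery checks: a
    layered-random network of 15 receptors, 18 transducers and 15 TFs
    (edge probability 0.1 on top of guaranteed paths), 12 samples per
    group, lognormal expression noise with sigma 0.25, and a 0.3×
    knockdown of the transducer SIG01 — the guaranteed-path carrier
    linking REC01 to TF01 — in the resistant group.
    """

    n_receptors: int = 15
    n_tfs: int = 15
    n_transducers: int = 18
    topology: str = "layered-random"
    edge_prob: float = 0.1
    n_per_group: int = 12
    n_controls: int = 0
    effect_genes: tuple[str, ...] = (_transducer(0),)
    effect_multiplier: float = 0.3
    noise_sigma: float = 0.25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_receptors, self.n_tfs, self.n_transducers, self.n_per_group) < 1:
            raise ValueError("all counts must be >= 1")
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"topology must be one of {TOPOLOGIES}, got {self.topology!r}")
        if not 0.0 < self.effect_multiplier <= 1.0:
            raise ValueError("effect_multiplier must be in (0, 1]")
        transducers = {_transducer(i) for i in range(self.n_transducers)}
        if not set(self.effect_genes) <= transducers:
            raise ValueError("effect_genes must be a subset of the transducer genes")

    @property
    def planted_pair(self) -> tuple[str, str]:
        """Receptor–TF pair routed through the first effect transducer."""
        k = int(self.effect_genes[0][3:]) - 1
        return _receptor(k % self.n_receptors), _tf(k % self.n_tfs)


def make_toy_network(spec: SyntheticSpec) -> tuple[SignalingNetwork, GeneRoleSets]:
    """Layered toy network; deterministic under ``spec.rng_seed``.

    Every receptor i carries a guaranteed path
    REC_i — SIG_{i mod K} — TF_{(i mod K) mod M}; the layered-random
    topology adds independent extra edges between adjacent layers with
    probability ``edge_prob``; chain keeps only the guaranteed paths; star
    routes everything through the first transducer.
    """
    rng = np.random.default_rng((spec.rng_seed, 0))
    receptors = [_receptor(i) for i in range(spec.n_receptors)]
    transducers = [_transducer(i) for i in range(spec.n_transducers)]
    tfs = [_tf(i) for i in range(spec.n_tfs)]
    roles = GeneRoleSets(frozenset(receptors), frozenset(tfs), frozenset(transducers))
    edges: set[tuple[str, str]] = set()
    if spec.topology == "star":
        hub = transducers[0]
        edges |= {(r, hub) for r in receptors}
        edges |= {(hub, t) for t in tfs}
        edges |= {(hub, k) for k in transducers[1:]}
    else:
        for i, r in enumerate(receptors):
            edges.add((r, transducers[i % spec.n_transducers]))
        for k, t in enumerate(transducers):
            edges.add((t, tfs[k % spec.n_tfs]))
        if spec.topology == "layered-random":
            for r in receptors:
                for t in transducers:
                    if rng.random() < spec.edge_prob:
                        edges.add((r, t))
            for t in transducers:
                for f in tfs:
                    if rng.random() < spec.edge_prob:
                        edges.add((t, f))
    records = [InteractionRecord(a, b, 0.9) for a, b in sorted(edges)]
    network = assemble_network(records, roles, BuilderConfig(min_confidence=0.6))
    return network, roles


def make_expression(
    spec: SyntheticSpec, network: SignalingNetwork, roles: GeneRoleSets
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Lognormal expression with the knockdown planted in the resistant group.

    Baseline values are iid lognormal(0, noise_sigma) per gene and sample;
    resistant samples have ``effect_genes`` multiplied by
    ``effect_multiplier``.  Metadata labels responders and resistant
    patients at timepoint "before" (plus optional controls) with sex
    assigned at random.  Deterministic under ``spec.rng_seed``.
    """
    rng = np.random.default_rng((spec.rng_seed, 1))
    genes = network.nodes
    responders = [f"RESP{i + 1:02d}" for i in range(spec.n_per_group)]
    resistant = [f"RSST{i + 1:02d}" for i in range(spec.n_per_group)]
    controls = [f"CTRL{i + 1:02d}" for i in range(spec.n_controls)]
    samples = responders + resistant + controls
    values = rng.lognormal(mean=0.0, sigma=spec.noise_sigma, size=(len(genes), len(samples)))
    frame = pd.DataFrame(values, index=genes, columns=samples)
    present_effects = [g for g in spec.effect_genes if g in frame.index]
    frame.loc[present_effects, resistant] *= spec.effect_multiplier
    meta = pd.DataFrame(
        {
            "sample": samples,
            "diagnosis": ["uc"] * (2 * spec.n_per_group) + ["control"] * spec.n_controls,
            "response": ["responder"] * spec.n_per_group
            + ["resistant"] * spec.n_per_group
            + ["n/a"] * spec.n_controls,
            "timepoint": ["before"] * (2 * spec.n_per_group) + ["n/a"] * spec.n_controls,
            "sex": rng.choice(["male", "female"], size=len(samples)).tolist(),
        }
    )
    return ExpressionMatrix(frame), meta


def make_null_dataset(
    spec: SyntheticSpec | None = None,
) -> tuple[SignalingNetwork, GeneRoleSets, ExpressionMatrix, pd.DataFrame]:
    """Dataset with no planted effect (effect_multiplier = 1): both groups
    exchangeable, for type-I-error / negative-control checks."""
    spec = replace(spec or SyntheticSpec(), effect_multiplier=1.0)
    network, roles = make_toy_network(spec)
    expr, meta = make_expression(spec, network, roles)
    return network, roles, expr, meta
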