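"""Signalling-network assembly from confidence-scored interactions.

Builds the undirected receptor → transducer → transcription-factor (TF)
network on which signal diffusion runs.  Interactions come from a
confidence-scored protein–protein interaction (PPI) list; only pairs whose
confidence strictly exceeds a threshold (default 0.6) are retained.  Role
membership (receptor / transducer / TF) is supplied as plain gene lists —
no ontology lookup happens here.

Key TFs can be selected from a TF→target regulatory-weight table by a
permutation test on each TF's summed edge weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROLE_RECEPTOR = "receptor"
ROLE_TF = "tf"
ROLE_TRANSDUCER = "transducer"


class InteractionRecord(NamedTuple):
    """One undirected PPI edge with a confidence score in [0, 1]."""

    protein_a: str
    protein_b: str
    confidence: float


@dataclass(frozen=True)
class GeneRoleSets:
    """Receptor, TF and signal-transducer gene sets (symbols)."""

    receptors: frozenset[str]
    tfs: frozenset[str]
    transducers: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "receptors", frozenset(self.receptors))
        object.__setattr__(self, "tfs", frozenset(self.tfs))
        object.__setattr__(self, "transducers", frozenset(self.transducers))
        overlap = (self.receptors & self.tfs) | (self.receptors & self.transducers) | (
            self.tfs & self.transducers
        )
        if overlap:
            logger.info("role sets overlap on %d genes: %s", len(overlap), sorted(overlap)[:10])

    @property
    def universe(self) -> frozenset[str]:
        return self.receptors | self.tfs | self.transducers

    def roles_of(self, gene: str) -> frozenset[str]:
        roles = set()
        if gene in self.receptors:
            roles.add(ROLE_RECEPTOR)
        if gene in self.tfs:
            roles.add(ROLE_TF)
        if gene in self.transducers:
            roles.add(ROLE_TRANSDUCER)
        return frozenset(roles)


@dataclass
class BuilderConfig:
    """Network-construction and TF-selection parameters.

    min_confidence
        Edges are kept only when confidence is *strictly* greater than this.
    hub_degree_threshold
        A hub gene has strictly more than this many edges.
    tf_alpha
        Significance level for the TF permutation test.
    n_permutations
        Number of target/weight shuffles for the empirical null.
    rng_seed
        Seed for the permutation RNG.
    """

    min_confidence: float = 0.6
    hub_degree_threshold: int = 50
    tf_alpha: float = 0.05
    n_permutations: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ValueError(f"min_confidence must be in [0, 1], got {self.min_confidence}")
        if self.n_permutations < 1:
            raise ValueError(f"n_permutations must be >= 1, got {self.n_permutations}")


@dataclass
class SignalingNetwork:
    """Undirected role-annotated graph with deterministic node ordering.

    Nodes are ordered lexicographically so adjacency matrices and all
    downstream results are bit-reproducible.
    """

    graph: nx.Graph

    def __post_init__(self) -> None:
        for u, v in self.graph.edges():
            if u == v:
                raise ValueError(f"self-loop on {u}")

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes())

    @property
    def node_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges())

    def neighbors(self, gene: str) -> list[str]:
        return sorted(self.graph.neighbors(gene))

    def roles_of(self, gene: str) -> frozenset[str]:
        return self.graph.nodes[gene]["roles"]

    def nodes_with_role(self, role: str) -> list[str]:
        return sorted(g for g in self.graph.nodes() if role in self.graph.nodes[g]["roles"])

    @property
    def receptors(self) -> list[str]:
        return self.nodes_with_role(ROLE_RECEPTOR)

    @property
    def tfs(self) -> list[str]:
        return self.nodes_with_role(ROLE_TF)

    def adjacency(self):
        """Sparse CSR adjacency (0/1) in lexicographic node order."""
        return nx.to_scipy_sparse_array(self.graph, nodelist=self.nodes, format="csr", dtype=float)


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def filter_interactions(
    records: Iterable[InteractionRecord], config: BuilderConfig
) -> list[InteractionRecord]:
    """Keep interactions with confidence strictly above the threshold.

    Pairs are canonicalized (lexicographic order) and deduplicated keeping
    the maximum confidence.  Idempotent.
    """
    best: dict[tuple[str, str], float] = {}
    for row, rec in enumerate(records):
        a, b, c = rec
        try:
            c = float(c)
        except (TypeError, ValueError):
            raise ValueError(f"non-numeric confidence {c!r} in interaction row {row}: {a}-{b}")
        if not np.isfinite(c) or not 0.0 <= c <= 1.0:
            raise ValueError(f"confidence {c!r} outside [0, 1] in interaction row {row}: {a}-{b}")
        key = _canonical(str(a), str(b))
        if c > best.get(key, -1.0):
            best[key] = c
    return [
        InteractionRecord(a, b, c)
        for (a, b), c in sorted(best.items())
        if c > config.min_confidence
    ]


def assemble_network(
    records: Iterable[InteractionRecord],
    roles: GeneRoleSets,
    config: BuilderConfig | None = None,
) -> SignalingNetwork:
    """Induced subgraph of the filtered PPI on receptors ∪ transducers ∪ TFs.

    Self-loops are dropped; role genes left isolated after filtering are
    removed with a warning (they can never carry flux).
    """
    config = config or BuilderConfig()
    if not (roles.receptors and roles.tfs and roles.transducers):
        raise ValueError("all three role sets must be non-empty for network assembly")
    kept = filter_interactions(records, config)
    universe = roles.universe
    g = nx.Graph()
    for a, b, c in kept:
        if a == b:
            continue
        if a in universe and b in universe:
            g.add_edge(a, b, confidence=c)
    if g.number_of_edges() == 0:
        raise ValueError("no network: no interaction connects two role-annotated genes")
    isolated = sorted(universe - set(g.nodes()))
    if isolated:
        logger.warning(
            "%d role genes have no retained edge and were dropped: %s%s",
            len(isolated),
            ", ".join(isolated[:10]),
            " ..." if len(isolated) > 10 else "",
        )
    for gene in g.nodes():
        g.nodes[gene]["roles"] = roles.roles_of(gene)
    if not any(ROLE_RECEPTOR in g.nodes[n]["roles"] for n in g.nodes()):
        raise ValueError("no receptor survived network assembly")
    return SignalingNetwork(g)


@dataclass
class TFSelectionResult:
    """Permutation-test outcome for one TF."""

    tf: str
    observed_score: float
    empirical_p: float
    selected: bool


def select_key_tfs(
    grn: pd.DataFrame, config: BuilderConfig | None = None
) -> list[TFSelectionResult]:
    """Select key TFs whose summed regulatory weight beats a permutation null.

    ``grn`` has columns ``tf``, ``target``, ``weight`` with unique
    (tf, target) pairs.  The observed score of a TF is the sum of its edge
    weights.  The null shuffles the (target, weight) rows jointly against
    the fixed tf column — each TF keeps its number of edges but receives a
    random draw of weights — and the empirical p-value is
    (1 + #{null >= observed}) / (1 + n_permutations).
    """
    config = config or BuilderConfig()
    required = {"tf", "target", "weight"}
    if not required.issubset(grn.columns):
        raise ValueError(f"GRN table needs columns {sorted(required)}")
    if grn.duplicated(subset=["tf", "target"]).any():
        raise ValueError("GRN table has duplicate (tf, target) pairs")
    if not np.isfinite(grn["weight"].to_numpy(dtype=float)).all():
        raise ValueError("GRN weights must be finite")
    tfs = grn["tf"].to_numpy()
    weights = grn["weight"].to_numpy(dtype=float)
    tf_names, tf_codes = np.unique(tfs, return_inverse=True)
    if len(tf_names) < 2 or grn["target"].nunique() < 2:
        raise ValueError("need at least 2 TFs and 2 targets for the permutation test")
    observed = np.bincount(tf_codes, weights=weights, minlength=len(tf_names))
    rng = np.random.default_rng(config.rng_seed)
    exceed = np.zeros(len(tf_names), dtype=int)
    for _ in range(config.n_permutations):
        perm = rng.permutation(len(weights))
        null = np.bincount(tf_codes, weights=weights[perm], minlength=len(tf_names))
        exceed += null >= observed
    pvals = (1.0 + exceed) / (1.0 + config.n_permutations)
    return [
        TFSelectionResult(tf=str(t), observed_score=float(o), empirical_p=float(p),
                          selected=bool(p < config.tf_alpha))
        for t, o, p in zip(tf_names, observed, pvals)
    ]


def hub_genes(network: SignalingNetwork, config: BuilderConfig | None = None) -> set[str]:
    """Nodes with strictly more than ``hub_degree_threshold`` edges."""
    config = config or BuilderConfig()
    thr = config.hub_degree_threshold
    return {g for g, d in network.graph.degree() if d > thr}
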