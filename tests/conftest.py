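"""Shared fixtures and independent reference implementations.

The reference implementations here are deliberately naive (per-node flux
loops, explicit step-up enumeration, concordant-pair counting) so they
stay independent of the library code paths they check.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netdiffuse.network import GeneRoleSets, SignalingNetwork


def build_network(edges, receptors=(), tfs=(), transducers=()):
    """Construct a SignalingNetwork directly from an edge list (tests only)."""
    roles = GeneRoleSets(frozenset(receptors), frozenset(tfs), frozenset(transducers))
    g = nx.Graph()
    for a, b in edges:
        g.add_edge(a, b)
    for gene in g.nodes():
        g.nodes[gene]["roles"] = roles.roles_of(gene)
    return SignalingNetwork(g), roles


def dense_diffusion_reference(nodes, weight, source, horizon):
    """Naive per-node flux-sum diffusion: returns (horizon+1) × n signals.

    ``weight`` is a dict {(i, j): w} over undirected edges (node names).
    Each step adds sum_j (S_j - S_i) * w_ij to node i.
    """
    idx = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros((n, n))
    for (a, b), val in weight.items():
        w[idx[a], idx[b]] = val
        w[idx[b], idx[a]] = val
    s = np.zeros(n)
    s[idx[source]] = 1.0
    out = np.empty((horizon + 1, n))
    out[0] = s
    for t in range(1, horizon + 1):
        flux = np.zeros(n)
        for i in range(n):
            for j in range(n):
                if w[i, j] > 0:
                    flux[i] += (s[j] - s[i]) * w[i, j]
        s = s + flux
        out[t] = s
    return out


def bh_reference(pvalues):
    """Step-up BH from first principles: adj_(i) = min_{j>=i} m p_(j)/j, clamped."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        adj_sorted[rank - 1] = running
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def auc_reference(values_a, values_b):
    """Concordant-pair counting with half credit for ties (unnormalized orientation)."""
    score = 0.0
    for va in values_a:
        for vb in values_b:
            if va > vb:
                score += 1.0
            elif va == vb:
                score += 0.5
    return score / (len(values_a) * len(values_b))


@pytest.fixture
def two_node():
    """Two-node receptor→TF network: closed-form diffusion testbed."""
    net, roles = build_network([("A", "B")], receptors=["A"], tfs=["B"], transducers=["Z"])
    return net, roles


@pytest.fixture
def chain_network():
    """Receptor — transducer — TF chain."""
    return build_network(
        [("R1", "K1"), ("K1", "T1")], receptors=["R1"], tfs=["T1"], transducers=["K1"]
    )
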