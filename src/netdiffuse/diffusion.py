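"""Discrete Fick's-law diffusion on expression-weighted signalling networks.

A unit of signal is placed on a receptor node and spreads synchronously:
the flux on edge (i, j) at step t is ``F = (S_i - S_j) * w_ij`` with edge
weight ``w_ij = (alpha * E_i) * (alpha * E_j)`` built from the patient's
normalized expression E, and each node adds the sum of its incident
fluxes.  In matrix form one step is ``S(t+1) = (I - L_w) S(t)`` with
``L_w`` the weighted graph Laplacian.

The connectivity readout is t50: the first timestep at which the signal
at a monitored transcription factor reaches 50% of its maximum over the
simulated horizon (default 2000 steps).  Per sample and per source
receptor this yields one t50 per TF; stacked over samples it gives the
samples × (receptor, TF)-pair feature matrix.

A single global scale ``alpha``, calibrated once per dataset, caps every
node's weighted degree at 0.5 so the update matrix is doubly stochastic
and entrywise non-negative: the signal is conserved, stays in [0, 1], and
never oscillates.  Sharing alpha across samples keeps t50 values
comparable between patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .network import SignalingNetwork, GeneRoleSets

EPSILON = 1e-6  # floor for normalized expression; keeps edges alive
MISSING_T50 = np.nan  # sentinel for TFs that never receive signal


@dataclass
class ExpressionMatrix:
    """Genes × samples non-negative intensity matrix.

    ``values`` is a DataFrame indexed by unique gene symbols with sample
    identifiers as columns.  ``normalized`` marks matrices already scaled
    to [EPSILON, 1].
    """

    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dupes[:10]}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("expression matrix contains missing values")

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.values.columns.tolist()


def normalize_expression(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Scale the whole matrix by its global maximum and floor at EPSILON.

    A single dataset-wide divisor preserves between-sample differences.
    Idempotent; negative input raises.
    """
    if raw.normalized:
        return raw
    arr = raw.values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError(
            "negative expression values found; supply unlogged / shifted intensities"
        )
    if not np.isfinite(arr).all():
        raise ValueError("expression values must be finite")
    gmax = arr.max() if arr.size else 0.0
    scaled = arr / gmax if gmax > 0 else np.zeros_like(arr)
    scaled = np.maximum(scaled, EPSILON)
    return ExpressionMatrix(
        pd.DataFrame(scaled, index=raw.values.index, columns=raw.values.columns),
        normalized=True,
    )


@dataclass
class DiffusionConfig:
    """Horizon, source, monitored TFs and the t50 crossing fraction."""

    horizon: int = 2000
    source: str | None = None
    monitored: tuple[str, ...] = ()
    t50_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError(f"horizon must be >= 1, got {self.horizon}")
        if not 0.0 < self.t50_fraction < 1.0:
            raise ValueError(f"t50_fraction must be in (0, 1), got {self.t50_fraction}")


@dataclass
class EdgeWeights:
    """Per-sample symmetric edge weights w_ij = (alpha E_i)(alpha E_j).

    ``matrix`` is a sparse symmetric n × n weight matrix in the network's
    lexicographic node order.  Every node's weighted degree is <= 0.5.
    """

    sample: str
    alpha: float
    nodes: list[str]
    matrix: sp.csr_array

    def weighted_degree(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel()


def _aligned_expression(expr: ExpressionMatrix, network: SignalingNetwork) -> pd.DataFrame:
    if not expr.normalized:
        raise ValueError("expression must be normalized first (normalize_expression)")
    nodes = network.nodes
    missing = sorted(set(nodes) - set(expr.values.index))
    if missing:
        raise ValueError(f"network genes absent from expression matrix: {missing}")
    return expr.values.loc[nodes]


def calibrate_weight_scale(expr: ExpressionMatrix, network: SignalingNetwork) -> float:
    """Global alpha so that max weighted degree over nodes and samples is 0.5.

    With raw degree d_i(s) = sum_j E_i E_j over network neighbours,
    alpha = min(1, sqrt(0.5 / max d)).  One alpha for the whole dataset.
    """
    if network.n_edges == 0:
        raise ValueError("empty network")
    e = _aligned_expression(expr, network).to_numpy(dtype=float)  # n_nodes × n_samples
    adj = network.adjacency()
    raw_degree = e * (adj @ e)  # d_i(s) = E_i * sum_{j in N(i)} E_j
    dmax = float(raw_degree.max())
    if dmax <= 0:
        return 1.0
    return min(1.0, float(np.sqrt(0.5 / dmax)))


def compute_edge_weights(
    expr: ExpressionMatrix, sample: str, network: SignalingNetwork, alpha: float
) -> EdgeWeights:
    """Build the symmetric weight matrix for one sample."""
    aligned = _aligned_expression(expr, network)
    if sample not in aligned.columns:
        raise ValueError(f"unknown sample {sample!r}")
    e = alpha * aligned[sample].to_numpy(dtype=float)
    adj = network.adjacency()
    w = adj.multiply(np.outer(e, e)) if network.n_nodes <= 2000 else _masked_outer(adj, e)
    w = sp.csr_array(w)
    deg = np.asarray(w.sum(axis=1)).ravel()
    bad = np.where(deg > 0.5 + 1e-12)[0]
    if bad.size:
        raise ValueError(
            f"stability bound violated at node {network.nodes[bad[0]]} "
            f"(weighted degree {deg[bad[0]]:.6g} > 0.5); recalibrate alpha"
        )
    return EdgeWeights(sample=sample, alpha=alpha, nodes=network.nodes, matrix=w)


def _masked_outer(adj: sp.csr_array, e: np.ndarray) -> sp.csr_array:
    coo = sp.coo_array(adj)
    return sp.csr_array(
        (e[coo.row] * e[coo.col], (coo.row, coo.col)), shape=adj.shape
    )


def _propagator(weights: EdgeWeights) -> sp.csr_array:
    """I - L_w: doubly stochastic when the weighted-degree bound holds."""
    w = weights.matrix
    deg = np.asarray(w.sum(axis=1)).ravel()
    n = w.shape[0]
    return sp.csr_array(sp.eye_array(n) - (sp.diags_array(deg) - w))


def diffuse(
    network: SignalingNetwork, weights: EdgeWeights, config: DiffusionConfig
) -> pd.DataFrame:
    """Run the diffusion from ``config.source`` and return monitored signals.

    Returns a (horizon + 1) × |monitored| DataFrame of signal levels, rows
    indexed by timestep 0..horizon.  Total signal is conserved to 1e-9.
    """
    idx = network.node_index
    if config.source is None or config.source not in idx:
        raise ValueError(f"source {config.source!r} not in network")
    monitored = list(config.monitored)
    unknown = [g for g in monitored if g not in idx]
    if unknown:
        raise ValueError(f"monitored genes not in network: {unknown}")
    p = _propagator(weights)
    n = p.shape[0]
    s = np.zeros(n)
    s[idx[config.source]] = 1.0
    mon_idx = np.array([idx[g] for g in monitored], dtype=int)
    out = np.empty((config.horizon + 1, len(monitored)))
    out[0] = s[mon_idx]
    for t in range(1, config.horizon + 1):
        s = p @ s
        out[t] = s[mon_idx]
    if abs(s.sum() - 1.0) > 1e-9:
        raise RuntimeError(f"signal not conserved: total {s.sum()!r} at horizon")
    return pd.DataFrame(out, index=pd.RangeIndex(config.horizon + 1, name="t"), columns=monitored)


def extract_t50(trajectory: np.ndarray | pd.Series, config: DiffusionConfig) -> float:
    """First timestep at which the signal reaches t50_fraction of its max.

    Returns NaN when the trajectory never receives any signal.
    """
    traj = np.asarray(trajectory, dtype=float)
    m = traj.max()
    if m <= 0:
        return MISSING_T50
    return float(np.argmax(traj >= config.t50_fraction * m))


@dataclass
class T50Matrix:
    """Samples × (receptor, TF)-pair matrix of diffusion times.

    ``values`` has a two-level column MultiIndex (receptor, tf), ordered
    receptor-major then TF, both lexicographic.  Missing entries (TF in a
    different component from the receptor) are NaN.
    """

    values: pd.DataFrame
    alpha: float
    horizon: int

    @property
    def samples(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(self.values.columns)


def t50_feature_matrix(
    expr: ExpressionMatrix,
    network: SignalingNetwork,
    roles: GeneRoleSets,
    config: DiffusionConfig | None = None,
    alpha: float | None = None,
) -> T50Matrix:
    """One diffusion run per (sample, receptor), monitoring all TFs.

    Receptors and TFs are the role-tagged nodes present in the network.
    Column count is |receptors| × |TFs|.  Samples are independent, so row
    order follows the input sample order and values do not depend on it.
    Runs for one sample batch all receptors into a single matrix iteration
    (mathematically identical to independent runs).
    """
    config = config or DiffusionConfig()
    expr = normalize_expression(expr)
    receptors = network.receptors
    tfs = network.tfs
    if not receptors or not tfs:
        raise ValueError("network must contain at least one receptor and one TF")
    if alpha is None:
        alpha = calibrate_weight_scale(expr, network)
    idx = network.node_index
    rec_idx = np.array([idx[r] for r in receptors], dtype=int)
    tf_idx = np.array([idx[t] for t in tfs], dtype=int)
    columns = pd.MultiIndex.from_product([receptors, tfs], names=["receptor", "tf"])
    rows = []
    frac = config.t50_fraction
    for sample in expr.samples:
        w = compute_edge_weights(expr, sample, network, alpha)
        p = _propagator(w)
        n = p.shape[0]
        state = np.zeros((n, len(receptors)))
        state[rec_idx, np.arange(len(receptors))] = 1.0
        traj = np.empty((config.horizon + 1, len(tfs), len(receptors)))
        traj[0] = state[tf_idx]
        for t in range(1, config.horizon + 1):
            state = p @ state
            traj[t] = state[tf_idx]
        m = traj.max(axis=0)  # (tf, receptor)
        t50 = np.argmax(traj >= frac * m, axis=0).astype(float)
        t50[m <= 0] = MISSING_T50
        rows.append(t50.T.ravel())  # receptor-major
    values = pd.DataFrame(np.array(rows), index=pd.Index(expr.samples, name="sample"),
                          columns=columns)
    return T50Matrix(values=values, alpha=alpha, horizon=config.horizon)
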