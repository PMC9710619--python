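"""Model / results interface tying the pipeline together.

``DiffusionConnectivity`` is constructed from an expression matrix, a
signalling network and role sets (plus optional sample metadata);
``fit()`` normalizes the expression, calibrates the global weight scale,
runs one diffusion per (sample, receptor) and returns a
``DiffusionConnectivityResults`` holding the samples × receptor-TF-pair
t50 matrix.  Differential testing, AUC screening, PCA/PLS scores and
Procrustes feature-space comparisons hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as _stats
from .diffusion import (
    DiffusionConfig,
    ExpressionMatrix,
    T50Matrix,
    calibrate_weight_scale,
    normalize_expression,
    t50_feature_matrix,
)
from .network import BuilderConfig, GeneRoleSets, SignalingNetwork, hub_genes
from .procrustes import ProcrustesResult, covariate_space, procrustes_explained


class DiffusionConnectivity:
    """Receptor→TF network-diffusion connectivity model for one dataset.

    Parameters
    ----------
    expression
        Genes × samples non-negative intensities (raw or normalized).
    network, roles
        Assembled signalling network and the role gene sets.
    metadata
        Optional sample metadata table used to build comparison designs.
    config
        Diffusion settings (horizon, t50 fraction).
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        network: SignalingNetwork,
        roles: GeneRoleSets,
        metadata: pd.DataFrame | None = None,
        config: DiffusionConfig | None = None,
    ) -> None:
        self.expression = normalize_expression(expression)
        self.network = network
        self.roles = roles
        self.metadata = None if metadata is None else _stats.validate_metadata(
            metadata.reset_index() if "sample" not in metadata.columns else metadata
        )
        self.config = config or DiffusionConfig()

    @classmethod
    def from_files(
        cls,
        expression_path,
        edges_path,
        receptors_path,
        tfs_path,
        transducers_path,
        metadata_path=None,
        builder_config: BuilderConfig | None = None,
        config: DiffusionConfig | None = None,
        header: bool = False,
    ) -> "DiffusionConnectivity":
        from . import io as _io
        from .network import assemble_network

        roles = GeneRoleSets(
            frozenset(_io.read_gene_list(receptors_path)),
            frozenset(_io.read_gene_list(tfs_path)),
            frozenset(_io.read_gene_list(transducers_path)),
        )
        records = _io.read_edges(edges_path, header=header)
        network = assemble_network(records, roles, builder_config or BuilderConfig())
        expr = _io.read_expression(expression_path)
        meta = None if metadata_path is None else _io.read_metadata(metadata_path)
        return cls(expr, network, roles, metadata=meta, config=config)

    def fit(self) -> "DiffusionConnectivityResults":
        """Calibrate the weight scale and compute the t50 feature matrix."""
        alpha = calibrate_weight_scale(self.expression, self.network)
        t50 = t50_feature_matrix(
            self.expression, self.network, self.roles, self.config, alpha=alpha
        )
        return DiffusionConnectivityResults(self, t50)


@dataclass
class DiffusionConnectivityResults:
    """Fitted t50 connectivity features plus the downstream analyses."""

    model: DiffusionConnectivity
    t50: T50Matrix

    @property
    def alpha(self) -> float:
        return self.t50.alpha

    def comparison(self, name: str) -> _stats.ComparisonDesign:
        if self.model.metadata is None:
            raise ValueError("model was built without sample metadata")
        return _stats.define_comparison(self.model.metadata.reset_index(), name)

    def differential(self, comparison: str | _stats.ComparisonDesign, **kwargs) -> pd.DataFrame:
        """Moderated-t differential connectivity table with BH adjustment."""
        design = self.comparison(comparison) if isinstance(comparison, str) else comparison
        return _stats.moderated_fit(self.t50, design, **kwargs)

    def auc_screen(self, comparison: str | _stats.ComparisonDesign) -> pd.DataFrame:
        """Per-pair orientation-normalized AUC table."""
        design = self.comparison(comparison) if isinstance(comparison, str) else comparison
        return _stats.auc_screen(self.t50, design)

    def pca(self, k: int = 2):
        """PCA scores of the t50 matrix (complete pairs only)."""
        return _stats.pca_scores(self._complete_matrix(), k)

    def pls(self, comparison: str | _stats.ComparisonDesign, k: int = 2):
        """PLS scores of the t50 matrix against a two-group indicator."""
        design = self.comparison(comparison) if isinstance(comparison, str) else comparison
        frame = self._complete_matrix()
        samples = design.group_a + design.group_b
        labels = np.array([0] * len(design.group_a) + [1] * len(design.group_b))
        return _stats.pls_scores(frame.loc[samples], labels, k)

    def _complete_matrix(self) -> pd.DataFrame:
        values = self.t50.values
        return values.loc[:, ~values.isna().any(axis=0)]

    def compare_feature_space(
        self,
        source: pd.DataFrame | np.ndarray,
        k: int | None = None,
        source_name: str = "source",
        direction: str = "source_explains_t50",
    ) -> ProcrustesResult:
        """Procrustes comparison between a source space and the t50 space."""
        target = self._complete_matrix()
        if isinstance(source, pd.DataFrame):
            source = source.loc[target.index]
        if direction == "source_explains_t50":
            return procrustes_explained(source, target, k, source_name, "t50")
        return procrustes_explained(target, source, k, "t50", source_name)

    def procrustes_report(
        self, covariates: pd.DataFrame | None = None, k: int | None = None
    ) -> pd.DataFrame:
        """Feature-space comparison report in the style of the dataset table.

        Rows: fraction of t50 variability explained by (a) full expression,
        (b) hub-gene expression (nodes with > 50 edges, where any exist),
        (c) the supplied global covariates, plus (d) the fraction of the
        full expression space explained by the hub genes.  Percentages are
        rounded to the nearest integer.
        """
        expr_t = self.model.expression.values.T  # samples × genes
        target = self._complete_matrix()
        n = target.shape[0]

        def _k(p: int, q: int) -> int | None:
            kmax = min(n - 1, p, q)
            return min(k, kmax) if k is not None else None

        rows = {}
        rows["expression_explains_t50"] = self.compare_feature_space(
            expr_t, _k(expr_t.shape[1], target.shape[1]), "expression"
        ).explained_fraction
        hubs = sorted(hub_genes(self.network_for_hubs()))
        if hubs:
            hub_expr = expr_t.loc[:, hubs]
            rows["hub_expression_explains_t50"] = self.compare_feature_space(
                hub_expr, _k(len(hubs), target.shape[1]), "hub_expression"
            ).explained_fraction
            rows["hub_explains_expression"] = procrustes_explained(
                hub_expr, expr_t, _k(len(hubs), expr_t.shape[1]),
                "hub_expression", "expression",
            ).explained_fraction
        if covariates is not None:
            cov = covariate_space(covariates, self.t50.samples)
            rows["covariates_explain_t50"] = self.compare_feature_space(
                cov, _k(cov.shape[1], target.shape[1]), "covariates"
            ).explained_fraction
        report = pd.DataFrame(
            {"explained_fraction": pd.Series(rows)},
        )
        report["percent"] = (100 * report["explained_fraction"]).round().astype(int)
        return report

    def network_for_hubs(self) -> SignalingNetwork:
        return self.model.network

    def summary(self) -> str:
        """Plain-text summary of the fitted feature space."""
        values = self.t50.values
        n_missing = int(values.isna().to_numpy().sum())
        lines = [
            "Network diffusion connectivity (t50) results",
            "=" * 46,
            f"samples:            {values.shape[0]}",
            f"receptors x TFs:    {len(self.model.network.receptors)} x "
            f"{len(self.model.network.tfs)} = {values.shape[1]} pairs",
            f"network:            {self.model.network.n_nodes} nodes, "
            f"{self.model.network.n_edges} edges",
            f"horizon (steps):    {self.t50.horizon}",
            f"weight scale alpha: {self.alpha:.6g}",
            f"missing t50 cells:  {n_missing}",
        ]
        defined = values.to_numpy()[~values.isna().to_numpy()]
        if defined.size:
            lines.append(
                f"t50 range:          [{defined.min():.0f}, {defined.max():.0f}] steps, "
                f"median {np.median(defined):.0f}"
            )
        return "\n".join(lines)
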