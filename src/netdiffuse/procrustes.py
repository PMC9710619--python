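"""Procrustes comparison of feature spaces.

Answers "how much of the t50 connectivity space is a linear shadow of
another space?" — e.g. the full expression matrix, the expression of hub
genes only, or a table of global covariates (immune-cell infiltration,
proliferation score).  Both spaces are reduced to their top-k principal
component scores; the source scores are then mapped onto the target
scores by the least-squares similarity transform (orthogonal rotation +
isotropic scaling + translation), and the explained fraction is
1 - RSS / TSS of the target scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes


@dataclass
class ProcrustesResult:
    """Directional comparison: how well the source space explains the target."""

    explained_fraction: float
    k: int
    source: str
    target: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.source} -> {self.target}: "
            f"{100 * self.explained_fraction:.0f}% explained (k={self.k})"
        )


def _pc_scores(x: np.ndarray, k: int) -> np.ndarray:
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    return u[:, :k] * s[:k]


def procrustes_explained(
    source: pd.DataFrame | np.ndarray,
    target: pd.DataFrame | np.ndarray,
    k: int | None = None,
    source_name: str = "source",
    target_name: str = "target",
) -> ProcrustesResult:
    """Fraction of the target space linearly explainable from the source.

    Rows are samples and must match in number and order (checked by index
    when both are DataFrames).  ``k`` defaults to
    min(n_samples - 1, 20, p, q).  Directional: explained(source→target)
    need not equal explained(target→source).
    """
    if isinstance(source, pd.DataFrame) and isinstance(target, pd.DataFrame):
        if not source.index.equals(target.index):
            raise ValueError("source and target must share the same sample rows in order")
    xs = np.asarray(source, dtype=float)
    xt = np.asarray(target, dtype=float)
    if xs.shape[0] != xt.shape[0]:
        raise ValueError(
            f"sample-row mismatch: source has {xs.shape[0]} rows, target {xt.shape[0]}"
        )
    n = xs.shape[0]
    kmax = min(n - 1, xs.shape[1], xt.shape[1])
    if k is None:
        k = min(kmax, 20)
    if not 1 <= k <= kmax:
        raise ValueError(f"k must be in [1, {kmax}], got {k}")
    x = _pc_scores(xs, k)
    y = _pc_scores(xt, k)
    # least-squares similarity transform of x onto y (rotation + scale);
    # both score matrices are already column-centered so translation is 0
    r, scale_num = orthogonal_procrustes(x, y)
    xnorm2 = (x**2).sum()
    s = scale_num / xnorm2 if xnorm2 > 0 else 0.0
    resid = y - s * (x @ r)
    tss = (y**2).sum()
    rss = (resid**2).sum()
    frac = 1.0 - rss / tss if tss > 0 else 0.0
    return ProcrustesResult(
        explained_fraction=float(frac), k=int(k), source=source_name, target=target_name
    )


def covariate_space(covariates: pd.DataFrame, sample_ids: list[str]) -> pd.DataFrame:
    """Validate and center a user-supplied covariate table (samples × c).

    The covariate estimation itself (cell deconvolution, proliferation
    signatures) happens upstream; this only checks ids and numeric dtype
    and column-centers the table.
    """
    non_numeric = [c for c in covariates.columns
                   if not np.issubdtype(covariates[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric covariate column(s): {non_numeric}")
    missing = [s for s in sample_ids if s not in covariates.index]
    if missing:
        raise ValueError(f"covariate table missing sample(s): {missing}")
    aligned = covariates.loc[sample_ids].astype(float)
    return aligned - aligned.mean(axis=0)
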