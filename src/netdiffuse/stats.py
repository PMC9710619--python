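"""Group-comparison statistics on the t50 connectivity matrix.

Implements the downstream pipeline: comparison-design assembly from sample
metadata, per-pair moderated two-sample testing with empirical-Bayes
variance shrinkage (the moderated t of differential-expression analysis),
Benjamini–Hochberg FDR adjustment, per-pair rank-based AUC screening, and
exploratory PCA / PLS scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.special as special
import scipy.stats as sstats
from sklearn.cross_decomposition import PLSRegression
from statsmodels.stats.multitest import multipletests

from .diffusion import T50Matrix

DIAGNOSES = {"control", "uc"}
RESPONSES = {"responder", "resistant", "n/a"}
TIMEPOINTS = {"before", "after", "n/a"}
SEXES = {"male", "female", "n/a"}

COMPARISONS = ("inflamed_vs_noninflamed", "resistant_vs_responder", "male_vs_female")


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check label vocabularies and control consistency; returns meta indexed by sample."""
    required = ["sample", "diagnosis", "response", "timepoint", "sex"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required column(s): {missing}")
    meta = meta.set_index("sample") if "sample" in meta.columns else meta
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    for col, vocab in [("diagnosis", DIAGNOSES), ("response", RESPONSES),
                       ("timepoint", TIMEPOINTS), ("sex", SEXES)]:
        bad = set(meta[col]) - vocab
        if bad:
            raise ValueError(f"invalid {col} label(s) {sorted(bad)}; allowed: {sorted(vocab)}")
    controls = meta[meta["diagnosis"] == "control"]
    if (controls["response"] != "n/a").any():
        raise ValueError("control samples must have response = n/a")
    return meta


@dataclass
class ComparisonDesign:
    """Two disjoint sample groups for a named comparison."""

    name: str
    group_a: list[str]
    group_b: list[str]

    def __post_init__(self) -> None:
        if set(self.group_a) & set(self.group_b):
            raise ValueError("comparison groups overlap")
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError(
                f"comparison {self.name!r} needs >= 2 samples per group "
                f"(got {len(self.group_a)} vs {len(self.group_b)})"
            )

    @property
    def counts(self) -> tuple[int, int]:
        return len(self.group_a), len(self.group_b)


def define_comparison(meta: pd.DataFrame, name: str) -> ComparisonDesign:
    """Assemble group membership for one of the three study comparisons.

    inflamed_vs_noninflamed
        Inflamed: patient samples before treatment, plus resistant patients
        after treatment.  Non-inflamed: normal controls plus responders
        after treatment.
    resistant_vs_responder
        Resistant vs responder patient samples taken before treatment.
    male_vs_female
        Patient samples before treatment split by sex (negative control).
    """
    meta = validate_metadata(meta.reset_index() if "sample" not in meta.columns else meta)
    uc = meta["diagnosis"] == "uc"
    before = meta["timepoint"] == "before"
    after = meta["timepoint"] == "after"
    if name == "inflamed_vs_noninflamed":
        inflamed = uc & (before | (after & (meta["response"] == "resistant")))
        noninflamed = (meta["diagnosis"] == "control") | (
            uc & after & (meta["response"] == "responder")
        )
        a, b = meta.index[inflamed], meta.index[noninflamed]
    elif name == "resistant_vs_responder":
        a = meta.index[uc & before & (meta["response"] == "resistant")]
        b = meta.index[uc & before & (meta["response"] == "responder")]
    elif name == "male_vs_female":
        a = meta.index[uc & before & (meta["sex"] == "male")]
        b = meta.index[uc & before & (meta["sex"] == "female")]
    else:
        raise ValueError(f"unknown comparison {name!r}; choose from {COMPARISONS}")
    return ComparisonDesign(name=name, group_a=list(a), group_b=list(b))


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-8:
            break
    return float(y)


def _fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match log residual variances to a scaled F distribution.

    Returns the prior df d0 (may be inf) and prior variance s0^2.
    Mirrors the empirical-Bayes hyperparameter fit used for moderated t
    statistics, supporting per-feature residual df.
    """
    ok = (s2 > 0) & (df > 0)
    if not ok.any():
        raise ValueError("degenerate input: no feature has positive residual variance")
    z = np.log(s2[ok])
    dfk = df[ok]
    e = z - special.digamma(dfk / 2.0) + np.log(dfk / 2.0)
    emean = e.mean()
    n = e.size
    if n < 2:
        return np.inf, float(np.exp(emean))
    evar = e.var(ddof=1) - special.polygamma(1, dfk / 2.0).mean()
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def moderated_fit(
    t50: T50Matrix | pd.DataFrame,
    design: ComparisonDesign,
    d0: float | None = None,
    s02: float | None = None,
) -> pd.DataFrame:
    """Per-pair moderated two-sample test between the design's groups.

    Missing t50 entries are handled pairwise-complete; a pair is analysed
    only when both groups retain >= 2 values.  The pooled residual
    variance of each pair is shrunk towards a prior ``s02`` with weight
    ``d0`` estimated by moment matching (pass ``d0``/``s02`` explicitly to
    override; ``d0=0`` recovers the ordinary pooled t).  Two-sided
    p-values use a t distribution with d + d0 degrees of freedom, and a
    BH-adjusted column is appended.

    Returns a DataFrame indexed by pair with columns delta (mean group-A
    minus group-B difference in timesteps), s2, df, n_a, n_b, moderated_t,
    p_value, adj_p_value.
    """
    values = t50.values if isinstance(t50, T50Matrix) else t50
    missing = [s for s in design.group_a + design.group_b if s not in values.index]
    if missing:
        raise ValueError(f"design samples absent from t50 matrix: {missing}")
    a = values.loc[design.group_a].to_numpy(dtype=float)
    b = values.loc[design.group_b].to_numpy(dtype=float)
    na = (~np.isnan(a)).sum(axis=0).astype(float)
    nb = (~np.isnan(b)).sum(axis=0).astype(float)
    analysable = (na >= 2) & (nb >= 2)
    import warnings

    with warnings.catch_warnings(), np.errstate(invalid="ignore", divide="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a, mean_b = np.nanmean(a, axis=0), np.nanmean(b, axis=0)
        var_a, var_b = np.nanvar(a, axis=0, ddof=1), np.nanvar(b, axis=0, ddof=1)
    delta = mean_a - mean_b
    df_resid = na + nb - 2.0
    s2 = ((na - 1) * var_a + (nb - 1) * var_b) / df_resid
    s2 = np.where(analysable, s2, np.nan)
    if d0 is None or s02 is None:
        positive = analysable & (s2 > 0)
        if not positive.any():
            raise ValueError("degenerate input: zero variance in every analysable feature")
        fit_d0, fit_s02 = _fit_f_dist(s2[positive], df_resid[positive])
        d0 = fit_d0 if d0 is None else d0
        s02 = fit_s02 if s02 is None else s02
    with np.errstate(invalid="ignore", divide="ignore"):
        if np.isinf(d0):
            s2_post = np.full_like(s2, s02)
            df_total = np.full_like(df_resid, np.inf)
        else:
            s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
            # zero-variance features fall back to the prior
            s2_post = np.where(s2 == 0, s02 if d0 > 0 else 0.0, s2_post)
            df_total = df_resid + d0
        se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
        tstat = delta / se
        pvals = 2.0 * sstats.t.sf(np.abs(tstat), df_total)
    tstat = np.where(analysable, tstat, np.nan)
    pvals = np.where(analysable, pvals, np.nan)
    adj = np.full_like(pvals, np.nan)
    ok = ~np.isnan(pvals)
    if ok.any():
        adj[ok] = bh_adjust(pvals[ok])
    out = pd.DataFrame(
        {
            "delta": delta,
            "s2": s2,
            "df": df_resid,
            "n_a": na.astype(int),
            "n_b": nb.astype(int),
            "moderated_t": tstat,
            "p_value": pvals,
            "adj_p_value": adj,
        },
        index=values.columns,
    )
    out.attrs["d0"] = float(d0)
    out.attrs["s02"] = float(s02)
    out.attrs["comparison"] = design.name
    return out


def pair_auc(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, bool, int, int]:
    """Rank-based AUC for one pair, orientation-normalized to >= 0.5.

    Ties get half credit (mid-rank).  Missing values are dropped per
    group; an empty group after removal yields (nan, False, n_a, n_b).
    Returns (auc, flipped, n_a, n_b) where ``flipped`` records whether the
    orientation was reversed to reach >= 0.5.
    """
    va = np.asarray(values_a, dtype=float)
    vb = np.asarray(values_b, dtype=float)
    va, vb = va[~np.isnan(va)], vb[~np.isnan(vb)]
    na, nb = len(va), len(vb)
    if na == 0 or nb == 0:
        return float("nan"), False, na, nb
    ranks = sstats.rankdata(np.concatenate([va, vb]))
    u = ranks[:na].sum() - na * (na + 1) / 2.0
    auc = u / (na * nb)
    flipped = auc < 0.5
    return (1.0 - auc if flipped else auc), bool(flipped), na, nb


def auc_screen(t50: T50Matrix | pd.DataFrame, design: ComparisonDesign) -> pd.DataFrame:
    """Per-pair AUC table (ROCTable) for a comparison design."""
    values = t50.values if isinstance(t50, T50Matrix) else t50
    a = values.loc[design.group_a].to_numpy(dtype=float)
    b = values.loc[design.group_b].to_numpy(dtype=float)
    rows = [pair_auc(a[:, j], b[:, j]) for j in range(values.shape[1])]
    out = pd.DataFrame(rows, columns=["auc", "flipped", "n_a", "n_b"], index=values.columns)
    out.attrs["comparison"] = design.name
    return out


def pca_scores(matrix: pd.DataFrame | np.ndarray, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """PCA scores via SVD of the column-centered matrix.

    Returns (scores n × k, variance fractions length k).
    """
    x = np.asarray(matrix, dtype=float)
    if not 1 <= k <= min(x.shape):
        raise ValueError(f"k must be in [1, {min(x.shape)}], got {k}")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    total = (s**2).sum()
    frac = s[:k] ** 2 / total if total > 0 else np.zeros(k)
    return u[:, :k] * s[:k], frac


def pls_scores(
    matrix: pd.DataFrame | np.ndarray, labels: np.ndarray, k: int = 2
) -> np.ndarray:
    """PLS (NIPALS) x-scores against a two-group indicator response."""
    x = np.asarray(matrix, dtype=float)
    if not 1 <= k <= min(x.shape):
        raise ValueError(f"k must be in [1, {min(x.shape)}], got {k}")
    groups = np.unique(np.asarray(labels))
    if len(groups) != 2:
        raise ValueError(f"labels must define exactly two groups, got {list(groups)}")
    y = (np.asarray(labels) == groups[1]).astype(float)
    pls = PLSRegression(n_components=k, scale=False)
    pls.fit(x, y)
    return pls.x_scores_
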