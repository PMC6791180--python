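"""Methylation-versus-expression statistics.

Covers the integration analyses: expression compared across gene methylation
bins (Kruskal-Wallis with pairwise Dunn contrasts, BH-adjusted), linear
models of expression on weighted methylation with caste and colony
structure, weighted-methylation contrasts between gene sets (DEG vs
non-DEG, DEE vs non-DEE) reported as model-comparison tables, hypergeometric
set-overlap tests, the regression of differential expression on differential
methylation, and a deterministic sample PCA for cluster reporting.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

FPKM_LOG_OFFSET = 0.01


# ---------------------------------------------------------------------------
# binned expression

def _dunn_pairwise(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's rank-based pairwise contrasts after Kruskal-Wallis.

    Z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j)),
    with the tie correction T = sum(t^3 - t) / (12 (N - 1)); two-sided
    p-values, BH-adjusted across pairs.
    """
    n = len(values)
    ranks = rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term

    labels = pd.unique(groups)
    mean_ranks = {g: ranks[groups == g].mean() for g in labels}
    sizes = {g: int((groups == g).sum()) for g in labels}

    rows = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        rows.append((a, b, z, 2.0 * stats.norm.sf(abs(z))))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])
    out["q"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    return out


def expression_by_meth_bin(
    bins: pd.DataFrame,
    expression: pd.DataFrame,
    gene_col: str = "gene_id",
    bin_col: str = "bin",
    expr_col: str = "fpkm",
    offset: float = FPKM_LOG_OFFSET,
    min_bin_size: int = 2,
) -> dict:
    """Compare log expression across gene methylation bins.

    Returns a dict with the Kruskal-Wallis ``H`` and ``p``, per-bin
    summaries, and the Dunn pairwise table.  Bins with fewer than
    ``min_bin_size`` genes are excluded with a warning.
    """
    merged = bins[[gene_col, bin_col]].merge(expression[[gene_col, expr_col]], on=gene_col)
    merged["log_expr"] = np.log(merged[expr_col] + offset)

    sizes = merged.groupby(bin_col)["log_expr"].size()
    small = sizes[sizes < min_bin_size].index.tolist()
    if small:
        warnings.warn(f"excluding bins with <{min_bin_size} genes: {small}", stacklevel=2)
        merged = merged[~merged[bin_col].isin(small)]
    groups = [sub["log_expr"].to_numpy() for _, sub in merged.groupby(bin_col)]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty bins")

    if all(np.allclose(g, groups[0][0]) for g in groups):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups)

    summaries = (
        merged.groupby(bin_col)["log_expr"]
        .agg(n="size", mean="mean", median="median")
        .reset_index()
    )
    dunn = _dunn_pairwise(
        merged["log_expr"].to_numpy(), merged[bin_col].to_numpy()
    )
    return {"H": float(h), "p": float(p), "summaries": summaries, "pairwise": dunn}


# ---------------------------------------------------------------------------
# expression ~ methylation models

def meth_expression_model(data: pd.DataFrame) -> pd.DataFrame:
    """Expression on weighted methylation with caste and colony structure.

    ``data`` has one row per gene per caste per colony with columns
    ``log_expr, W, caste, colony``.  Fits log_expr ~ W * caste with a
    colony random intercept; if the mixed fit is singular or fails, falls
    back to OLS with fixed colony effects (the fixed-effect targets are the
    same).  Returns a coefficient table with term, estimate, stat, p and
    the method used.
    """
    if data["W"].nunique() <= 1:
        return pd.DataFrame(
            [{"term": "W", "estimate": np.nan, "stat": np.nan, "p": np.nan,
              "method": "inestimable", "flag": "W constant"}]
        )
    method = "mixedlm"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(
                "log_expr ~ W * C(caste)", data, groups=data["colony"]
            ).fit(reml=True, method="lbfgs")
        if not np.isfinite(fit.params).all() or not np.isfinite(fit.bse).all():
            raise ValueError("singular mixed fit")
        params, stats_, pvals = fit.params, fit.tvalues, fit.pvalues
    except Exception:
        method = "ols_fixed_colony"
        fit = smf.ols("log_expr ~ W * C(caste) + C(colony)", data).fit()
        params, stats_, pvals = fit.params, fit.tvalues, fit.pvalues

    rows = []
    for term in params.index:
        if term in ("Group Var",):
            continue
        rows.append(
            {"term": term, "estimate": float(params[term]),
             "stat": float(stats_[term]), "p": float(pvals[term]),
             "method": method, "flag": ""}
        )
    return pd.DataFrame(rows)


def group_methylation_contrast(data: pd.DataFrame,
                               group_col: str = "group") -> pd.DataFrame:
    """Weighted-methylation contrast between gene sets, as a model table.

    ``data`` has one row per unit per caste with columns ``W``, ``caste``
    and the group flag (e.g. DEG vs non-DEG).  Fits W ~ group * caste (full)
    against W ~ group + caste (main effects) and reports three rows:

    * interaction vs. main-effects model (Res. Df, RSS, Df, sum of squares,
      F, p of the comparison),
    * the group main effect (drop-one F test from the main-effects model),
    * the caste main effect.
    """
    data = data.copy()
    data["_group"] = data[group_col].astype(str)
    full = smf.ols("W ~ C(_group) * C(caste)", data).fit()
    main = smf.ols("W ~ C(_group) + C(caste)", data).fit()
    no_group = smf.ols("W ~ C(caste)", data).fit()
    no_caste = smf.ols("W ~ C(_group)", data).fit()

    def compare(reduced, fuller):
        ss = reduced.ssr - fuller.ssr
        df = reduced.df_resid - fuller.df_resid
        f = (ss / df) / (fuller.ssr / fuller.df_resid) if df > 0 else np.nan
        p = stats.f.sf(f, df, fuller.df_resid) if df > 0 else np.nan
        return ss, df, f, p

    rows = []
    ss, df, f, p = compare(main, full)
    rows.append(("interaction_vs_main", full.df_resid, full.ssr, -df, -ss, f, p))
    ss, df, f, p = compare(no_group, main)
    rows.append((f"{group_col}_effect", no_group.df_resid, no_group.ssr, df, ss, f, p))
    ss, df, f, p = compare(no_caste, main)
    rows.append(("caste_effect", no_caste.df_resid, no_caste.ssr, df, ss, f, p))
    return pd.DataFrame(
        rows, columns=["comparison", "res_df", "rss", "df", "sum_sq", "F", "p"]
    )


# ---------------------------------------------------------------------------
# set overlap

@dataclass(frozen=True)
class OverlapResult:
    """Hypergeometric upper-tail overlap between two gene sets in a universe."""

    size_a: int
    size_b: int
    universe: int
    overlap: int
    p: float


def overlap_test(set_a, set_b, universe) -> OverlapResult:
    """P(X >= k) for the overlap k of two sets drawn from a shared universe."""
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("both sets must be subsets of the universe")
    k = len(set_a & set_b)
    n_universe = len(universe)
    p = float(stats.hypergeom.sf(k - 1, n_universe, len(set_a), len(set_b)))
    return OverlapResult(
        size_a=len(set_a), size_b=len(set_b), universe=n_universe, overlap=k,
        p=min(p, 1.0),
    )


# ---------------------------------------------------------------------------
# DM x DE relationship

def dm_de_relationship(delta_w, log2fc) -> dict:
    """OLS of expression log2 fold change on the methylation difference.

    Restricted upstream to genes with some methylation difference and a DE
    flag.  Returns slope, intercept, F, p, and R^2; needs >= 3 points for a
    residual degree of freedom.
    """
    delta_w = np.asarray(delta_w, dtype=float)
    log2fc = np.asarray(log2fc, dtype=float)
    if len(delta_w) < 3:
        raise ValueError("need >= 3 genes for a residual degree of freedom")
    x = sm.add_constant(delta_w)
    fit = sm.OLS(log2fc, x).fit()
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "F": float(fit.fvalue),
        "df": (int(fit.df_model), int(fit.df_resid)),
        "p": float(fit.f_pvalue),
        "r2": float(fit.rsquared),
    }


# ---------------------------------------------------------------------------
# PCA

def sample_pca(matrix: pd.DataFrame, n_components: int = 2) -> dict:
    """Centered PCA of a samples x features matrix via SVD.

    Deterministic: component signs are fixed so the largest-magnitude
    loading of each component is positive.  Returns coordinates (samples x
    PCs), loadings, and the fraction of variance explained.
    """
    x = matrix.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention
    for j in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    n_components = min(n_components, len(s))
    coords = u[:, :n_components] * s[:n_components]
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else var
    return {
        "coordinates": pd.DataFrame(
            coords, index=matrix.index,
            columns=[f"PC{j + 1}" for j in range(n_components)],
        ),
        "loadings": pd.DataFrame(
            vt[:n_components].T, index=matrix.columns,
            columns=[f"PC{j + 1}" for j in range(n_components)],
        ),
        "explained_variance_ratio": explained[:n_components],
    }


def silhouette_by_label(coords: pd.DataFrame, labels: pd.Series) -> float:
    """Mean silhouette of samples grouped by a label, on the PCA coordinates."""
    x = coords.to_numpy(dtype=float)
    labels = np.asarray(labels)
    n = len(x)
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    sil = []
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        if not same.any():
            continue
        a = d[i, same].mean()
        b = min(
            d[i, labels == other].mean()
            for other in np.unique(labels) if other != labels[i]
        )
        sil.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return float(np.mean(sil)) if sil else 0.0
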