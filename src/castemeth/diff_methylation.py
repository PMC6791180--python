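"""Site-level differential methylation and gene-level dual-threshold calls.

Per informative CpG site, methylated/total read counts across the samples
are modelled with a binomial logistic regression on caste plus colony (the
colony covariate absorbs the strong shared inter-colony variation).  The
caste effect is tested by a likelihood-ratio test of the full model against
the colony-only model; p-values are Benjamini-Hochberg adjusted across all
tested sites.  A site is differentially methylated (DM) when q < 0.05 and
the caste-pooled methylation proportions differ by at least 10%.  A gene is
DM when it contains at least one DM CpG and the caste weighted-methylation
levels differ by at least 10% across the whole gene.

All sites share one design matrix, so the per-site GLMs are fitted with a
single batched Newton (Fisher-scoring) solver over a 3-D array of normal
equations; an independent statsmodels fit is used as the test oracle, not
in this code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SITE_KEY = ["chrom", "pos", "strand"]

_ETA_CLIP = 30.0
_BETA_DIVERGED = 25.0


def _design_matrices(metadata: pd.DataFrame, caste_order=("sterile", "reproductive")):
    """Full (intercept + caste + colony dummies) and reduced (no caste) designs.

    The caste indicator is 1 for reproductive, so a positive coefficient
    means higher methylation odds in reproductive workers.
    """
    caste = (metadata["caste"] == caste_order[1]).to_numpy(dtype=float)
    colonies = sorted(metadata["colony"].unique())
    cols = [np.ones(len(metadata)), caste]
    for colony in colonies[1:]:
        cols.append((metadata["colony"] == colony).to_numpy(dtype=float))
    x_full = np.column_stack(cols)
    x_reduced = np.delete(x_full, 1, axis=1)
    return x_full, x_reduced


def _batched_binomial_glm(k, n, x, max_iter: int = 60, tol: float = 1e-10):
    """Fit one binomial-logit GLM per site, all sites sharing the design ``x``.

    k, n : (B, m) methylated/total counts; x : (m, p).
    Returns (beta (B, p), loglik (B,), converged (B,)).  The log-likelihood
    omits the binomial coefficient, which cancels in likelihood ratios.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    nb, m = k.shape
    p = x.shape[1]
    beta = np.zeros((nb, p))
    # intercept start at pooled logit
    pooled = np.clip(k.sum(axis=1) / np.maximum(n.sum(axis=1), 1.0), 1e-6, 1 - 1e-6)
    beta[:, 0] = np.log(pooled / (1 - pooled))

    def loglik(b):
        eta = np.clip(b @ x.T, -_ETA_CLIP, _ETA_CLIP)
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        return (k * np.log(mu) + (n - k) * np.log1p(-mu)).sum(axis=1)

    ll = loglik(beta)
    active = np.ones(nb, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        b = beta[active]
        eta = np.clip(b @ x.T, -_ETA_CLIP, _ETA_CLIP)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = n[active] * mu * (1.0 - mu)            # (Ba, m)
        grad = (k[active] - n[active] * mu) @ x    # (Ba, p)
        info = np.einsum("bm,mp,mq->bpq", w, x, x)  # (Ba, p, p)
        info += 1e-10 * np.eye(p)
        try:
            step = np.linalg.solve(info, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.einsum("bpq,bq->bp", np.linalg.pinv(info), grad)
        # step-halving to guarantee non-decreasing likelihood
        new_b = b + step
        new_ll = loglik_rows(k[active], n[active], x, new_b)
        bad = new_ll < ll[active] - 1e-12
        halvings = 0
        while bad.any() and halvings < 25:
            step[bad] *= 0.5
            new_b[bad] = b[bad] + step[bad]
            new_ll[bad] = loglik_rows(k[active][bad], n[active][bad], x, new_b[bad])
            bad = new_ll < ll[active] - 1e-12
            halvings += 1
        # a site is done when the likelihood has plateaued or the step is
        # negligible; under separation the coefficients diverge but the
        # clipped likelihood plateaus, which is sufficient for the LRT
        moved = (np.abs(new_b - b).max(axis=1) > tol) & (
            np.abs(new_ll - ll[active]) > 1e-9
        )
        idx = np.flatnonzero(active)
        beta[idx] = new_b
        ll[idx] = new_ll
        still = idx[moved]
        active = np.zeros(nb, dtype=bool)
        active[still] = True

    converged = ~active & np.isfinite(ll)
    return beta, ll, converged


def loglik_rows(k, n, x, b):
    eta = np.clip(b @ x.T, -_ETA_CLIP, _ETA_CLIP)
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    return (k * np.log(mu) + (n - k) * np.log1p(-mu)).sum(axis=1)


def dm_sites(
    tables: dict[str, pd.DataFrame],
    metadata: pd.DataFrame,
    sites: pd.DataFrame | None = None,
    alpha: float = 0.05,
    min_diff: float = 0.10,
) -> pd.DataFrame:
    """Test every (informative) site for a caste effect on methylation.

    Parameters
    ----------
    tables
        Per-sample coverage-filtered count tables sharing one site universe.
    metadata
        sample_id / caste / colony for every table.
    sites
        Optional informative-site table (``chrom, pos, strand``) to restrict
        testing to — this is the multiple-testing-burden reduction step.
    alpha, min_diff
        DM thresholds: q < alpha and |pooled proportion difference| >= min_diff.

    Returns one row per tested site: ``meth_diff`` (reproductive - sterile,
    pooled proportions), likelihood-ratio ``p``, BH ``q``, ``is_dm`` and a
    ``degenerate`` flag (zero-variability or diverged fits; those get p = 1).
    """
    metadata = metadata.reset_index(drop=True)
    if metadata.groupby("caste")["sample_id"].count().min() < 2:
        raise ValueError("need at least 2 samples per caste")
    sample_ids = list(metadata["sample_id"])

    indexed = {s: tables[s].set_index(SITE_KEY) for s in sample_ids}
    universe = None
    for t in indexed.values():
        universe = t.index if universe is None else universe.intersection(t.index)
    if sites is not None:
        wanted = pd.MultiIndex.from_frame(sites[SITE_KEY])
        universe = universe.intersection(wanted)
    universe = universe.sortlevel()[0] if universe.nlevels > 1 else universe
    if len(universe) == 0:
        raise ValueError("no sites to test")

    k = np.column_stack([indexed[s].loc[universe, "n_meth"].to_numpy() for s in sample_ids])
    n = np.column_stack([indexed[s].loc[universe, "n_total"].to_numpy() for s in sample_ids])

    x_full, x_reduced = _design_matrices(metadata)

    beta_f, ll_f, conv_f = _batched_binomial_glm(k, n, x_full)
    beta_r, ll_r, conv_r = _batched_binomial_glm(k, n, x_reduced)

    lrt = np.maximum(2.0 * (ll_f - ll_r), 0.0)
    p = stats.chi2.sf(lrt, df=1)

    rates = k / np.maximum(n, 1.0)
    zero_var = np.all(rates == rates[:, [0]], axis=1)

    # complete separation on the caste term: one caste sits on the boundary
    # (no methylated reads at all, or fully methylated) while the other does
    # not; the caste coefficient is then unbounded and the chi-squared
    # approximation to the LRT is invalid, so the site gets p = 1, flagged
    repro = (metadata["caste"] == "reproductive").to_numpy()
    kr, ks = k[:, repro].sum(axis=1), k[:, ~repro].sum(axis=1)
    nr, ns = n[:, repro].sum(axis=1), n[:, ~repro].sum(axis=1)
    caste_sep = ((kr == 0) != (ks == 0)) | ((kr == nr) != (ks == ns))

    degenerate = zero_var | caste_sep | ~conv_f | ~conv_r
    p = np.where(degenerate, 1.0, p)
    with np.errstate(invalid="ignore"):
        p_repro = k[:, repro].sum(axis=1) / np.maximum(n[:, repro].sum(axis=1), 1.0)
        p_sterile = k[:, ~repro].sum(axis=1) / np.maximum(n[:, ~repro].sum(axis=1), 1.0)
    meth_diff = p_repro - p_sterile

    _, q, _, _ = multipletests(p, method="fdr_bh")

    out = pd.DataFrame(universe.to_frame(index=False))
    out["meth_diff"] = meth_diff
    out["p"] = p
    out["q"] = q
    out["is_dm"] = (q < alpha) & (np.abs(meth_diff) >= min_diff)
    out["degenerate"] = degenerate
    out["caste_coef"] = beta_f[:, 1]
    return out


def dm_genes(
    site_results: pd.DataFrame,
    site_gene_map: pd.DataFrame,
    caste_w: pd.DataFrame,
    min_dw: float = 0.10,
) -> pd.DataFrame:
    """Gene-level DM calls: >=1 DM CpG and caste weighted-methylation gap >= 10%.

    ``site_gene_map`` assigns sites to genes (``chrom, pos, gene_id``; the
    intergenic label and empty gene ids are ignored — intergenic DM sites are
    reported separately via :func:`intergenic_dm_sites`).  ``caste_w`` is the
    caste-level weighted methylation per gene from methylation_metrics.
    """
    genic = site_gene_map[
        (site_gene_map["gene_id"] != "") & (site_gene_map["gene_id"].notna())
    ][["chrom", "pos", "gene_id"]].drop_duplicates()
    merged = site_results.merge(genic, on=["chrom", "pos"], how="inner")
    dm_counts = (
        merged.groupby("gene_id")["is_dm"].sum().astype(int).rename("n_dm_cpgs")
    )

    w_wide = caste_w.pivot_table(index="gene_id", columns="caste", values="W")
    for caste in ("reproductive", "sterile"):
        if caste not in w_wide.columns:
            w_wide[caste] = np.nan
    dw = (w_wide["reproductive"] - w_wide["sterile"]).rename("delta_w")

    genes = sorted(set(dm_counts.index) | set(dw.index))
    out = pd.DataFrame({"gene_id": genes})
    out = out.merge(dm_counts.reset_index(), on="gene_id", how="left")
    out = out.merge(dw.reset_index(), on="gene_id", how="left")
    out["n_dm_cpgs"] = out["n_dm_cpgs"].fillna(0).astype(int)
    out["is_dm_gene"] = (out["n_dm_cpgs"] >= 1) & (out["delta_w"].abs() >= min_dw)
    out["hyper_in"] = np.select(
        [out["delta_w"] > 0, out["delta_w"] < 0],
        ["reproductive", "sterile"],
        default="",
    )
    return out


def intergenic_dm_sites(site_results: pd.DataFrame,
                        annotation: pd.DataFrame) -> pd.DataFrame:
    """DM sites outside any gene, with the nearest gene within the flank.

    ``annotation`` is the output of io_formats.annotate_sites.
    """
    inter = annotation[annotation["feature_type"] == "intergenic"]
    dm = site_results[site_results["is_dm"]]
    return dm.merge(
        inter[["chrom", "pos", "nearest_gene", "distance"]], on=["chrom", "pos"],
        how="inner",
    )


def direction_test(n_hyper_a: int, n_hyper_b: int):
    """Chi-squared goodness of fit of two direction counts against 50:50.

    Returns (chi2, df, p) with df = 1.
    """
    if n_hyper_a + n_hyper_b <= 0:
        raise ValueError("at least one count must be positive")
    chi2, p = stats.chisquare([n_hyper_a, n_hyper_b])
    return float(chi2), 1, float(p)


@dataclass
class PermutationNull:
    """Null distribution of the DM-site count under caste-label shuffling."""

    counts: np.ndarray
    observed: int
    labelings: int

    @property
    def quantile(self) -> float:
        """Empirical quantile of the observed count in the null."""
        if len(self.counts) == 0:
            return float("nan")
        return float(np.mean(self.counts < self.observed))


def permutation_null(
    tables: dict[str, pd.DataFrame],
    metadata: pd.DataFrame,
    sites: pd.DataFrame | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
    enumerate_distinct: bool = False,
    alpha: float = 0.05,
    min_diff: float = 0.10,
) -> PermutationNull:
    """Recompute the DM-site count under shuffled caste labels.

    With ``enumerate_distinct=True`` every balanced caste assignment is
    evaluated exactly once (C(6,3) = 20 for the six-library design) instead
    of random shuffles.

    With strong shared colony structure and few replicates, label
    permutations break the colony/caste alignment and the resulting null is
    not exchangeable, so this distribution should be read as descriptive
    support, not a calibrated test.
    """
    warnings.warn(
        "permutation null under colony structure is not a calibrated test; "
        "interpret the distribution descriptively",
        stacklevel=2,
    )
    observed = int(
        dm_sites(tables, metadata, sites=sites, alpha=alpha, min_diff=min_diff)[
            "is_dm"
        ].sum()
    )
    m = len(metadata)
    caste_labels = metadata["caste"].to_numpy()
    n_repro = int((caste_labels == "reproductive").sum())

    if enumerate_distinct:
        assignments = [set(c) for c in combinations(range(m), n_repro)]
    else:
        rng = np.random.default_rng(seed)
        assignments = [
            set(rng.choice(m, size=n_repro, replace=False)) for _ in range(n_perm)
        ]

    counts = []
    for assign in assignments:
        permuted = metadata.copy()
        permuted["caste"] = [
            "reproductive" if i in assign else "sterile" for i in range(m)
        ]
        res = dm_sites(tables, permuted, sites=sites, alpha=alpha, min_diff=min_diff)
        counts.append(int(res["is_dm"].sum()))
    return PermutationNull(
        counts=np.array(counts, dtype=int),
        observed=observed,
        labelings=len(assignments),
    )
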