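"""Weighted methylation levels, genome summaries, bins, methylated-gene calls.

The weighted methylation level W of a unit (gene, exon, feature class,
linkage group, or whole genome) in a sample is the coverage-weighted
average: the sum of methylated read counts divided by the sum of total read
counts over all CpGs in the unit.  Caste-level W is the mean of the per
colony-sample W values for that caste, matching the study design of one
pooled library per caste per colony.

Per-gene caste W is binned into four classes: no methylation (W = 0),
low (0 < W <= 0.2), medium (0.2 < W <= 0.7) and high (0.7 < W <= 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

BIN_LABELS = ["none", "low", "medium", "high"]


def weighted_level(
    sites: pd.DataFrame,
    unit_cols: list[str] | str = "gene_id",
    sample_col: str | None = None,
) -> pd.DataFrame:
    """Weighted methylation level per unit (and per sample when present).

    ``sites`` needs ``n_meth``/``n_total`` plus the unit column(s).  Units
    with zero total coverage get ``W = NaN`` and ``defined = False`` so they
    can be excluded from downstream means.
    Returns columns: unit cols (+ sample), ``W``, ``n_cpgs``, ``defined``.
    """
    if isinstance(unit_cols, str):
        unit_cols = [unit_cols]
    group_cols = unit_cols + ([sample_col] if sample_col else [])
    g = sites.groupby(group_cols, sort=True)
    out = g.agg(
        n_meth_sum=("n_meth", "sum"),
        n_total_sum=("n_total", "sum"),
        n_cpgs=("n_total", "size"),
    ).reset_index()
    out["defined"] = out["n_total_sum"] > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        out["W"] = np.where(
            out["defined"], out["n_meth_sum"] / out["n_total_sum"].replace(0, np.nan), np.nan
        )
    return out.drop(columns=["n_meth_sum", "n_total_sum"])[
        group_cols + ["W", "n_cpgs", "defined"]
    ]


def caste_weighted_level(
    per_sample_w: pd.DataFrame,
    metadata: pd.DataFrame,
    unit_cols: list[str] | str = "gene_id",
    sample_col: str = "sample_id",
) -> pd.DataFrame:
    """Caste-level W: mean of per-sample W over each caste's colony samples.

    Undefined per-sample values are excluded from the mean.
    """
    if isinstance(unit_cols, str):
        unit_cols = [unit_cols]
    merged = per_sample_w.merge(
        metadata[[sample_col, "caste"]], on=sample_col, how="left"
    )
    merged = merged[merged["defined"]]
    out = (
        merged.groupby(unit_cols + ["caste"], sort=True)["W"]
        .mean()
        .rename("W")
        .reset_index()
    )
    return out


def classify_methylated_genes(per_sample_w: pd.DataFrame,
                              gene_col: str = "gene_id") -> set[str]:
    """Genes with weighted methylation level > 0 in at least one sample."""
    positive = per_sample_w[(per_sample_w["defined"]) & (per_sample_w["W"] > 0)]
    return set(positive[gene_col].unique())


def assign_bin(w) -> np.ndarray:
    """Methylation bin for W values: none / low / medium / high.

    Exactly 0 is 'none'; boundaries 0.2 and 0.7 belong to the lower bin
    (upper-inclusive half-open intervals).
    """
    w = np.asarray(w, dtype=float)
    if np.any((w < 0) | (w > 1)):
        raise ValueError("W must lie in [0, 1]")
    out = np.empty(w.shape, dtype=object)
    out[w == 0] = "none"
    out[(w > 0) & (w <= 0.2)] = "low"
    out[(w > 0.2) & (w <= 0.7)] = "medium"
    out[w > 0.7] = "high"
    return out


def bin_genes(caste_w: pd.DataFrame, gene_col: str = "gene_id") -> pd.DataFrame:
    """Per-gene per-caste methylation bin from caste-level W."""
    out = caste_w.copy()
    out["bin"] = assign_bin(out["W"].to_numpy())
    return out


def _mean_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    values = values[~np.isnan(values)]
    m = float(np.mean(values)) if len(values) else np.nan
    if len(values) < 2:
        return m, np.nan, np.nan
    half = stats.t.ppf(0.5 + level / 2, len(values) - 1) * stats.sem(values)
    return m, m - half, m + half


def feature_summary(
    annotated_sites: pd.DataFrame,
    metadata: pd.DataFrame,
    by: str = "feature_type",
) -> pd.DataFrame:
    """Weighted methylation per feature class (or other grouping) per caste.

    ``annotated_sites`` is a long table with ``sample_id, n_meth, n_total``
    and the grouping column.  Returns the caste mean of the per-sample W
    values with a 95% t-interval across colony samples.
    """
    per_sample = weighted_level(annotated_sites, unit_cols=by, sample_col="sample_id")
    merged = per_sample.merge(metadata[["sample_id", "caste"]], on="sample_id")
    merged = merged[merged["defined"]]
    rows = []
    for (group, caste), sub in merged.groupby([by, "caste"], sort=True):
        m, lo, hi = _mean_ci(sub["W"].to_numpy())
        rows.append((group, caste, m, lo, hi, int(sub["n_cpgs"].sum())))
    return pd.DataFrame(rows, columns=[by, "caste", "W_mean", "ci_low", "ci_high", "n_cpgs"])


def linkage_summary(sites: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Weighted methylation per linkage group (chromosome) per caste."""
    return feature_summary(sites, metadata, by="chrom")


def genome_summary(sites: pd.DataFrame, metadata: pd.DataFrame,
                   error_rate: float = 0.0) -> pd.DataFrame:
    """Genome-wide weighted methylation per sample, error-corrected.

    The raw genome-wide level is corrected for the bisulfite non-conversion
    rate as max(0, (raw - e) / (1 - e)).
    """
    per_sample = weighted_level(sites.assign(genome="genome"),
                                unit_cols="genome", sample_col="sample_id")
    per_sample["W_corrected"] = np.maximum(
        0.0, (per_sample["W"] - error_rate) / (1.0 - error_rate)
    )
    return per_sample.merge(metadata[["sample_id", "caste", "colony"]], on="sample_id")
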