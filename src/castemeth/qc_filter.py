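"""Conversion-efficiency estimation and coverage filtering.

Bisulfite conversion efficiency is estimated from the unmethylated lambda
spike-in as one minus the weighted methylation level of the lambda table.
Coverage filtering removes, in every sample, sites covered by fewer than
``min_cov`` reads or above that sample's 99.9th-percentile coverage, keeping
only sites that survive in all samples (the intersection universe).

The percentile thresholds are computed once from the input tables and are
recorded in the report; re-applying the filter at those fixed thresholds is
a no-op, which is the idempotency the pipeline relies on.  Recomputing a
within-sample percentile on already-filtered data would by construction
find a new, slightly lower cutoff, so the threshold is part of the filter's
state, not re-derived per pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SITE_KEY = ["chrom", "pos", "strand"]


@dataclass
class QcReport:
    """Bookkeeping of the QC stage."""

    conversion_efficiency: float | None = None
    coverage_thresholds: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_sites_input: int = 0
    n_sites_kept: int = 0
    n_sites_removed_low: int = 0
    n_sites_removed_high: int = 0
    n_sites_removed_not_shared: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("conversion_efficiency", self.conversion_efficiency),
            ("n_sites_input", self.n_sites_input),
            ("n_sites_kept", self.n_sites_kept),
            ("n_sites_removed_low", self.n_sites_removed_low),
            ("n_sites_removed_high", self.n_sites_removed_high),
            ("n_sites_removed_not_shared", self.n_sites_removed_not_shared),
        ]
        for sample, (lo, hi) in self.coverage_thresholds.items():
            rows.append((f"min_coverage[{sample}]", lo))
            rows.append((f"coverage_p999[{sample}]", hi))
        return pd.DataFrame(rows, columns=["metric", "value"])


def conversion_efficiency(lambda_counts: pd.DataFrame) -> float:
    """1 - (sum methylated / sum total) over the lambda spike-in sites.

    The spike is fully unmethylated, so any methylated read reflects failed
    bisulfite conversion; the complement of its weighted methylation level
    estimates the conversion efficiency.
    """
    total = int(lambda_counts["n_total"].sum())
    if total == 0:
        raise ValueError("lambda table has zero total coverage")
    return 1.0 - float(lambda_counts["n_meth"].sum()) / total


def corrected_site_level(n_meth, n_total, error_rate: float):
    """Single-site methylation level corrected for non-conversion error.

    max(0, (n_meth/n_total - e) / (1 - e)); vectorized over array inputs.
    """
    raw = np.asarray(n_meth, dtype=float) / np.asarray(n_total, dtype=float)
    corrected = np.maximum(0.0, (raw - error_rate) / (1.0 - error_rate))
    if np.isscalar(n_meth) or np.ndim(n_meth) == 0:
        return float(corrected)
    return corrected


def noncpg_methylation_level(report: pd.DataFrame, error_rate: float = 0.0) -> float:
    """Weighted non-CpG methylation from a cytosine report, error-corrected.

    Expects a ``context`` column; rows whose context is not ``CpG`` / ``CG``
    are pooled.
    """
    if "context" not in report.columns:
        raise ValueError("cytosine report with a 'context' column required")
    non = report[~report["context"].isin(["CpG", "CG"])]
    total = int(non["n_total"].sum())
    if total == 0:
        return 0.0
    raw = float(non["n_meth"].sum()) / total
    return max(0.0, (raw - error_rate) / (1.0 - error_rate))


def compute_coverage_thresholds(
    tables: dict[str, pd.DataFrame], min_cov: int = 10, pct: float = 99.9
) -> dict[str, tuple[float, float]]:
    """Per-sample (low, high) coverage bounds: min_cov and the pct percentile.

    ``pct=None`` (or inf) disables the upper bound.
    """
    thresholds = {}
    for sample, table in tables.items():
        cov = table["n_total"].to_numpy()
        covered = cov[cov > 0]
        if pct is None or np.isinf(pct):
            hi = np.inf
        else:
            hi = float(np.percentile(covered, pct)) if len(covered) else np.inf
        thresholds[sample] = (float(min_cov), hi)
    return thresholds


def apply_coverage_thresholds(
    tables: dict[str, pd.DataFrame],
    thresholds: dict[str, tuple[float, float]],
) -> tuple[dict[str, pd.DataFrame], QcReport]:
    """Keep a site iff, in every sample, low <= n_total <= high.

    Sites absent from any sample's table are dropped (intersection universe).
    Idempotent at fixed thresholds.
    """
    report = QcReport(coverage_thresholds=dict(thresholds))

    indexed = {s: t.set_index(SITE_KEY) for s, t in tables.items()}
    universe = None
    for idx in (t.index for t in indexed.values()):
        universe = idx if universe is None else universe.intersection(idx)
    if universe is None:
        raise ValueError("no samples provided")

    first = next(iter(indexed.values()))
    report.n_sites_input = len(first)
    report.n_sites_removed_not_shared = len(first) - len(universe)
    if len(universe) == 0:
        sizes = {s: len(t) for s, t in tables.items()}
        raise ValueError(f"empty site intersection across samples: {sizes}")

    keep = np.ones(len(universe), dtype=bool)
    fail_low = np.zeros(len(universe), dtype=bool)
    fail_high = np.zeros(len(universe), dtype=bool)
    for sample, table in indexed.items():
        cov = table.loc[universe, "n_total"].to_numpy()
        lo, hi = thresholds[sample]
        fail_low |= cov < lo
        fail_high |= cov > hi
    keep = ~(fail_low | fail_high)
    report.n_sites_removed_low = int(fail_low.sum())
    report.n_sites_removed_high = int((fail_high & ~fail_low).sum())
    report.n_sites_kept = int(keep.sum())

    kept_index = universe[keep]
    filtered = {
        s: t.loc[kept_index].reset_index()[list(tables[s].columns)]
        for s, t in indexed.items()
    }
    return filtered, report


def filter_sites(
    tables: dict[str, pd.DataFrame],
    min_cov: int = 10,
    pct: float = 99.9,
    lambda_counts: pd.DataFrame | None = None,
) -> tuple[dict[str, pd.DataFrame], QcReport]:
    """Coverage-filter all samples jointly and assemble the QC report.

    A site is kept iff in every sample ``min_cov <= n_total <=`` that
    sample's ``pct``-percentile coverage, over the intersection of all
    samples' site universes.
    """
    thresholds = compute_coverage_thresholds(tables, min_cov=min_cov, pct=pct)
    filtered, report = apply_coverage_thresholds(tables, thresholds)
    if lambda_counts is not None:
        report.conversion_efficiency = conversion_efficiency(lambda_counts)
    return filtered, report
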