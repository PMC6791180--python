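"""End-to-end orchestration: counts -> QC -> status calls -> DM -> metrics.

Convenience layer tying the pipeline stages together for whole-study runs
(simulated or real), with truth-based evaluation helpers for simulated
studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from castemeth import (
    diff_methylation,
    methylation_metrics,
    msc_caller,
    qc_filter,
    synthetic_data,
)


@dataclass
class PipelineResult:
    """Everything the core methylation pipeline produces for one study."""

    sim: synthetic_data.SimulatedWgbs
    filtered: dict[str, pd.DataFrame]
    qc_report: qc_filter.QcReport
    models: dict[str, msc_caller.MscModel]
    calls: dict[str, pd.DataFrame]
    informative: pd.DataFrame
    site_results: pd.DataFrame
    per_sample_w: pd.DataFrame
    caste_w: pd.DataFrame
    gene_results: pd.DataFrame


def run_simulated_study(
    config: synthetic_data.SimConfig,
    msc_fdr: float = 0.05,
    alpha: float = 0.05,
    min_diff: float = 0.10,
) -> PipelineResult:
    """Simulate a study and run the full methylation pipeline on it.

    The mixture error rate is set to the study's conversion-efficiency
    estimate from a matching lambda spike-in, as it would be on real data.
    """
    sim = synthetic_data.simulate_wgbs(config)
    lam = synthetic_data.simulate_lambda(config)
    error_rate = 1.0 - qc_filter.conversion_efficiency(lam)

    filtered, qc_report = qc_filter.filter_sites(sim.samples, lambda_counts=lam)

    models, calls = {}, {}
    for sample, table in filtered.items():
        model = msc_caller.fit_msc(table["n_meth"], table["n_total"], p0=error_rate)
        models[sample] = model
        calls[sample] = msc_caller.call_status(model, table, fdr_target=msc_fdr)

    informative = msc_caller.filter_informative(calls)
    site_results = diff_methylation.dm_sites(
        filtered, sim.metadata, sites=informative, alpha=alpha, min_diff=min_diff
    )

    gene_map = sim.truth_sites.loc[
        sim.truth_sites["gene_id"] != "", ["chrom", "pos", "gene_id"]
    ]
    long = pd.concat(
        [
            t.merge(gene_map, on=["chrom", "pos"]).assign(sample_id=s)
            for s, t in filtered.items()
        ],
        ignore_index=True,
    )
    per_sample_w = methylation_metrics.weighted_level(
        long, unit_cols="gene_id", sample_col="sample_id"
    )
    caste_w = methylation_metrics.caste_weighted_level(per_sample_w, sim.metadata)
    gene_results = diff_methylation.dm_genes(
        site_results, gene_map, caste_w, min_dw=min_diff
    )
    return PipelineResult(
        sim=sim, filtered=filtered, qc_report=qc_report, models=models,
        calls=calls, informative=informative, site_results=site_results,
        per_sample_w=per_sample_w, caste_w=caste_w, gene_results=gene_results,
    )


def evaluate_msc_calls(result: PipelineResult) -> pd.DataFrame:
    """Per-sample sensitivity and realized false-call rate against truth."""
    truth = result.sim.truth_sites.set_index(["chrom", "pos"])["true_class"]
    rows = []
    for sample, calls in result.calls.items():
        is_meth = (
            truth.loc[list(zip(calls["chrom"], calls["pos"]))] == "methylated"
        ).to_numpy()
        called = (calls["status"] == "methylated").to_numpy()
        sens = (called & is_meth).sum() / max(is_meth.sum(), 1)
        fcr = (called & ~is_meth).sum() / max(called.sum(), 1)
        rows.append((sample, float(sens), float(fcr), int(called.sum())))
    return pd.DataFrame(rows, columns=["sample_id", "sensitivity", "false_call_rate", "n_called"])


def evaluate_dm_genes(result: PipelineResult) -> dict:
    """Truth-DM gene recovery of the full pipeline."""
    truth_dm = set(
        result.sim.truth_genes.loc[result.sim.truth_genes["dm_flag"], "gene_id"]
    )
    called = set(
        result.gene_results.loc[result.gene_results["is_dm_gene"], "gene_id"]
    )
    sens = len(truth_dm & called) / len(truth_dm) if truth_dm else float("nan")
    return {
        "n_truth_dm_genes": len(truth_dm),
        "n_called_dm_genes": len(called),
        "sensitivity": sens,
        "false_positives": len(called - truth_dm),
    }


def null_calibration(
    base_config: synthetic_data.SimConfig, seeds: list[int]
) -> dict:
    """Raw-p calibration of the site test under no caste effect.

    For each seed the full pipeline runs with dm_effect = 0; the fraction of
    raw p < 0.05 is pooled over all sites where the likelihood-ratio test
    was actually computed (degenerate sites carry an assigned p = 1, not a
    raw p-value, and stay out of the calibration metric).
    """
    import dataclasses

    n_sig = n_tested = 0
    dm_gene_counts = []
    for seed in seeds:
        config = dataclasses.replace(
            base_config, n_dm_sites=0, n_dm_genes=0, dm_effect=0.0, seed=seed
        )
        res = run_simulated_study(config)
        tested = res.site_results[~res.site_results["degenerate"]]
        n_sig += int((tested["p"] < 0.05).sum())
        n_tested += len(tested)
        dm_gene_counts.append(int(res.gene_results["is_dm_gene"].sum()))
    return {
        "fraction_p_lt_05": n_sig / max(n_tested, 1),
        "n_tested": n_tested,
        "median_dm_genes": float(np.median(dm_gene_counts)),
        "dm_gene_counts": dm_gene_counts,
    }
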