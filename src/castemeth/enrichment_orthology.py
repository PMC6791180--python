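"""GO enrichment and reciprocal-best-hit (RBH) orthology.

Enrichment is an upper-tail hypergeometric test per GO term against a
configurable background, BH-adjusted within the run.  Orthologs are built
from two BLAST hit tables (A vs B, B vs A): hits above the e-value
threshold are dropped, each query keeps its single best hit (lowest
e-value, ties broken by bitscore, unresolved ties discard the query), only
pairs that are best hits in both directions to the same partner survive,
and any gene matched by more than one distinct partner anywhere in the
best-hit graph is removed with all its matches — the result is a
one-to-one partial matching.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def go_enrichment(
    study: set[str] | list[str],
    background: set[str] | list[str],
    go_map: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric GO-term enrichment of a study set within a background.

    Only terms annotated to at least one study gene are tested (zero-overlap
    terms would only dilute the BH correction).  Annotation rows outside the
    background are ignored.

    Returns one row per tested term: k (study genes with term), K
    (background genes with term), n (study size), N (background size),
    p, q and the ``enriched`` flag (q < alpha).
    """
    study = set(study)
    background = set(background)
    if not study <= background:
        raise ValueError("study set must be a subset of the background")
    if not study:
        return pd.DataFrame(
            columns=["go_id", "k", "K", "n", "N", "p", "q", "enriched"]
        )

    in_bg = go_map[go_map["gene_id"].isin(background)]
    by_term = in_bg.groupby("go_id")["gene_id"].apply(set)
    n, n_bg = len(study), len(background)

    rows = []
    for go_id, genes in by_term.items():
        k = len(genes & study)
        if k == 0:
            continue
        big_k = len(genes)
        p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n))
        rows.append((go_id, k, big_k, n, n_bg, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["go_id", "k", "K", "n", "N", "p"])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["q"] = []
    out["enriched"] = out["q"] < alpha
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def _best_hits(hits: pd.DataFrame, max_evalue: float) -> dict[str, str]:
    """Best subject per query: lowest e-value, tie -> higher bitscore,
    unresolved tie -> query discarded (logged)."""
    kept = hits[hits["evalue"] <= max_evalue]
    best: dict[str, str] = {}
    discarded = []
    for query, sub in kept.groupby("query_id"):
        top = sub[sub["evalue"] == sub["evalue"].min()]
        top = top[top["bitscore"] == top["bitscore"].max()]
        subjects = set(top["subject_id"])
        if len(subjects) > 1:
            discarded.append(query)
            continue
        best[query] = next(iter(subjects))
    if discarded:
        warnings.warn(
            f"discarded {len(discarded)} queries with unresolvable best-hit ties",
            stacklevel=3,
        )
    return best


def reciprocal_best_hits(
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    max_evalue: float = 1e-3,
) -> pd.DataFrame:
    """One-to-one putative orthologs from two directed BLAST hit tables.

    Returns columns ``gene_a, gene_b, evalue_ab, evalue_ba``.
    """
    best_ab = _best_hits(hits_ab, max_evalue)
    best_ba = _best_hits(hits_ba, max_evalue)

    # partner multiplicity over the whole best-hit graph: a gene matched by
    # (or matching) more than one distinct partner is discarded with all its
    # matches, even when its reciprocal pair would otherwise be unique
    partners_a: dict[str, set[str]] = {}
    partners_b: dict[str, set[str]] = {}
    for a, b in best_ab.items():
        partners_a.setdefault(a, set()).add(b)
        partners_b.setdefault(b, set()).add(a)
    for b, a in best_ba.items():
        partners_b.setdefault(b, set()).add(a)
        partners_a.setdefault(a, set()).add(b)

    pairs = [
        (a, b)
        for a, b in best_ab.items()
        if best_ba.get(b) == a
        and len(partners_a[a]) == 1
        and len(partners_b[b]) == 1
    ]

    ev_ab = hits_ab.set_index(["query_id", "subject_id"])["evalue"]
    ev_ba = hits_ba.set_index(["query_id", "subject_id"])["evalue"]
    rows = [
        (a, b, float(np.min(np.atleast_1d(ev_ab.loc[(a, b)]))),
         float(np.min(np.atleast_1d(ev_ba.loc[(b, a)]))))
        for a, b in sorted(pairs)
    ]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "evalue_ab", "evalue_ba"])


def cross_species_dm_overlap(
    orthologs: pd.DataFrame,
    dm_genes_a: set[str] | list[str],
    dm_genes_b: set[str] | list[str],
) -> tuple[int, int, list[str]]:
    """Map species-A DM genes through the ortholog pairs to species B.

    Returns (number of A-side DM genes present in the ortholog list, number
    whose partner is also DM in species B, and that overlapping gene list).
    """
    dm_a, dm_b = set(dm_genes_a), set(dm_genes_b)
    if orthologs.empty:
        return 0, 0, []
    a_to_b = dict(zip(orthologs["gene_a"], orthologs["gene_b"]))
    present = [g for g in sorted(dm_a) if g in a_to_b]
    overlap = [g for g in present if a_to_b[g] in dm_b]
    return len(present), len(overlap), overlap
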