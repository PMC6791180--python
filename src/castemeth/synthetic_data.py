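"""Synthetic WGBS, expression, spike-in, BLAST and GO data with known truth.

The generator emulates the design of a pooled caste-methylome study: six
WGBS libraries (two castes x three colonies), ~17.7x mean coverage, a very
sparsely methylated genome (~2% of CpGs in a methylated state, genome-wide
methylation fraction on the order of 0.2%), bisulfite non-conversion error
around 0.45%, strong shared inter-colony variation on the logit scale, and
a small set of truly differentially methylated (DM) sites concentrated in a
few DM genes with at least a 10% caste effect.

All randomness flows from ``SimConfig.seed`` through a single
``numpy.random.Generator``; identical configs give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from castemeth import io_formats

CASTES = ("reproductive", "sterile")


@dataclass
class SimConfig:
    """Parameters of the synthetic caste-methylome study.

    Methylated-site levels are drawn from Beta(``meth_level_alpha``,
    ``meth_level_beta``); DM sites shift the caste-specific level by
    +/- ``dm_effect``/2 on the proportion scale.  ``colony_sd`` is the SD of
    a logit-scale colony random effect shared by both libraries of a colony.
    Coverage is negative binomial with mean ``mean_coverage`` and size
    (dispersion) parameter ``coverage_dispersion``, truncated at 1 read.
    """

    n_sites: int = 50_000
    n_genes: int | None = None          # derived from sites_per_gene when None
    sites_per_gene: int = 8
    n_exons_per_gene: int = 3
    frac_methylated_sites: float = 0.02
    mean_coverage: float = 17.7
    coverage_dispersion: float = 8.0
    nonconversion: float = 0.0045       # bisulfite non-conversion error rate
    meth_level_alpha: float = 8.0
    meth_level_beta: float = 2.0
    n_dm_sites: int = 100
    n_dm_genes: int = 20
    dm_effect: float = 0.30             # |p_repro - p_sterile| at DM sites
    colony_sd: float = 0.5
    n_colonies: int = 3
    n_linkage_groups: int = 3
    frac_intergenic_sites: float = 0.2
    site_spacing_bp: int = 60
    seed: int = 1

    # expression side
    n_rna_replicates: int = 3           # individuals per caste per colony
    n_de_genes: int = 30
    de_log2fc: float = 2.0
    n_dee_exons: int = 15
    expression_dispersion: float = 0.2  # NB dispersion (1/size scale)
    n_lambda_sites: int = 10_000

    def validate(self) -> None:
        if not 0.0 <= self.frac_methylated_sites <= 1.0:
            raise ValueError("frac_methylated_sites must be in [0, 1]")
        if not 0.0 <= self.nonconversion < 1.0:
            raise ValueError("nonconversion must be in [0, 1)")
        if not 0.0 <= self.dm_effect <= 1.0:
            raise ValueError("dm_effect must be in [0, 1]")
        if self.dm_effect / 2 + 0.01 > 0.99 - self.dm_effect / 2:
            raise ValueError(
                "dm_effect incompatible with the clipped level support "
                "[0.01, 0.99]: no level admits a +/- dm_effect/2 shift"
            )
        for name in ("n_sites", "n_dm_sites", "n_dm_genes",
                     "n_colonies", "n_lambda_sites"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_dm_sites > 0 and self.n_dm_genes == 0:
            raise ValueError("n_dm_sites > 0 requires n_dm_genes > 0")

    def resolve_n_genes(self) -> int:
        """Gene count: explicit, or the genic sites divided into genes of
        ``sites_per_gene`` CpGs."""
        if self.n_genes is not None:
            return self.n_genes
        n_genic = int(round(self.n_sites * (1.0 - self.frac_intergenic_sites)))
        return max(n_genic // self.sites_per_gene, 1)


@dataclass
class SimulatedWgbs:
    """Bundle of per-sample count tables, metadata, annotation and truth."""

    samples: dict[str, pd.DataFrame]
    metadata: pd.DataFrame
    features: pd.DataFrame
    truth_sites: pd.DataFrame
    truth_genes: pd.DataFrame
    config: SimConfig


def _truncated_nb(rng: np.random.Generator, mean: float, size_param: float,
                  n: int) -> np.ndarray:
    p = size_param / (size_param + mean)
    cov = rng.negative_binomial(size_param, p, size=n)
    return np.maximum(cov, 1)


def _layout_genome(config: SimConfig, rng: np.random.Generator):
    """Place sites on linkage groups and carve gene/exon intervals over them.

    Returns (sites DataFrame with chrom/pos/gene_id, features DataFrame).
    """
    n = config.n_sites
    n_genes = config.resolve_n_genes()
    n_genic = int(round(n * (1.0 - config.frac_intergenic_sites)))
    sites_per_gene = max(n_genic // max(n_genes, 1), 1) if n_genes else 0

    chroms = np.empty(n, dtype=object)
    pos = np.empty(n, dtype=np.int64)
    gene_id = np.full(n, "", dtype=object)

    lg_sizes = np.full(config.n_linkage_groups, n // config.n_linkage_groups)
    lg_sizes[: n % config.n_linkage_groups] += 1

    feature_rows = []
    i = 0
    gene_counter = 0
    genes_per_lg = n_genes // config.n_linkage_groups
    extra = n_genes % config.n_linkage_groups
    for lg, lg_size in enumerate(lg_sizes):
        chrom = f"LG{lg + 1}"
        lg_pos = config.site_spacing_bp * (1 + np.arange(lg_size)) \
            + rng.integers(0, config.site_spacing_bp // 2, size=lg_size)
        lg_pos = np.sort(lg_pos)
        chroms[i : i + lg_size] = chrom
        pos[i : i + lg_size] = lg_pos
        n_genes_here = genes_per_lg + (1 if lg < extra else 0)
        cursor = 0
        for _g in range(n_genes_here):
            if cursor + sites_per_gene > lg_size:
                break
            gid = f"gene{gene_counter:04d}"
            gene_counter += 1
            idx = slice(i + cursor, i + cursor + sites_per_gene)
            gene_id[idx] = gid
            gstart = int(lg_pos[cursor]) - 10
            gend = int(lg_pos[cursor + sites_per_gene - 1]) + 10
            feature_rows.append((chrom, gstart, gend, "+", "gene", gid))
            # exons partition the gene span
            bounds = np.linspace(gstart, gend, config.n_exons_per_gene + 1).astype(int)
            for e in range(config.n_exons_per_gene):
                estart = int(bounds[e]) + (1 if e > 0 else 0)
                eend = int(bounds[e + 1])
                feature_rows.append((chrom, estart, eend, "+", "exon", gid))
            # leave an intergenic gap of sites between genes where possible
            cursor += sites_per_gene + max(
                (lg_size - n_genes_here * sites_per_gene) // max(n_genes_here, 1), 0
            )
        i += lg_size

    sites = pd.DataFrame({"chrom": chroms, "pos": pos, "strand": "+", "gene_id": gene_id})
    features = pd.DataFrame(feature_rows, columns=io_formats.FEATURE_COLUMNS)
    return sites, features


def simulate_wgbs(config: SimConfig) -> SimulatedWgbs:
    """Generate per-sample CpG count tables plus ground truth.

    Unmethylated sites emit methylated reads at the non-conversion rate only.
    Methylated sites draw a latent level from the configured Beta, restricted
    to the support that admits a symmetric +/- dm_effect/2 caste shift without
    clipping, so every DM site differs by exactly ``dm_effect`` in true
    caste proportions.  The hyper-methylated caste is Bernoulli(1/2) per DM
    gene and shared by that gene's DM sites, so gene-level effects are
    coherent while the hyper/hypo direction test keeps a true null.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    sites, features = _layout_genome(config, rng)
    n = config.n_sites

    genic = np.flatnonzero(sites["gene_id"].to_numpy() != "")
    gene_ids = sites["gene_id"].to_numpy()

    n_meth_target = int(round(config.frac_methylated_sites * n))

    # Gene-body methylation in insects is bimodal: a methylated gene has most
    # of its CpGs methylated, an unmethylated gene essentially none.  The
    # methylated-site budget is therefore spent gene-wise: DM genes are fully
    # methylated genes in which a quota of sites carries the caste shift, the
    # rest of the budget fills further fully-methylated genes, and a small
    # remainder is scattered as isolated methylated CpGs.
    all_genes = sorted(set(gene_ids[genic]))
    dm_genes: list[str] = []
    dm_site_idx = np.empty(0, dtype=np.int64)
    is_meth = np.zeros(n, dtype=bool)
    if config.n_dm_sites > 0:
        if len(all_genes) < config.n_dm_genes:
            raise ValueError("not enough genes to host the requested DM genes")
        dm_genes = list(rng.choice(all_genes, size=config.n_dm_genes, replace=False))
        per_gene = np.full(config.n_dm_genes, config.n_dm_sites // config.n_dm_genes)
        per_gene[: config.n_dm_sites % config.n_dm_genes] += 1
        chosen = []
        for gid, quota in zip(dm_genes, per_gene):
            gsites = np.flatnonzero(gene_ids == gid)
            is_meth[gsites] = True
            chosen.append(rng.choice(gsites, size=min(quota, len(gsites)), replace=False))
        dm_site_idx = np.sort(np.concatenate(chosen)) if chosen else dm_site_idx

    dm_flag = np.zeros(n, dtype=bool)
    dm_flag[dm_site_idx] = True

    # spend the remaining budget: whole methylated genes, then scattered sites
    remaining = n_meth_target - int(is_meth.sum())
    if remaining > 0:
        other_genes = [g for g in all_genes if g not in set(dm_genes)]
        order = rng.permutation(len(other_genes))
        for gi in order:
            gsites = np.flatnonzero(gene_ids == other_genes[gi])
            if len(gsites) > remaining:
                break
            is_meth[gsites] = True
            remaining -= len(gsites)
        if remaining > 0:
            pool = np.flatnonzero(~is_meth)
            scatter = rng.choice(pool, size=min(remaining, len(pool)), replace=False)
            is_meth[scatter] = True

    # latent per-site methylated level, restricted so DM shifts never clip
    lo, hi = 0.01 + config.dm_effect / 2, 0.99 - config.dm_effect / 2
    base = rng.beta(config.meth_level_alpha, config.meth_level_beta, size=n)
    level = np.where(is_meth, base, 0.0)
    level_dm = np.clip(base, lo, hi)

    # Hyper/hypo direction is Bernoulli(1/2) per DM *gene* and shared by the
    # gene's DM sites: a DM gene is coherently hyper-methylated in one caste,
    # and the gene-level direction test still has a true null.
    direction = np.ones(n)
    if dm_genes:
        gene_dir = {g: (1.0 if rng.random() < 0.5 else -1.0) for g in dm_genes}
        for idx in dm_site_idx:
            direction[idx] = gene_dir[gene_ids[idx]]
    p_repro = np.where(is_meth, level, 0.0)
    p_sterile = p_repro.copy()
    p_repro[dm_flag] = level_dm[dm_flag] + direction[dm_flag] * config.dm_effect / 2
    p_sterile[dm_flag] = level_dm[dm_flag] - direction[dm_flag] * config.dm_effect / 2

    colony_names = [f"C{j + 1}" for j in range(config.n_colonies)]
    colony_effect = rng.normal(0.0, config.colony_sd, size=config.n_colonies)

    samples: dict[str, pd.DataFrame] = {}
    meta_rows = []
    for ci, colony in enumerate(colony_names):
        for caste in CASTES:
            sample_id = f"{colony}_{caste}"
            meta_rows.append((sample_id, caste, colony))
            cov = _truncated_nb(rng, config.mean_coverage, config.coverage_dispersion, n)
            p_caste = p_repro if caste == "reproductive" else p_sterile
            p_site = np.where(
                is_meth,
                expit(logit(np.clip(p_caste, 1e-9, 1 - 1e-9)) + colony_effect[ci]),
                config.nonconversion,
            )
            n_meth = rng.binomial(cov, p_site)
            samples[sample_id] = pd.DataFrame(
                {
                    "chrom": sites["chrom"],
                    "pos": sites["pos"],
                    "strand": sites["strand"],
                    "n_meth": n_meth,
                    "n_total": cov,
                }
            )

    metadata = pd.DataFrame(meta_rows, columns=["sample_id", "caste", "colony"])

    truth_sites = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "pos": sites["pos"],
            "gene_id": sites["gene_id"],
            "true_class": np.where(is_meth, "methylated", "unmethylated"),
            "p_reproductive": p_repro,
            "p_sterile": p_sterile,
            "dm_flag": dm_flag,
        }
    )

    gene_meth = (
        truth_sites[truth_sites["gene_id"] != ""]
        .groupby("gene_id")["true_class"]
        .apply(lambda s: (s == "methylated").any())
    )
    truth_genes = pd.DataFrame(
        {
            "gene_id": gene_meth.index,
            "methylated": gene_meth.to_numpy(),
            "dm_flag": [g in set(dm_genes) for g in gene_meth.index],
        }
    ).reset_index(drop=True)

    return SimulatedWgbs(
        samples=samples,
        metadata=metadata,
        features=features,
        truth_sites=truth_sites,
        truth_genes=truth_genes,
        config=config,
    )


def simulate_lambda(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Unmethylated lambda spike-in: every methylated read is non-conversion error."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_lambda_sites
    cov = _truncated_nb(rng, config.mean_coverage, config.coverage_dispersion, n)
    n_meth = rng.binomial(cov, config.nonconversion)
    return pd.DataFrame(
        {
            "chrom": "lambda",
            "pos": 10 * (1 + np.arange(n)),
            "strand": "+",
            "n_meth": n_meth,
            "n_total": cov,
        }
    )


@dataclass
class SimulatedExpression:
    """Gene/exon count matrices, FPKM, and truth-derived DE/DEE result tables."""

    gene_counts: pd.DataFrame      # genes x samples
    gene_fpkm: pd.DataFrame
    exon_counts: pd.DataFrame      # (gene, exon) x samples
    metadata: pd.DataFrame         # 18 RNA samples: sample_id, caste, colony
    de_results: pd.DataFrame       # gene_id, log2fc, q, de_flag
    dee_results: pd.DataFrame      # gene_id, exon_id, log2fc, q, dee_flag
    gene_means: pd.DataFrame       # configured per-gene baseline means


def simulate_expression(config: SimConfig, seed: int | None = None) -> SimulatedExpression:
    """Negative-binomial expression for 3 individuals per caste per colony.

    A configured subset of genes carries a caste log2 fold change; a subset of
    exons carries a usage shift on top of its gene's expression.  The DE/DEE
    result tables are derived from truth (flagged rows get q = 1e-4, the rest
    q = 1), standing in for upstream count-model output.
    """
    config.validate()
    rng = np.random.default_rng((config.seed if seed is None else seed) + 104729)

    n_genes = config.resolve_n_genes()
    gene_ids = [f"gene{i:04d}" for i in range(n_genes)]
    base_mean = rng.lognormal(mean=4.0, sigma=1.0, size=n_genes)
    gene_len_kb = rng.uniform(0.5, 5.0, size=n_genes)

    de_idx = rng.choice(n_genes, size=min(config.n_de_genes, n_genes), replace=False)
    lfc = np.zeros(n_genes)
    lfc[de_idx] = config.de_log2fc * np.where(rng.random(len(de_idx)) < 0.5, 1.0, -1.0)

    colony_names = [f"C{j + 1}" for j in range(config.n_colonies)]
    meta_rows = []
    for colony in colony_names:
        for caste in CASTES:
            for r in range(config.n_rna_replicates):
                meta_rows.append((f"{colony}_{caste}_r{r + 1}", caste, colony))
    metadata = pd.DataFrame(meta_rows, columns=["sample_id", "caste", "colony"])

    size_param = 1.0 / config.expression_dispersion
    counts = {}
    for row in metadata.itertuples(index=False):
        mean = base_mean * np.where(
            row.caste == "reproductive", 2.0 ** (lfc / 2), 2.0 ** (-lfc / 2)
        )
        p = size_param / (size_param + mean)
        counts[row.sample_id] = rng.negative_binomial(size_param, p, size=n_genes)
    gene_counts = pd.DataFrame(counts, index=gene_ids)

    lib_size = gene_counts.sum(axis=0)
    fpkm = gene_counts.div(gene_len_kb, axis=0).div(lib_size / 1e6, axis=1)
    gene_fpkm = fpkm

    # exons: per-gene counts split over exons with Dirichlet usage proportions;
    # DEE exons get a caste-specific usage multiplier.
    n_ex = config.n_exons_per_gene
    exon_index = pd.MultiIndex.from_product(
        [gene_ids, [f"e{k + 1}" for k in range(n_ex)]], names=["gene_id", "exon_id"]
    )
    usage = rng.dirichlet(np.full(n_ex, 5.0), size=n_genes)  # genes x exons
    dee_pool = [(g, e) for g in range(n_genes) for e in range(n_ex)]
    dee_pick = rng.choice(len(dee_pool), size=min(config.n_dee_exons, len(dee_pool)),
                          replace=False)
    dee_mask = np.zeros((n_genes, n_ex), dtype=bool)
    dee_lfc = np.zeros((n_genes, n_ex))
    for j in dee_pick:
        g, e = dee_pool[j]
        dee_mask[g, e] = True
        dee_lfc[g, e] = config.de_log2fc * (1.0 if rng.random() < 0.5 else -1.0)

    exon_counts = {}
    for row in metadata.itertuples(index=False):
        mult = np.ones((n_genes, n_ex))
        shift = 2.0 ** (dee_lfc / 2) if row.caste == "reproductive" else 2.0 ** (-dee_lfc / 2)
        mult = np.where(dee_mask, shift, mult)
        w = usage * mult
        w = w / w.sum(axis=1, keepdims=True)
        gene_total = gene_counts[row.sample_id].to_numpy()
        mat = np.stack(
            [rng.multinomial(gene_total[g], w[g]) for g in range(n_genes)]
        )
        exon_counts[row.sample_id] = mat.ravel()
    exon_counts = pd.DataFrame(exon_counts, index=exon_index)

    de_results = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log2fc": lfc,
            "q": np.where(lfc != 0.0, 1e-4, 1.0),
            "de_flag": lfc != 0.0,
        }
    )
    dee_results = pd.DataFrame(
        {
            "gene_id": exon_index.get_level_values(0),
            "exon_id": exon_index.get_level_values(1),
            "log2fc": dee_lfc.ravel(),
            "q": np.where(dee_mask.ravel(), 1e-4, 1.0),
            "dee_flag": dee_mask.ravel(),
        }
    )
    gene_means = pd.DataFrame({"gene_id": gene_ids, "base_mean": base_mean,
                               "length_kb": gene_len_kb})

    return SimulatedExpression(
        gene_counts=gene_counts,
        gene_fpkm=gene_fpkm,
        exon_counts=exon_counts,
        metadata=metadata,
        de_results=de_results,
        dee_results=dee_results,
        gene_means=gene_means,
    )


def simulate_blast_tables(
    n_pairs: int = 40,
    n_ambiguous: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Toy reciprocal BLAST hit tables with known ortholog truth.

    Returns (hits_ab, hits_ba, truth) where truth lists the one-to-one pairs
    that a reciprocal-best-hit filter should recover.  ``n_ambiguous`` extra
    species-A genes are made to best-hit already-taken B genes, which must be
    discarded along with their partners.
    """
    rng = np.random.default_rng(seed)
    rows_ab, rows_ba, truth = [], [], []

    def hit(q, s, ev, bits):
        return (q, s, 90.0, 200, 5, 1, 1, 200, 1, 200, ev, bits)

    for i in range(n_pairs):
        a, b = f"A{i:03d}", f"B{i:03d}"
        ev = 10.0 ** rng.uniform(-50, -5)
        rows_ab.append(hit(a, b, ev, 300.0))
        rows_ba.append(hit(b, a, ev, 300.0))
        # weaker secondary hits
        if i + 1 < n_pairs:
            rows_ab.append(hit(a, f"B{i + 1:03d}", ev * 1e3, 100.0))
        truth.append((a, b))

    # ambiguous queries whose best hit collides with a kept pair's subject
    kept = set()
    for j in range(n_ambiguous):
        a_extra = f"A9{j:02d}"
        b_tgt = f"B{j:03d}"
        rows_ab.append(hit(a_extra, b_tgt, 1e-40, 280.0))
        rows_ba.append(hit(b_tgt, a_extra, 1e-45, 310.0))
        kept.add(b_tgt)
    truth = [(a, b) for a, b in truth if b not in kept]

    cols = io_formats.BLAST_COLUMNS
    return (
        pd.DataFrame(rows_ab, columns=cols),
        pd.DataFrame(rows_ba, columns=cols),
        pd.DataFrame(truth, columns=["gene_a", "gene_b"]),
    )


def simulate_go_map(
    genes: list[str], n_terms: int = 30, mean_terms_per_gene: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Random gene -> GO annotation map (many-to-many)."""
    rng = np.random.default_rng(seed)
    terms = [f"GO:{7000000 + t}" for t in range(n_terms)]
    rows = []
    for g in genes:
        k = min(rng.poisson(mean_terms_per_gene), n_terms)
        for t in rng.choice(n_terms, size=k, replace=False):
            rows.append((g, terms[t]))
    return pd.DataFrame(rows, columns=["gene_id", "go_id"])


def write_simulation(sim: SimulatedWgbs, outdir: str | Path,
                     lambda_table: pd.DataFrame | None = None) -> None:
    """Write a simulated study to disk in the pipeline's input dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sample_id, table in sim.samples.items():
        io_formats.write_coverage_table(table, outdir / f"{sample_id}.cov")
    sim.metadata.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    io_formats.write_features_gff3(sim.features, outdir / "features.gff3")
    sim.truth_sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    sim.truth_genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    if lambda_table is not None:
        io_formats.write_coverage_table(lambda_table, outdir / "lambda.cov")
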