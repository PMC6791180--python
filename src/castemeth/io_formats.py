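"""Readers and writers for the tabular formats the pipeline touches.

All genomic coordinates are held internally as 1-based inclusive positions
(the convention of Bismark coverage files and GFF3).  BED input is converted
at the boundary: a BED interval ``[start, end)`` (0-based half-open) becomes
``[start + 1, end]``.

Per-CpG count tables are pandas DataFrames with columns
``chrom, pos, strand, n_meth, n_total`` (one row per cytosine); zero-coverage
rows are retained at parse time so that filtering is an explicit, observable
step downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

COVERAGE_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_total"]
FEATURE_COLUMNS = ["chrom", "start", "end", "strand", "feature_type", "gene_id"]
BLAST_COLUMNS = [
    "query_id", "subject_id", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

KNOWN_FEATURE_TYPES = frozenset({"gene", "exon", "intron", "ncRNA", "flank"})

CASTES = ("reproductive", "sterile")


@dataclass(frozen=True)
class CpGCountRecord:
    """One cytosine in one sample: position and methylated/total read counts."""

    chrom: str
    pos: int          # 1-based
    strand: str       # '+' or '-'
    n_meth: int
    n_total: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not (0 <= self.n_meth <= self.n_total):
            raise ValueError(
                f"counts must satisfy 0 <= n_meth <= n_total, got "
                f"({self.n_meth}, {self.n_total})"
            )


@dataclass(frozen=True)
class SampleMeta:
    """A pooled WGBS library: its caste label and source colony (the model covariates)."""

    sample_id: str
    caste: str
    colony: str

    def __post_init__(self) -> None:
        if self.caste not in CASTES:
            raise ValueError(f"caste must be one of {CASTES}, got {self.caste!r}")


@dataclass(frozen=True)
class FeatureInterval:
    """Annotated genomic interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    strand: str
    feature_type: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end: {self.start} > {self.end}")


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"evalue must be >= 0, got {self.evalue}")


# ---------------------------------------------------------------------------
# coordinate conversion

def bed_to_internal(start: int, end: int) -> tuple[int, int]:
    """0-based half-open BED interval -> 1-based inclusive."""
    return start + 1, end


def internal_to_bed(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open BED."""
    return start - 1, end


# ---------------------------------------------------------------------------
# coverage tables

def read_coverage_table(path: str | Path) -> pd.DataFrame:
    """Read a Bismark coverage file (6 columns) or cytosine report (7 columns).

    The dialect is auto-detected from the column count of the first data row:

    * ``.cov``: chrom, start, end, percent_methylated, count_methylated,
      count_unmethylated (1-based; start == end for single cytosines).
    * cytosine report: chrom, pos, strand, count_methylated,
      count_unmethylated, context, trinucleotide.

    Returns a DataFrame with :data:`COVERAGE_COLUMNS` (plus ``context`` for
    cytosine reports).  Zero-coverage rows are retained.

    Raises ``ValueError`` naming the 1-based line number for malformed rows
    or negative counts.
    """
    path = Path(path)
    rows: list[tuple] = []
    has_context = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if has_context is None:
                if len(fields) == 6:
                    has_context = False
                elif len(fields) == 7:
                    has_context = True
                else:
                    raise ValueError(
                        f"{path}:{lineno}: expected 6 (coverage) or 7 "
                        f"(cytosine report) columns, got {len(fields)}"
                    )
            try:
                if not has_context:
                    if len(fields) != 6:
                        raise ValueError("wrong column count")
                    chrom, start, end, _pct, n_meth, n_unmeth = fields
                    pos = int(start)
                    int(end)  # validated though unused (start == end per cytosine)
                    strand = "+"
                    context = None
                else:
                    if len(fields) != 7:
                        raise ValueError("wrong column count")
                    chrom, p, strand, n_meth, n_unmeth, context, _tri = fields
                    pos = int(p)
                n_meth = int(n_meth)
                n_unmeth = int(n_unmeth)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
            if n_meth < 0 or n_unmeth < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            if pos < 1:
                raise ValueError(f"{path}:{lineno}: position must be >= 1")
            rows.append((chrom, pos, strand, n_meth, n_meth + n_unmeth, context))

    df = pd.DataFrame(rows, columns=COVERAGE_COLUMNS + ["context"])
    df["pos"] = df["pos"].astype(np.int64)
    df["n_meth"] = df["n_meth"].astype(np.int64)
    df["n_total"] = df["n_total"].astype(np.int64)
    if has_context is not True:
        df = df.drop(columns=["context"])
    return df


def write_coverage_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a count table in the Bismark ``.cov`` dialect (6 columns, no header)."""
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"],
            "end": df["pos"],
            "percent": np.where(
                df["n_total"] > 0, 100.0 * df["n_meth"] / df["n_total"].replace(0, 1), 0.0
            ),
            "n_meth": df["n_meth"],
            "n_unmeth": df["n_total"] - df["n_meth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# feature annotation

def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        key, value = part.split("=", 1)
        out[key] = value
    return out


def read_features(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read a feature annotation as GFF3 or BED.

    ``fmt`` is ``"gff3"`` or ``"bed"``; if ``None`` it is inferred from the
    file extension.  Output columns: :data:`FEATURE_COLUMNS`, all intervals
    1-based inclusive.  Unknown feature types are kept verbatim with a
    warning.  For BED input (which has no type column) the feature type
    defaults to ``gene`` and the 4th column supplies the gene id.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        if suffix in {".gff", ".gff3"}:
            fmt = "gff3"
        elif suffix == ".bed":
            fmt = "bed"
        else:
            raise ValueError(f"cannot infer format from extension {suffix!r}")

    rows = []
    unknown_types: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fmt == "gff3":
                if len(fields) < 9:
                    raise ValueError(f"{path}:{lineno}: GFF3 row has <9 columns")
                chrom, _src, ftype, start, end, _score, strand, _phase, attr = fields[:9]
                attrs = _parse_gff3_attributes(attr)
                gene_id = (
                    attrs.get("gene_id")
                    or (attrs.get("ID") if ftype == "gene" else None)
                    or attrs.get("Parent")
                    or attrs.get("ID", "")
                )
                start_i, end_i = int(start), int(end)
            else:
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: BED row has <3 columns")
                chrom = fields[0]
                start_i, end_i = bed_to_internal(int(fields[1]), int(fields[2]))
                gene_id = fields[3] if len(fields) > 3 else ""
                strand = fields[5] if len(fields) > 5 else "."
                ftype = "gene"
            if ftype not in KNOWN_FEATURE_TYPES:
                unknown_types.add(ftype)
            rows.append((chrom, start_i, end_i, strand, ftype, gene_id))

    if unknown_types:
        warnings.warn(
            f"unknown feature types kept verbatim: {sorted(unknown_types)}",
            stacklevel=2,
        )
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_features_gff3(df: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as minimal GFF3 (gene_id carried in attributes)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in df.itertuples(index=False):
            attrs = f"ID={row.gene_id}.{row.feature_type};gene_id={row.gene_id}"
            fh.write(
                f"{row.chrom}\t.\t{row.feature_type}\t{row.start}\t{row.end}"
                f"\t.\t{row.strand}\t.\t{attrs}\n"
            )


def annotate_sites(
    sites: pd.DataFrame, features: pd.DataFrame, flank_bp: int = 5000
) -> pd.DataFrame:
    """Assign each CpG site to every overlapping feature interval.

    Boundary positions are inclusive on both ends.  Sites overlapping no
    feature are labelled ``intergenic``; if the nearest gene lies within
    ``flank_bp`` of the site its id is recorded in ``nearest_gene`` together
    with the distance.  A site inside multiple features yields multiple rows.

    Returns a DataFrame with ``chrom, pos, feature_type, gene_id,
    nearest_gene, distance``.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")

    trees: dict[str, IntervalTree] = {}
    gene_bounds: dict[str, list[tuple[int, int, str]]] = {}
    for row in features.itertuples(index=False):
        # IntervalTree is half-open; +1 on end makes the query inclusive.
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end + 1, (row.feature_type, row.gene_id)
        )
        if row.feature_type == "gene":
            gene_bounds.setdefault(row.chrom, []).append((row.start, row.end, row.gene_id))

    out = []
    for row in sites.itertuples(index=False):
        tree = trees.get(row.chrom)
        hits = sorted(tree[row.pos], key=lambda iv: (iv.begin, iv.data)) if tree else []
        if hits:
            for iv in hits:
                ftype, gid = iv.data
                out.append((row.chrom, row.pos, ftype, gid, "", 0))
        else:
            nearest, ndist = "", -1
            for start, end, gid in gene_bounds.get(row.chrom, []):
                dist = start - row.pos if row.pos < start else row.pos - end
                if 0 < dist <= flank_bp and (ndist < 0 or dist < ndist):
                    nearest, ndist = gid, dist
            out.append((row.chrom, row.pos, "intergenic", "", nearest, max(ndist, 0)))

    return pd.DataFrame(
        out, columns=["chrom", "pos", "feature_type", "gene_id", "nearest_gene", "distance"]
    )


# ---------------------------------------------------------------------------
# BLAST tables and GO maps

def read_blast_table(path: str | Path) -> pd.DataFrame:
    """Read a 12-column BLAST tabular (outfmt 6) file.

    Duplicate identical rows are dropped with a warning.  Returns a DataFrame
    with :data:`BLAST_COLUMNS`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=BLAST_COLUMNS, comment="#",
            dtype={"query_id": str, "subject_id": str},
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BLAST_COLUMNS)
    if (df["evalue"] < 0).any():
        raise ValueError(f"{path}: negative e-value")
    n_before = len(df)
    df = df.drop_duplicates()
    if len(df) < n_before:
        warnings.warn(f"{path}: dropped {n_before - len(df)} duplicate rows", stacklevel=2)
    return df.reset_index(drop=True)


def read_go_map(path: str | Path) -> pd.DataFrame:
    """Read a two-column gene -> GO-term table (many-to-many).

    Duplicate pairs are dropped with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "go_id"], dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["gene_id", "go_id"])
    n_before = len(df)
    df = df.drop_duplicates()
    if len(df) < n_before:
        warnings.warn(f"{path}: dropped {n_before - len(df)} duplicate pairs", stacklevel=2)
    return df.reset_index(drop=True)


def go_map_to_dict(go_map: pd.DataFrame) -> dict[str, set[str]]:
    """Gene -> set of GO ids."""
    return {g: set(sub["go_id"]) for g, sub in go_map.groupby("gene_id")}


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata TSV with columns sample_id, caste, colony."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "caste", "colony"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    bad = set(df["caste"]) - set(CASTES)
    if bad:
        raise ValueError(f"unknown caste labels: {sorted(bad)}")
    return df
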