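"""Annotate, filter, orient and aggregate per-cell allele counts.

Raw per-cell counts are a long table keyed by cell barcode with ref/alt
read counts at each SNP (``cell, chrom, pos, ref, alt, ref_count,
alt_count``). This module:

* annotates SNPs against a gene model (exonic / intronic / intergenic,
  imprinted flag) — the error model is site-class specific;
* filters out sites that cannot be modelled: imprinted genes, intergenic
  sites, zero-coverage sites, and genes with known complex
  allele-specific expression (HLA and haemoglobin genes by default);
* re-orients ref/alt counts into major/minor counts (m_s, n_s) using the
  phase assignment from tumour DNA;
* sums counts per (cell, segment) for reporting and binning. The
  likelihood itself consumes per-SNP counts, since error and ASE rates
  are site-specific.
"""

from __future__ import annotations

import logging
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .core import normalize_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "default_imprinted_genes",
    "DEFAULT_EXCLUDED_GENE_PREFIXES",
    "annotate_snps",
    "filter_snps",
    "apply_site_filter",
    "orient_counts",
    "aggregate_by_segment",
]

CELL_COUNT_COLUMNS = ["cell", "chrom", "pos", "ref", "alt", "ref_count", "alt_count"]

# Genes with complex allele-specific expression, excluded from the model.
DEFAULT_EXCLUDED_GENE_PREFIXES = ("HLA-",)
DEFAULT_EXCLUDED_GENES = frozenset(
    {"HBA1", "HBA2", "HBB", "HBD", "HBE1", "HBG1", "HBG2", "HBM", "HBQ1", "HBZ"}
)


def default_imprinted_genes() -> frozenset[str]:
    """Built-in curated imprinted-gene list (one symbol per line resource)."""
    text = (
        importlib_resources.files("scallele")
        .joinpath("resources/imprinted_genes.txt")
        .read_text()
    )
    return frozenset(
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


class GeneModel:
    """Gene bodies and exon intervals, 0-based half-open coordinates.

    Backed by two DataFrames: ``genes`` (gene, chrom, start, end) and
    ``exons`` (gene, chrom, start, end).
    """

    def __init__(self, genes: pd.DataFrame, exons: pd.DataFrame):
        self.genes = genes.assign(chrom=genes["chrom"].map(normalize_chrom))
        self.exons = exons.assign(chrom=exons["chrom"].map(normalize_chrom))
        self._gene_trees: dict[str, IntervalTree] = {}
        self._exon_trees: dict[str, IntervalTree] = {}
        for chrom, grp in self.genes.groupby("chrom"):
            self._gene_trees[chrom] = IntervalTree.from_tuples(
                zip(grp["start"], grp["end"], grp["gene"])
            )
        for chrom, grp in self.exons.groupby("chrom"):
            self._exon_trees[chrom] = IntervalTree.from_tuples(
                zip(grp["start"], grp["end"], grp["gene"])
            )

    @classmethod
    def from_bed12(cls, path: str | Path) -> "GeneModel":
        """Read a BED12 gene model (blocks are exons; name column = gene)."""
        genes, exons = [], []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.rstrip("\n").split("\t")
                chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
                genes.append((name, chrom, start, end))
                if len(f) >= 12:
                    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                    offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                    for size, off in zip(sizes, offsets):
                        exons.append((name, chrom, start + off, start + off + size))
                else:
                    exons.append((name, chrom, start, end))
        cols = ["gene", "chrom", "start", "end"]
        return cls(pd.DataFrame(genes, columns=cols), pd.DataFrame(exons, columns=cols))

    def to_bed12(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for _, g in self.genes.sort_values(["chrom", "start"]).iterrows():
                ex = self.exons[self.exons["gene"] == g["gene"]].sort_values("start")
                sizes = ",".join(str(e - s) for s, e in zip(ex["start"], ex["end"]))
                offs = ",".join(str(s - g["start"]) for s in ex["start"])
                fh.write(
                    f"{g['chrom']}\t{g['start']}\t{g['end']}\t{g['gene']}\t0\t+\t"
                    f"{g['start']}\t{g['end']}\t0\t{len(ex)}\t{sizes},\t{offs},\n"
                )

    def _hits(self, trees, chrom: str, pos0: int) -> list[str]:
        tree = trees.get(normalize_chrom(chrom))
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.at(pos0))


def annotate_snps(
    snps: pd.DataFrame,
    gene_model: GeneModel | None = None,
    imprinted: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Label each SNP exonic / intronic / intergenic with its gene.

    Exonic wins over intronic; with overlapping genes the first gene in
    sorted symbol order is used. ``imprinted`` defaults to the built-in
    curated list. Without a gene model every site is intergenic (warned).
    """
    imprinted_set = (
        default_imprinted_genes() if imprinted is None else frozenset(imprinted)
    )
    out = snps.loc[:, ["chrom", "pos"]].drop_duplicates().copy()
    out["chrom"] = out["chrom"].map(normalize_chrom)
    if gene_model is None:
        logger.warning("no gene model supplied; all %d sites set intergenic", len(out))
        out["gene"] = ""
        out["site_class"] = "intergenic"
        out["imprinted"] = False
        return out.reset_index(drop=True)

    genes, classes = [], []
    for chrom, pos in zip(out["chrom"], out["pos"]):
        pos0 = pos - 1
        ex = gene_model._hits(gene_model._exon_trees, chrom, pos0)
        if ex:
            genes.append(ex[0])
            classes.append("exonic")
            continue
        gb = gene_model._hits(gene_model._gene_trees, chrom, pos0)
        if gb:
            genes.append(gb[0])
            classes.append("intronic")
        else:
            genes.append("")
            classes.append("intergenic")
    out["gene"] = genes
    out["site_class"] = classes
    out["imprinted"] = out["gene"].isin(imprinted_set)
    return out.reset_index(drop=True)


def filter_snps(
    counts: pd.DataFrame,
    annotations: pd.DataFrame,
    excluded_genes: Iterable[str] | None = None,
    excluded_prefixes: Sequence[str] = DEFAULT_EXCLUDED_GENE_PREFIXES,
) -> pd.DataFrame:
    """Site-level filter: the retained (chrom, pos) sites with annotation.

    Removes sites that are imprinted, intergenic, in an excluded gene
    (default HLA-* and haemoglobin genes), or have zero total coverage
    summed over all cells in ``counts``. Purely site-level: the result
    does not depend on how reads distribute over cells.
    """
    excluded = (
        DEFAULT_EXCLUDED_GENES if excluded_genes is None else frozenset(excluded_genes)
    )
    cov = (
        counts.assign(chrom=counts["chrom"].map(normalize_chrom))
        .assign(_tot=lambda d: d["ref_count"] + d["alt_count"])
        .groupby(["chrom", "pos"], as_index=False)["_tot"]
        .sum()
    )
    ann = annotations.merge(cov, on=["chrom", "pos"], how="left")
    ann["_tot"] = ann["_tot"].fillna(0)
    bad_gene = ann["gene"].isin(excluded) | ann["gene"].str.startswith(
        tuple(excluded_prefixes), na=False
    )
    keep = (
        ~ann["imprinted"]
        & (ann["site_class"] != "intergenic")
        & (ann["_tot"] > 0)
        & ~bad_gene
    )
    return ann.loc[keep].drop(columns="_tot").reset_index(drop=True)


def apply_site_filter(counts: pd.DataFrame, retained: pd.DataFrame) -> pd.DataFrame:
    """Restrict a counts table to retained (chrom, pos) sites."""
    keys = retained.loc[:, ["chrom", "pos"]]
    return counts.merge(keys, on=["chrom", "pos"], how="inner")


def orient_counts(raw: pd.DataFrame, phased: pd.DataFrame) -> pd.DataFrame:
    """Convert per-cell ref/alt counts into major/minor counts (m_s, n_s).

    ``phased`` carries ``major_is_alt`` and ``segment_id`` per site (from
    :func:`scallele.hetsnps.phase_segments`). Records at unphased sites
    are dropped (count logged).
    """
    raw = raw.assign(chrom=raw["chrom"].map(normalize_chrom))
    merged = raw.merge(
        phased.loc[:, ["chrom", "pos", "segment_id", "major_is_alt"]],
        on=["chrom", "pos"],
        how="left",
    )
    unphased = merged["major_is_alt"].isna()
    if unphased.any():
        logger.info("dropping %d records at unphased sites", int(unphased.sum()))
    merged = merged.loc[~unphased].copy()
    alt_major = merged["major_is_alt"].astype(bool)
    merged["major_count"] = merged["alt_count"].where(alt_major, merged["ref_count"])
    merged["minor_count"] = merged["ref_count"].where(alt_major, merged["alt_count"])
    cols = ["cell", "chrom", "pos", "segment_id", "major_count", "minor_count"]
    extra = [c for c in ("gene", "site_class") if c in merged.columns]
    return merged.loc[:, cols + extra].reset_index(drop=True)


def aggregate_by_segment(
    oriented: pd.DataFrame, cells: Sequence[str] | None = None
) -> pd.DataFrame:
    """Sum major/minor counts per (cell, segment).

    Each site must belong to exactly one segment (guaranteed by phasing
    against disjoint segments; violations raise). When ``cells`` is
    given, cells with no reads in a segment get explicit (0, 0) rows.
    """
    per_site = oriented.groupby(["chrom", "pos"])["segment_id"].nunique()
    if (per_site > 1).any():
        dup = per_site[per_site > 1].index[0]
        raise ValueError(f"site {dup} assigned to multiple segments; segments overlap")
    agg = (
        oriented.groupby(["cell", "segment_id"], as_index=False)[
            ["major_count", "minor_count"]
        ]
        .sum()
        .rename(columns={"major_count": "major_total", "minor_count": "minor_total"})
    )
    if cells is not None:
        seg_ids = agg["segment_id"].unique() if len(agg) else []
        full = pd.MultiIndex.from_product(
            [list(cells), list(seg_ids)], names=["cell", "segment_id"]
        )
        agg = (
            agg.set_index(["cell", "segment_id"])
            .reindex(full, fill_value=0)
            .reset_index()
        )
    return agg
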