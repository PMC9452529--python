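"""Heterozygous-SNP calling and phasing from bulk DNA allele counts.

Candidate heterozygous sites come from normal (or matched) DNA: a site is
kept when both alleles are seen, its B-allele frequency (BAF, the
fraction of reads carrying the non-reference allele) lies in [0.2, 0.8],
and an exact two-sided binomial test against p = 0.5 does not reject
heterozygosity after Benjamini-Hochberg correction at 5% FDR.

Within copy-number segments where the two haplotypes differ in copy
number (nMajor != nMinor) the tumour DNA BAF is shifted away from 0.5,
which phases each SNP: the allele on the higher-copy haplotype is the
*major* allele. Sites whose tumour BAF is not significantly different
from 0.5 (same test, BH at 5% FDR jointly across all phased segments)
are excluded as unphaseable.

Site tables are pandas DataFrames with columns
``chrom, pos, ref, alt, ref_count, alt_count`` (``pos`` 1-based, as in VCF).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .core import CopyNumberSegment, normalize_chrom

__all__ = [
    "SITE_COLUMNS",
    "baf",
    "binom_pvalues",
    "call_het_snps",
    "phase_segment",
    "phase_segments",
]

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "ref_count", "alt_count"]


def baf(sites: pd.DataFrame) -> pd.Series:
    """B-allele frequency: alt_count / (ref_count + alt_count); NaN at zero depth."""
    total = sites["ref_count"] + sites["alt_count"]
    with np.errstate(invalid="ignore"):
        return sites["alt_count"] / total.where(total > 0)


def binom_pvalues(k: Sequence[int], n: Sequence[int], p: float = 0.5) -> np.ndarray:
    """Exact two-sided binomial p-values for k successes out of n trials.

    Uses the "minlike" convention (sum of all outcome probabilities no
    larger than that of the observed outcome), the convention of
    :func:`scipy.stats.binomtest`. Duplicate (k, n) pairs are computed once.
    """
    k = np.asarray(k, dtype=int)
    n = np.asarray(n, dtype=int)
    out = np.ones(len(k), dtype=float)
    cache: dict[tuple[int, int], float] = {}
    for i, (ki, ni) in enumerate(zip(k, n)):
        if ni <= 0:
            continue
        key = (int(ki), int(ni))
        if key not in cache:
            cache[key] = binomtest(int(ki), int(ni), p).pvalue
        out[i] = cache[key]
    return out


def call_het_snps(
    sites: pd.DataFrame,
    baf_low: float = 0.2,
    baf_high: float = 0.8,
    fdr: float = 0.05,
    min_reads_per_allele: int = 1,
) -> pd.DataFrame:
    """Call usable heterozygous SNPs from DNA allele counts.

    Keeps sites with at least ``min_reads_per_allele`` reads on each
    allele and BAF within [baf_low, baf_high], then removes sites whose
    allele balance is inconsistent with heterozygosity: exact two-sided
    binomial test against p=0.5, Benjamini-Hochberg corrected at ``fdr``
    across all candidate sites.
    """
    if sites.empty:
        return sites.copy()
    sites = sites.copy()
    sites["chrom"] = sites["chrom"].map(normalize_chrom)
    b = baf(sites)
    candidate = (
        (sites["ref_count"] >= min_reads_per_allele)
        & (sites["alt_count"] >= min_reads_per_allele)
        & (b >= baf_low)
        & (b <= baf_high)
    )
    cand = sites.loc[candidate]
    if cand.empty:
        return cand
    pvals = binom_pvalues(
        cand["alt_count"].to_numpy(), (cand["ref_count"] + cand["alt_count"]).to_numpy()
    )
    reject, *_ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    return cand.loc[~reject].reset_index(drop=True)


def _assign_segments(
    sites: pd.DataFrame, segments: Sequence[CopyNumberSegment]
) -> pd.Series:
    """Segment id owning each site (NaN when the site lies in no segment)."""
    seg_id = pd.Series(pd.NA, index=sites.index, dtype="object")
    chrom = sites["chrom"].map(normalize_chrom)
    pos0 = sites["pos"] - 1  # 1-based VCF position -> 0-based
    for seg in segments:
        iv = seg.interval
        mask = (chrom == iv.chrom) & (pos0 >= iv.start) & (pos0 < iv.end)
        seg_id[mask] = seg.segment_id
    return seg_id


def phase_segments(
    tumour_sites: pd.DataFrame,
    segments: Sequence[CopyNumberSegment],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Phase heterozygous SNPs inside copy-number-imbalanced segments.

    Only segments with nMajor != nMinor are used (a balanced segment
    gives no BAF shift to phase from). For each covered site the exact
    two-sided binomial test against BAF 0.5 is BH-corrected jointly
    across all sites in all such segments; significant sites receive
    ``major_is_alt = (BAF > 0.5)``, the rest are excluded.

    Returns the phased sites with extra columns ``segment_id`` and
    ``major_is_alt``, sorted by position with p-value ties broken stably.
    """
    uneven = [s for s in segments if s.n_major != s.n_minor]
    empty = pd.DataFrame(columns=SITE_COLUMNS + ["segment_id", "major_is_alt"])
    if tumour_sites.empty or not uneven:
        return empty
    sites = tumour_sites.copy()
    sites["chrom"] = sites["chrom"].map(normalize_chrom)
    sites["segment_id"] = _assign_segments(sites, uneven)
    total = sites["ref_count"] + sites["alt_count"]
    sites = sites[sites["segment_id"].notna() & (total > 0)]
    if sites.empty:
        return empty
    sites = sites.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    pvals = binom_pvalues(
        sites["alt_count"].to_numpy(),
        (sites["ref_count"] + sites["alt_count"]).to_numpy(),
    )
    reject, *_ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    phased = sites.loc[reject].copy()
    phased["major_is_alt"] = baf(phased) > 0.5
    return phased.reset_index(drop=True)


def phase_segment(
    tumour_sites: pd.DataFrame, seg: CopyNumberSegment, fdr: float = 0.05
) -> pd.DataFrame:
    """Phase SNPs within a single segment; see :func:`phase_segments`."""
    if seg.n_major == seg.n_minor:
        raise ValueError(
            f"segment {seg.segment_id} has equal haplotype copy numbers "
            f"({seg.n_major},{seg.n_minor}); phasing needs a copy-number imbalance"
        )
    return phase_segments(tumour_sites, [seg], fdr=fdr)
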