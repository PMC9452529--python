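"""Evaluation utilities: genome bins, window scores, ROC, summaries.

Mirrors the benchmarking protocol for allelic copy-number detection:
allele counts aggregated by group (e.g. cell type) into adaptive genome
bins of at least 500 counts, fixed 5-Mb window scores |BAF - 0.5|
compared against ground-truth copy-number segments via ROC/AUC, per-cell
coverage histograms, and per-group classification summaries.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve

from .core import CopyNumberSegment, GenomeRegistry, GenomicInterval, normalize_chrom

__all__ = [
    "adaptive_bins",
    "window_scores",
    "label_windows",
    "roc_auc",
    "coverage_histogram",
    "classification_summary",
]

BIN_COLUMNS = [
    "label",
    "chrom",
    "start",
    "end",
    "total_major",
    "total_minor",
    "ratio",
    "undersized",
]


def adaptive_bins(
    counts: pd.DataFrame,
    min_count: int = 500,
    group_col: str | None = None,
) -> pd.DataFrame:
    """Aggregate oriented counts into genome bins of >= ``min_count`` reads.

    Greedy left-to-right accumulation per chromosome (and per group when
    ``group_col`` is given): a bin closes once it holds ``min_count``
    major+minor reads; an undersized final remainder is merged into the
    previous bin. A chromosome with fewer than ``min_count`` reads in
    total yields a single bin flagged ``undersized``.
    """
    counts = counts.assign(chrom=counts["chrom"].map(normalize_chrom))
    group_keys = [group_col, "chrom"] if group_col else ["chrom"]
    rows = []
    for keys, grp in counts.groupby(group_keys):
        keys = keys if isinstance(keys, tuple) else (keys,)
        label = keys[0] if group_col else ""
        chrom = keys[-1]
        grp = grp.sort_values("pos", kind="stable")
        pos = grp["pos"].to_numpy()
        maj = grp["major_count"].to_numpy()
        mino = grp["minor_count"].to_numpy()
        tot = maj + mino
        bins: list[list] = []
        start_idx = 0
        acc = 0
        for i in range(len(grp)):
            acc += tot[i]
            if acc >= min_count:
                bins.append(
                    [
                        label,
                        chrom,
                        pos[start_idx] - 1,
                        pos[i],
                        maj[start_idx : i + 1].sum(),
                        mino[start_idx : i + 1].sum(),
                    ]
                )
                start_idx = i + 1
                acc = 0
        if start_idx < len(grp):  # undersized remainder
            rem = [
                label,
                chrom,
                pos[start_idx] - 1,
                pos[-1],
                maj[start_idx:].sum(),
                mino[start_idx:].sum(),
            ]
            if bins:
                last = bins[-1]
                last[3] = rem[3]
                last[4] += rem[4]
                last[5] += rem[5]
            else:
                bins.append(rem)
        rows.extend(bins)
    out = pd.DataFrame(
        rows, columns=["label", "chrom", "start", "end", "total_major", "total_minor"]
    )
    totals = out["total_major"] + out["total_minor"]
    out["ratio"] = out["total_major"] / totals.where(totals > 0)
    out["undersized"] = totals < min_count
    return out


def window_scores(
    counts: pd.DataFrame,
    registry: GenomeRegistry,
    width: int = 5_000_000,
    group_col: str | None = None,
) -> pd.DataFrame:
    """Score fixed genome windows by allelic imbalance.

    Windows of ``width`` bases tile every registry chromosome; the score
    of a window is |aggregate major fraction - 0.5| over the oriented
    counts falling inside it. Windows without any reads are omitted
    (they carry no evidence and are excluded from ROC analysis).
    """
    counts = counts.assign(chrom=counts["chrom"].map(normalize_chrom))
    counts = counts[counts["chrom"].isin(set(registry.chromosomes))].copy()
    counts["start"] = ((counts["pos"] - 1) // width) * width
    group_keys = ([group_col] if group_col else []) + ["chrom", "start"]
    agg = counts.groupby(group_keys, as_index=False)[
        ["major_count", "minor_count"]
    ].sum()
    agg["end"] = [
        min(s + width, registry[c]) for c, s in zip(agg["chrom"], agg["start"])
    ]
    total = agg["major_count"] + agg["minor_count"]
    agg = agg[total > 0].copy()
    agg["score"] = np.abs(
        agg["major_count"] / (agg["major_count"] + agg["minor_count"]) - 0.5
    )
    if not group_col:
        agg.insert(0, "label", "")
    else:
        agg = agg.rename(columns={group_col: "label"})
    return agg.reset_index(drop=True)


def label_windows(
    windows: pd.DataFrame,
    true_segments: Iterable[CopyNumberSegment],
    min_overlap: float = 0.5,
) -> pd.DataFrame:
    """Attach ground-truth labels: a window is ``altered`` when at least
    ``min_overlap`` of it overlaps a truly copy-number-changed segment."""
    segs = [
        s
        for s in true_segments
        if s.n_major + s.n_minor >= 1 and (s.n_major, s.n_minor) != (1, 1)
    ]
    out = windows.copy()
    truth = []
    for chrom, start, end in zip(out["chrom"], out["start"], out["end"]):
        win = GenomicInterval(chrom, start, end)
        ov = sum(s.interval.overlap(win) for s in segs)
        truth.append("altered" if ov >= min_overlap * win.length else "neutral")
    out["truth"] = truth
    return out


def roc_auc(
    scores: Sequence[float], labels: Sequence[str], positive: str = "altered"
) -> tuple[pd.DataFrame, float]:
    """ROC curve and area for window scores against truth labels.

    Thresholds sweep all distinct score values (with the usual infinite
    sentinel); the area uses trapezoidal integration. Raises when only
    one class is present.
    """
    y = np.asarray([1 if lab == positive else 0 for lab in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both altered and neutral windows")
    fpr, tpr, thresh = roc_curve(y, np.asarray(scores, dtype=float))
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresh})
    return curve, float(_sk_auc(fpr, tpr))


def coverage_histogram(per_cell_totals: Iterable[int]) -> pd.Series:
    """Histogram: number of cells (value) with N covering reads (index)."""
    totals = pd.Series(list(per_cell_totals), dtype=int)
    if totals.empty:
        return pd.Series(dtype=int, name="n_cells")
    hist = totals.value_counts().sort_index()
    hist.name = "n_cells"
    hist.index.name = "n_reads"
    return hist


def classification_summary(
    calls: pd.DataFrame,
    groups: pd.Series | pd.DataFrame,
    truth: pd.Series | None = None,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group cancer/normal fractions over assigned cells.

    ``groups`` maps cell -> group label (cell type); unassigned cells are
    excluded from the fractions (reported separately). When per-cell
    ``truth`` labels are given, also returns the confusion matrix of
    call label vs truth.
    """
    if isinstance(groups, pd.DataFrame):
        groups = groups.set_index("cell")["group"]
    df = calls.copy()
    df["group"] = df["cell"].map(groups)
    rows = []
    for grp, sub in df.groupby("group"):
        n_cancer = int((sub["label"] == "cancer").sum())
        n_normal = int((sub["label"] == "normal").sum())
        n_un = int((sub["label"] == "unassigned").sum())
        assigned = n_cancer + n_normal
        rows.append(
            {
                "group": grp,
                "n_cancer": n_cancer,
                "n_normal": n_normal,
                "n_unassigned": n_un,
                "fraction_cancer": n_cancer / assigned if assigned else np.nan,
            }
        )
    summary = pd.DataFrame(rows)
    if truth is None:
        return summary
    df["truth"] = df["cell"].map(truth)
    confusion = pd.crosstab(df["label"], df["truth"])
    return summary, confusion
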