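"""Genome bins, window scores, ROC and summaries."""

import numpy as np
import pandas as pd
import pytest

from scallele.core import CopyNumberSegment, GenomeRegistry, GenomicInterval
from scallele.evaluate import (
    adaptive_bins,
    classification_summary,
    coverage_histogram,
    label_windows,
    roc_auc,
    window_scores,
)

MB = 1_000_000
REG = GenomeRegistry({"1": 100 * MB})


def counts_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "major_count", "minor_count"])


def uniform_counts(n, chrom="1", major=1, minor=0):
    step = 100 * MB // n
    return counts_df([(chrom, (i + 1) * step, major, minor) for i in range(n)])


class TestAdaptiveBins:
    def test_uniform_counts_split_evenly(self):
        bins = adaptive_bins(uniform_counts(1000), min_count=500)
        assert len(bins) == 2
        assert not bins["undersized"].any()

    def test_undersized_chromosome_flagged(self):
        bins = adaptive_bins(uniform_counts(499), min_count=500)
        assert len(bins) == 1 and bool(bins["undersized"].iloc[0])

    def test_remainder_merged_into_last_bin(self):
        bins = adaptive_bins(uniform_counts(1200), min_count=500)
        assert len(bins) == 2
        assert (bins["total_major"] + bins["total_minor"]).tolist() == [500, 700]

    def test_counts_conserved(self):
        rng = np.random.default_rng(2)
        df = counts_df(
            [
                ("1", int(p), int(m), int(n))
                for p, m, n in zip(
                    np.sort(rng.integers(1, 100 * MB, 400)),
                    rng.poisson(3, 400),
                    rng.poisson(3, 400),
                )
            ]
        )
        bins = adaptive_bins(df, min_count=300)
        assert bins["total_major"].sum() == df["major_count"].sum()
        assert bins["total_minor"].sum() == df["minor_count"].sum()

    def test_diploid_bin_ratios_concentrate_near_half(self):
        # binomial concentration: >=500 reads/bin keeps |ratio-0.5| small
        rng = np.random.default_rng(7)
        pos = np.sort(rng.integers(1, 100 * MB, 5000))
        major = rng.binomial(2, 0.5, size=5000)
        df = counts_df(
            [("1", int(p), int(m), int(2 - m)) for p, m in zip(pos, major)]
        )
        bins = adaptive_bins(df, min_count=500)
        assert np.mean(np.abs(bins["ratio"] - 0.5)) < 0.05


class TestWindowScores:
    def test_window_count_and_arithmetic(self):
        ws = window_scores(uniform_counts(2000), REG, width=5 * MB)
        assert len(ws) == 20  # 100 Mb / 5 Mb, all covered

    def test_loh_window_scores_half(self):
        ws = window_scores(uniform_counts(1000, major=10, minor=0), REG)
        assert ws["score"].min() == pytest.approx(0.5)

    def test_diploid_window_scores_near_zero(self):
        ws = window_scores(uniform_counts(1000, major=5, minor=5), REG)
        assert ws["score"].max() == pytest.approx(0.0)

    def test_empty_windows_excluded(self):
        df = counts_df([("1", 100, 3, 3)])  # only the first window covered
        ws = window_scores(df, REG, width=5 * MB)
        assert len(ws) == 1


class TestRoc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.1, 0.2], ["altered"] * 2 + ["neutral"] * 2)
        assert auc == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        labels = np.where(rng.random(4000) < 0.5, "altered", "neutral")
        _, auc = roc_auc(scores, labels)
        assert abs(auc - 0.5) < 0.03

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            roc_auc([0.1, 0.2], ["altered", "altered"])

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.random(200)
        labels = np.where(scores + rng.normal(0, 0.3, 200) > 0.5, "altered", "neutral")
        _, a1 = roc_auc(scores, labels)
        _, a2 = roc_auc(np.exp(5 * scores), labels)
        assert a1 == pytest.approx(a2)


class TestLabelWindows:
    def test_half_overlap_rule(self):
        wins = pd.DataFrame(
            {
                "chrom": ["1", "1", "1"],
                "start": [0, 5 * MB, 10 * MB],
                "end": [5 * MB, 10 * MB, 15 * MB],
                "score": [0.4, 0.1, 0.0],
            }
        )
        # altered region covers window 1 fully, 40% of window 2, none of 3
        segs = [CopyNumberSegment(GenomicInterval("1", 0, 7 * MB), 2, 0)]
        out = label_windows(wins, segs)
        assert list(out["truth"]) == ["altered", "neutral", "neutral"]

    def test_balanced_segments_not_altered(self):
        wins = pd.DataFrame(
            {"chrom": ["1"], "start": [0], "end": [5 * MB], "score": [0.0]}
        )
        segs = [CopyNumberSegment(GenomicInterval("1", 0, 50 * MB), 1, 1)]
        assert label_windows(wins, segs)["truth"].iloc[0] == "neutral"


class TestCoverageHistogram:
    def test_counts_cells_per_depth(self):
        hist = coverage_histogram([0, 0, 3])
        assert hist.to_dict() == {0: 2, 3: 1}

    def test_empty_input(self):
        assert coverage_histogram([]).empty

    def test_mass_equals_cell_count(self):
        totals = [0, 1, 1, 5, 9, 9, 9]
        assert coverage_histogram(totals).sum() == len(totals)


class TestClassificationSummary:
    def calls(self, rows):
        return pd.DataFrame(rows, columns=["cell", "posterior_cancer", "label"])

    def test_fraction_excludes_unassigned(self):
        calls = self.calls(
            [(f"c{i}", 1.0, "cancer") for i in range(90)]
            + [(f"n{i}", 0.0, "normal") for i in range(10)]
            + [(f"u{i}", 0.5, "unassigned") for i in range(50)]
        )
        groups = pd.Series("tumour", index=calls["cell"])
        out = classification_summary(calls, groups)
        assert out["fraction_cancer"].iloc[0] == pytest.approx(0.9)
        assert out["n_unassigned"].iloc[0] == 50

    def test_all_unassigned_group_is_missing(self):
        calls = self.calls([("c1", 0.5, "unassigned")])
        out = classification_summary(calls, pd.Series("g", index=calls["cell"]))
        assert np.isnan(out["fraction_cancer"].iloc[0])

    def test_perfect_calls_give_diagonal_confusion(self):
        calls = self.calls([("c1", 1.0, "cancer"), ("c2", 0.0, "normal")])
        groups = pd.Series("g", index=calls["cell"])
        truth = pd.Series(["cancer", "normal"], index=["c1", "c2"])
        _, confusion = classification_summary(calls, groups, truth)
        assert confusion.loc["cancer", "cancer"] == 1
        assert confusion.loc["normal", "normal"] == 1
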