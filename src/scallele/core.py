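"""Genomic coordinates, copy-number segments, and segment post-processing.

Copy-number segments come from whole-genome DNA callers (Battenberg,
ASCAT, ...) as intervals with major/minor haplotype copy numbers. This
module defines the in-memory representation, the major-allele fraction
``f = nMajor / (nMajor + nMinor)`` that drives the allelic-ratio model,
and the artifact-removal rules applied to raw caller output before
segments are used as genotype hypotheses.

Coordinates are 0-based half-open internally; on-disk formats convert at
the boundary (see :mod:`scallele.io`). Chromosome names are normalized by
stripping any ``chr`` prefix.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "normalize_chrom",
    "GenomicInterval",
    "GenomeRegistry",
    "CopyNumberSegment",
    "CancerGenotype",
    "major_allele_fraction",
    "clean_segments",
    "flag_subclonal",
    "GRCH38_LENGTHS",
]


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix so mixed GRCh37/38 inputs agree."""
    name = str(name)
    return name[3:] if name.lower().startswith("chr") else name


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos0: int) -> bool:
        """True if a 0-based position lies within the interval."""
        return self.start <= pos0 < self.end

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if disjoint chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


# GRCh38 primary-assembly chromosome lengths (chr1-22, X, Y).
GRCH38_LENGTHS: dict[str, int] = {
    "1": 248_956_422, "2": 242_193_529, "3": 198_295_559, "4": 190_214_555,
    "5": 181_538_259, "6": 170_805_979, "7": 159_345_973, "8": 145_138_636,
    "9": 138_394_717, "10": 133_797_422, "11": 135_086_622, "12": 133_275_309,
    "13": 114_364_328, "14": 107_043_718, "15": 101_991_189, "16": 90_338_345,
    "17": 83_257_441, "18": 80_373_285, "19": 58_617_616, "20": 64_444_167,
    "21": 46_709_983, "22": 50_818_468, "X": 156_040_895, "Y": 57_227_415,
}


class GenomeRegistry:
    """Ordered chromosome -> length map used for windows, bins and sanity checks."""

    def __init__(self, lengths: Mapping[str, int]):
        clean: dict[str, int] = {}
        for chrom, length in lengths.items():
            length = int(length)
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
            clean[normalize_chrom(chrom)] = length
        if not clean:
            raise ValueError("empty genome registry")
        self._lengths = clean

    @classmethod
    def grch38(cls, include_sex: bool = True) -> "GenomeRegistry":
        lengths = dict(GRCH38_LENGTHS)
        if not include_sex:
            lengths.pop("X")
            lengths.pop("Y")
        return cls(lengths)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._lengths)

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return normalize_chrom(chrom) in self._lengths

    def __getitem__(self, chrom: str) -> int:
        return self._lengths[normalize_chrom(chrom)]

    def __len__(self) -> int:
        return len(self._lengths)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeRegistry) and self._lengths == other._lengths

    def tile(self, width: int, chrom: str | None = None) -> Iterator[GenomicInterval]:
        """Yield fixed-width windows tiling each chromosome (last one truncated)."""
        chroms = [chrom] if chrom is not None else self.chromosomes
        for c in chroms:
            length = self[c]
            for start in range(0, length, width):
                yield GenomicInterval(c, start, min(start + width, length))


@dataclass(frozen=True)
class CopyNumberSegment:
    """A copy-number state over an interval.

    ``n_major``/``n_minor`` are the copy numbers of the more- and
    less-abundant haplotype; ``cell_fraction`` is the fraction of tumour
    cells carrying the state (1.0 = clonal).
    """

    interval: GenomicInterval
    n_major: int
    n_minor: int
    cell_fraction: float = 1.0
    segment_id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.n_major < 0 or self.n_minor < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.n_major < self.n_minor:
            raise ValueError(
                f"n_major ({self.n_major}) must be >= n_minor ({self.n_minor})"
            )
        if not (0.0 < self.cell_fraction <= 1.0):
            raise ValueError(f"cell_fraction {self.cell_fraction} outside (0, 1]")
        if not self.segment_id:
            iv = self.interval
            object.__setattr__(
                self, "segment_id", f"{iv.chrom}:{iv.start + 1}-{iv.end}"
            )

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def state(self) -> tuple[int, int]:
        return (self.n_major, self.n_minor)


def major_allele_fraction(seg: CopyNumberSegment) -> float:
    """Major-haplotype fraction f = nMajor / (nMajor + nMinor).

    0.5 for a balanced diploid segment, 2/3 for a single-copy gain, 1.0
    for loss of heterozygosity. Homozygous deletions (total copy number
    zero) have no defined allelic ratio and must be excluded upstream.
    """
    total = seg.n_major + seg.n_minor
    if total == 0:
        raise ValueError(
            f"segment {seg.segment_id} has zero total copies (homozygous deletion); "
            "exclude it from genotype hypotheses"
        )
    return seg.n_major / total


@dataclass(frozen=True)
class CancerGenotype:
    """A named hypothesis: a set of non-overlapping copy-number-altered segments.

    Only segments with an informative allelic ratio (f != 0.5 and total
    copy number >= 1) may enter a genotype; use :meth:`from_segments` to
    drop uninformative ones automatically.
    """

    name: str
    segments: tuple[CopyNumberSegment, ...]

    def __init__(self, name: str, segments: Iterable[CopyNumberSegment]):
        segments = tuple(segments)
        for seg in segments:
            if major_allele_fraction(seg) == 0.5:
                raise ValueError(
                    f"segment {seg.segment_id} is allelically balanced (f=0.5) and "
                    "carries no signal; use CancerGenotype.from_segments to drop it"
                )
        for a, b in itertools.combinations(segments, 2):
            if a.interval.overlap(b.interval) > 0:
                raise ValueError(
                    f"overlapping segments {a.segment_id} and {b.segment_id}"
                )
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "segments", segments)

    @classmethod
    def from_segments(
        cls, name: str, segments: Iterable[CopyNumberSegment]
    ) -> "CancerGenotype":
        """Build a genotype keeping only segments with an informative ratio."""
        kept = [
            s
            for s in segments
            if s.n_major + s.n_minor >= 1 and major_allele_fraction(s) != 0.5
        ]
        return cls(name, kept)

    def fraction_by_segment(self) -> dict[str, float]:
        """Map segment_id -> hypothesised major-allele fraction f."""
        return {s.segment_id: major_allele_fraction(s) for s in self.segments}

    def __len__(self) -> int:
        return len(self.segments)


def _merge_run(run: list[CopyNumberSegment]) -> CopyNumberSegment:
    first, last = run[0], run[-1]
    total_len = sum(s.length for s in run)
    cf = sum(s.cell_fraction * s.length for s in run) / total_len
    return CopyNumberSegment(
        GenomicInterval(first.interval.chrom, first.interval.start, last.interval.end),
        first.n_major,
        first.n_minor,
        cell_fraction=cf,
    )


def clean_segments(
    segs: Sequence[CopyNumberSegment],
    registry: GenomeRegistry,
    *,
    min_length: int = 1_000_000,
    min_chrom_fraction: float = 0.10,
    max_gap: int = 1_000_000,
    chrom_state_fraction: float = 0.90,
) -> list[CopyNumberSegment]:
    """Post-process raw DNA copy-number caller output.

    Three rules, applied per chromosome in order:

    1. drop segments shorter than ``min_length`` (1 Mb) or shorter than
       ``min_chrom_fraction`` (10%) of their chromosome -- likely artifacts;
    2. merge consecutive segments with identical (nMajor, nMinor) state
       separated by a gap smaller than ``max_gap`` (1 Mb);
    3. if one state covers at least ``chrom_state_fraction`` (90%) of the
       chromosome's segment-covered length, set the whole covered extent
       of the chromosome to that state.

    The 10% rule uses the registry chromosome length; the 90% rule uses
    covered length. The operation is idempotent and never increases the
    segment count.
    """
    by_chrom: dict[str, list[CopyNumberSegment]] = {}
    for seg in segs:
        chrom = seg.interval.chrom
        if chrom not in registry:
            raise KeyError(f"chromosome {chrom!r} not in genome registry")
        by_chrom.setdefault(chrom, []).append(seg)

    out: list[CopyNumberSegment] = []
    for chrom, chrom_segs in by_chrom.items():
        chrom_segs = sorted(chrom_segs, key=lambda s: s.interval.start)
        # covered span before artifact removal: the 90% rule restores
        # state over this extent, so dropping a small discordant segment
        # does not shrink the chromosome's covered footprint
        span_start = chrom_segs[0].interval.start
        span_end = max(s.interval.end for s in chrom_segs)

        min_len = max(min_length, int(min_chrom_fraction * registry[chrom]))
        chrom_segs = [s for s in chrom_segs if s.length >= min_len]
        if not chrom_segs:
            continue

        # gap filling between identical states
        merged: list[CopyNumberSegment] = []
        run: list[CopyNumberSegment] = [chrom_segs[0]]
        for seg in chrom_segs[1:]:
            gap = seg.interval.start - run[-1].interval.end
            if seg.state == run[-1].state and gap < max_gap:
                run.append(seg)
            else:
                merged.append(_merge_run(run))
                run = [seg]
        merged.append(_merge_run(run))

        # whole-chromosome smoothing on covered length
        covered = sum(s.length for s in merged)
        by_state: dict[tuple[int, int], int] = {}
        for s in merged:
            by_state[s.state] = by_state.get(s.state, 0) + s.length
        state, state_len = max(by_state.items(), key=lambda kv: kv[1])
        spans_all = (
            len(merged) == 1
            and merged[0].interval.start == span_start
            and merged[0].interval.end == span_end
        )
        if state_len / covered >= chrom_state_fraction and not spans_all:
            in_state = [s for s in merged if s.state == state]
            cf = sum(s.cell_fraction * s.length for s in in_state) / state_len
            merged = [
                CopyNumberSegment(
                    GenomicInterval(chrom, span_start, span_end),
                    state[0],
                    state[1],
                    cell_fraction=cf,
                )
            ]
        out.extend(merged)

    out.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    return out


def flag_subclonal(
    segs: Iterable[CopyNumberSegment],
    *,
    clonal_min_fraction: float = 0.50,
    subclonal_min_fraction: float = 0.10,
    min_subclonal_length: int = 20_000_000,
) -> tuple[list[CopyNumberSegment], list[CopyNumberSegment]]:
    """Partition segments into (clonal, subclonal) sets by tumour-cell fraction.

    A segment is clonal when its cell fraction is >= 0.5, subclonal when a
    minority state is present in >= 10% but < 50% of tumour cells over a
    stretch longer than 20 Mb. Segments matching neither rule are dropped.
    """
    clonal: list[CopyNumberSegment] = []
    subclonal: list[CopyNumberSegment] = []
    for seg in segs:
        if seg.cell_fraction >= clonal_min_fraction:
            clonal.append(seg)
        elif (
            seg.cell_fraction >= subclonal_min_fraction
            and seg.length > min_subclonal_length
        ):
            subclonal.append(seg)
    return clonal, subclonal
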