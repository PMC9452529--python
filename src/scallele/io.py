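"""Readers and writers for the on-disk formats.

Conventions: internal coordinates are 0-based half-open; segment TSVs
(Battenberg-like) are 1-based inclusive on disk; VCF positions are
1-based. Chromosome names are normalized (``chr`` prefix stripped) on
input and written back bare by default (``chr_prefix=True`` restores the
prefix).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .core import CopyNumberSegment, GenomeRegistry, GenomicInterval, normalize_chrom

__all__ = [
    "read_registry",
    "write_registry",
    "read_segments",
    "write_segments",
    "read_site_counts",
    "write_site_counts",
    "read_cell_counts",
    "write_cell_counts",
    "read_calls",
    "write_calls",
    "read_vcf_sites",
    "write_vcf_sites",
]

SEGMENT_COLUMNS = ["chrom", "start", "end", "nMajor", "nMinor", "cellFraction"]


def read_registry(path: str | Path) -> GenomeRegistry:
    """Read a chrom<TAB>length table; FASTA .fai files work as-is."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return GenomeRegistry(dict(zip(df[0].astype(str), df[1].astype(int))))


def write_registry(registry: GenomeRegistry, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in registry.chromosomes:
            fh.write(f"{chrom}\t{registry[chrom]}\n")


def read_segments(path: str | Path) -> list[CopyNumberSegment]:
    """Read a Battenberg-like segments TSV (1-based inclusive on disk)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SEGMENT_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"segments file {path} missing columns {missing}")
    segs = []
    for _, row in df.iterrows():
        cf = float(row["cellFraction"]) if "cellFraction" in df.columns else 1.0
        segs.append(
            CopyNumberSegment(
                GenomicInterval(str(row["chrom"]), int(row["start"]) - 1, int(row["end"])),
                int(row["nMajor"]),
                int(row["nMinor"]),
                cell_fraction=cf,
            )
        )
    return segs


def write_segments(
    segs: Iterable[CopyNumberSegment], path: str | Path, chr_prefix: bool = False
) -> None:
    rows = []
    for s in segs:
        chrom = ("chr" + s.interval.chrom) if chr_prefix else s.interval.chrom
        rows.append(
            (chrom, s.interval.start + 1, s.interval.end, s.n_major, s.n_minor,
             s.cell_fraction)
        )
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if "chrom" in df.columns:
        df["chrom"] = df["chrom"].astype(str).map(normalize_chrom)
    return df


def read_site_counts(path: str | Path) -> pd.DataFrame:
    """Bulk DNA allele counts: chrom, pos, ref, alt, ref_count, alt_count."""
    return _read_tsv(path, ["chrom", "pos", "ref", "alt", "ref_count", "alt_count"])


def write_site_counts(sites: pd.DataFrame, path: str | Path) -> None:
    sites.to_csv(path, sep="\t", index=False)


def read_cell_counts(path: str | Path) -> pd.DataFrame:
    """Long per-cell counts: cell, chrom, pos, ref, alt, ref_count, alt_count."""
    return _read_tsv(
        path, ["cell", "chrom", "pos", "ref", "alt", "ref_count", "alt_count"]
    )


def write_cell_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ["cell", "posterior_cancer", "label"])


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_INFO = [
    ('##INFO=<ID=RC,Number=1,Type=Integer,Description="Reference allele read count">'),
    ('##INFO=<ID=AC,Number=1,Type=Integer,Description="Alternate allele read count">'),
    ('##INFO=<ID=SEGID,Number=1,Type=String,Description="Owning copy-number segment">'),
    ('##INFO=<ID=MAJOR,Number=1,Type=String,Description="Major allele (REF or ALT)">'),
]


def write_vcf_sites(
    sites: pd.DataFrame,
    path: str | Path,
    registry: GenomeRegistry | None = None,
    chr_prefix: bool = False,
) -> None:
    """Write sites (optionally phased) as an uncompressed VCF.

    Counts go to INFO/RC and INFO/AC; when ``segment_id`` and
    ``major_is_alt`` columns are present they are stored as INFO/SEGID
    and INFO/MAJOR so phase survives a round trip.
    """
    header = pysam.VariantHeader()
    for line in _VCF_INFO:
        header.add_line(line)
    chroms = (
        registry.chromosomes
        if registry is not None
        else sorted(sites["chrom"].astype(str).unique())
    )
    for chrom in chroms:
        name = ("chr" + chrom) if chr_prefix else chrom
        length = registry[chrom] if registry is not None else None
        header.contigs.add(name, length=length)
    phased = "major_is_alt" in sites.columns
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for _, row in sites.sort_values(["chrom", "pos"]).iterrows():
            chrom = ("chr" + row["chrom"]) if chr_prefix else row["chrom"]
            rec = vf.new_record(
                contig=chrom,
                start=int(row["pos"]) - 1,
                stop=int(row["pos"]),
                alleles=(row["ref"], row["alt"]),
            )
            rec.info["RC"] = int(row["ref_count"])
            rec.info["AC"] = int(row["alt_count"])
            if phased:
                rec.info["SEGID"] = str(row["segment_id"])
                rec.info["MAJOR"] = "ALT" if bool(row["major_is_alt"]) else "REF"
            vf.write(rec)


def read_vcf_sites(path: str | Path) -> pd.DataFrame:
    """Read sites from a VCF written by :func:`write_vcf_sites`.

    Counts are taken from INFO/RC + INFO/AC, or from the first sample's
    AD field when RC/AC are absent. Phase columns are recovered when
    present. Malformed or count-less records raise with the record named.
    """
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"{path}: record {rec.chrom}:{rec.pos} is not biallelic"
                )
            info = dict(rec.info)
            if "RC" in info and "AC" in info:
                rc, ac = int(info["RC"]), int(info["AC"])
            else:
                samples = list(rec.samples.values())
                if not samples or samples[0].get("AD") is None:
                    raise ValueError(
                        f"{path}: record {rec.chrom}:{rec.pos} has no RC/AC INFO "
                        "tags and no sample AD field"
                    )
                ad = samples[0]["AD"]
                rc, ac = int(ad[0]), int(ad[1])
            row = {
                "chrom": normalize_chrom(rec.chrom),
                "pos": int(rec.pos),
                "ref": rec.ref,
                "alt": rec.alts[0],
                "ref_count": rc,
                "alt_count": ac,
            }
            if "SEGID" in info:
                row["segment_id"] = str(info["SEGID"])
                row["major_is_alt"] = info.get("MAJOR") == "ALT"
            rows.append(row)
    return pd.DataFrame(rows)
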