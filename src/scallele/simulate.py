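"""Synthetic-data generator mirroring the model's generative assumptions.

Produces every input the pipeline consumes without any external data: a
toy genome registry, a gene model, heterozygous SNP positions, bulk
tumour/normal DNA allele counts, and per-cell single-cell allele counts
with known truth (clone labels, per-gene ASE ratios, overdispersion,
haplotype assignments). Defaults emulate the observed single-cell depth
of 1522 SNP-covering reads per cell, beta-binomial allele splits with
site-class errors, per-gene allele-specific expression, and a
configurable clonal genotype (a 30-Mb copy-neutral LoH plus a 50-Mb
single-copy gain) with an optional subclone.

Haplotype convention: haplotype A is the major haplotype of every
altered segment; each SNP's alternate allele sits on haplotype A with
probability 1/2 (recorded as ``alt_on_hap_a``). All randomness flows
from a single integer seed, so identical configs give identical tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CancerGenotype, CopyNumberSegment, GenomeRegistry, GenomicInterval
from .model import expected_allelic_ratio
from .sc_counts import GeneModel, annotate_snps

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "Reference", "SimTruth", "simulate_reference",
           "simulate_bulk_dna", "simulate_cells", "default_segments"]

_BASES = np.array(list("ACGT"))


def default_segments() -> list[CopyNumberSegment]:
    """Default clonal cancer genotype: 30 Mb cnLoH on chr1, 50 Mb gain on chr2."""
    return [
        CopyNumberSegment(GenomicInterval("1", 10_000_000, 40_000_000), 2, 0),
        CopyNumberSegment(GenomicInterval("2", 0, 50_000_000), 2, 1),
    ]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    Depth defaults match the observed single-cell coverage (mean 1522
    informative reads per cell); the toy genome is three 100-Mb
    chromosomes, dense enough in SNPs that per-segment read counts are
    realistic while staying small.
    """

    seed: int = 0
    chrom_lengths: tuple[tuple[str, int], ...] = (
        ("1", 100_000_000),
        ("2", 100_000_000),
        ("3", 100_000_000),
    )
    segments: tuple[CopyNumberSegment, ...] = field(
        default_factory=lambda: tuple(default_segments())
    )
    subclone_segments: tuple[CopyNumberSegment, ...] = ()
    snp_density: float = 20.0  # het SNPs per Mb, placed within genes
    genes_per_mb: float = 1.0
    gene_length: int = 20_000
    n_exons: int = 5
    exon_fraction: float = 0.25
    n_cancer: int = 300
    n_normal: int = 200
    n_subclone: int = 0
    mean_informative_reads: float = 1522.0
    depth_dispersion: float = 2.0  # negative-binomial shape of per-cell totals
    epsilon: tuple[tuple[str, float], ...] = (("exonic", 0.01), ("intronic", 0.05))
    ase_spread: float = 30.0  # Beta concentration of true per-gene rho
    phi: float = 0.2  # true beta-binomial overdispersion
    expression_sigma: float = 1.0  # log-normal spread of gene expression weights
    bulk_depth: float = 100.0  # mean DNA read depth per site

    @property
    def registry(self) -> GenomeRegistry:
        return GenomeRegistry(dict(self.chrom_lengths))

    @property
    def epsilon_by_class(self) -> dict[str, float]:
        return dict(self.epsilon)


@dataclass
class Reference:
    """Simulated static inputs plus the per-SNP/per-gene truth."""

    registry: GenomeRegistry
    gene_model: GeneModel
    snps: pd.DataFrame  # chrom,pos,ref,alt,gene,site_class,alt_on_hap_a
    segments: list[CopyNumberSegment]
    rho_by_gene: pd.DataFrame  # gene,rho,weight


@dataclass
class SimTruth:
    """Ground truth emitted alongside the simulated cell counts."""

    cells: pd.DataFrame  # cell,clone
    rho_by_gene: pd.DataFrame
    phi: float
    genotypes: dict[str, CancerGenotype]


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    # independent, reproducible stream per stage so e.g. regenerating
    # cells does not perturb the reference
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stage]))


def simulate_reference(cfg: SimConfig) -> Reference:
    """Generate genome, gene model, het SNPs and truth annotations.

    Genes are placed one per ``1/genes_per_mb`` slot (non-overlapping),
    each with ``n_exons`` evenly spaced exon blocks totalling
    ``exon_fraction`` of the gene. SNPs land uniformly within randomly
    chosen genes at ``snp_density`` per Mb of chromosome.
    """
    rng = _rng(cfg, 0)
    registry = cfg.registry
    genes, exons = [], []
    gene_rows = []
    for chrom in registry.chromosomes:
        length = registry[chrom]
        n_genes = int(round(cfg.genes_per_mb * length / 1e6))
        slot = length / max(n_genes, 1)
        for i in range(n_genes):
            lo = int(i * slot)
            hi = int(min((i + 1) * slot, length)) - cfg.gene_length
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            name = f"G{chrom}_{i:04d}"
            genes.append((name, chrom, start, start + cfg.gene_length))
            block = cfg.gene_length / cfg.n_exons
            exon_len = int(block * cfg.exon_fraction)
            for j in range(cfg.n_exons):
                ex_start = start + int(j * block)
                exons.append((name, chrom, ex_start, ex_start + exon_len))
            gene_rows.append((name, chrom))
    cols = ["gene", "chrom", "start", "end"]
    gene_model = GeneModel(
        pd.DataFrame(genes, columns=cols), pd.DataFrame(exons, columns=cols)
    )

    snp_rows = []
    gene_df = gene_model.genes
    for chrom in registry.chromosomes:
        cg = gene_df[gene_df["chrom"] == chrom].reset_index(drop=True)
        n_snps = int(round(cfg.snp_density * registry[chrom] / 1e6))
        if not len(cg):
            if n_snps:
                logger.warning("chromosome %s has no genes; no SNPs placed", chrom)
            continue
        gidx = rng.integers(0, len(cg), size=n_snps)
        for gi in gidx:
            g = cg.iloc[int(gi)]
            pos0 = int(rng.integers(g["start"], g["end"]))
            snp_rows.append((chrom, pos0 + 1))
    snps = (
        pd.DataFrame(snp_rows, columns=["chrom", "pos"])
        .drop_duplicates()
        .sort_values(["chrom", "pos"])
        .reset_index(drop=True)
    )
    ref_idx = rng.integers(0, 4, size=len(snps))
    alt_shift = rng.integers(1, 4, size=len(snps))
    snps["ref"] = _BASES[ref_idx]
    snps["alt"] = _BASES[(ref_idx + alt_shift) % 4]
    ann = annotate_snps(snps, gene_model, imprinted=())
    snps = snps.merge(ann, on=["chrom", "pos"])
    snps["alt_on_hap_a"] = rng.random(len(snps)) < 0.5

    gene_names = gene_model.genes["gene"]
    half = cfg.ase_spread / 2.0
    rho = rng.beta(half, half, size=len(gene_names))
    weight = rng.lognormal(0.0, cfg.expression_sigma, size=len(gene_names))
    rho_by_gene = pd.DataFrame({"gene": gene_names, "rho": rho, "weight": weight})

    for seg in cfg.segments + cfg.subclone_segments:
        n_in = int(
            (
                (snps["chrom"] == seg.interval.chrom)
                & (snps["pos"] - 1 >= seg.interval.start)
                & (snps["pos"] - 1 < seg.interval.end)
            ).sum()
        )
        if n_in == 0:
            logger.warning("segment %s contains no simulated SNPs", seg.segment_id)

    return Reference(registry, gene_model, snps, list(cfg.segments), rho_by_gene)


def _segment_f(
    snps: pd.DataFrame, segments: Sequence[CopyNumberSegment]
) -> np.ndarray:
    """Major-haplotype fraction per SNP under a genotype (0.5 outside segments)."""
    f = np.full(len(snps), 0.5)
    chrom = snps["chrom"].to_numpy()
    pos0 = snps["pos"].to_numpy() - 1
    for seg in segments:
        total = seg.n_major + seg.n_minor
        if total == 0:
            continue
        mask = (
            (chrom == seg.interval.chrom)
            & (pos0 >= seg.interval.start)
            & (pos0 < seg.interval.end)
        )
        f[mask] = seg.n_major / total
    return f


def simulate_bulk_dna(
    cfg: SimConfig,
    ref: Reference,
    purity: float = 1.0,
    depth: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bulk DNA allele counts at each het SNP for normal and tumour samples.

    Normal DNA draws alt reads from Binomial(depth, 0.5). Tumour DNA
    mixes the tumour genotype with normal contamination at the given
    ``purity``: the alt-read fraction is the alt-allele copy fraction of
    the mixture, resolved through each SNP's haplotype assignment.
    Clonal segments contribute at their ``cell_fraction``; subclone
    segments at the subclone's share of tumour cells, so their BAF shift
    is attenuated exactly as a minority population dilutes bulk DNA.
    """
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity {purity} outside (0, 1]")
    depth = cfg.bulk_depth if depth is None else depth
    rng = _rng(cfg, 1)
    snps = ref.snps
    n = len(snps)
    d_norm = rng.poisson(depth, size=n)
    d_tum = rng.poisson(depth, size=n)
    alt_norm = rng.binomial(d_norm, 0.5)

    maj = np.ones(n)
    mino = np.ones(n)
    chrom = snps["chrom"].to_numpy()
    pos0 = snps["pos"].to_numpy() - 1
    n_tumour_cells = cfg.n_cancer + cfg.n_subclone
    sub_cf = cfg.n_subclone / n_tumour_cells if n_tumour_cells else 0.0
    seg_fracs = [(seg, seg.cell_fraction) for seg in cfg.segments]
    seg_fracs += [(seg, sub_cf) for seg in cfg.subclone_segments if sub_cf > 0]
    for seg, cf in seg_fracs:
        mask = (
            (chrom == seg.interval.chrom)
            & (pos0 >= seg.interval.start)
            & (pos0 < seg.interval.end)
        )
        maj[mask] = cf * seg.n_major + (1.0 - cf) * 1.0
        mino[mask] = cf * seg.n_minor + (1.0 - cf) * 1.0
    alt_on_a = snps["alt_on_hap_a"].to_numpy()
    alt_copies = purity * np.where(alt_on_a, maj, mino) + (1.0 - purity) * 1.0
    tot_copies = purity * (maj + mino) + (1.0 - purity) * 2.0
    baf = np.divide(alt_copies, tot_copies, out=np.zeros(n), where=tot_copies > 0)
    alt_tum = rng.binomial(d_tum, baf)

    base = snps.loc[:, ["chrom", "pos", "ref", "alt"]]
    normal = base.assign(ref_count=d_norm - alt_norm, alt_count=alt_norm)
    tumour = base.assign(ref_count=d_tum - alt_tum, alt_count=alt_tum)
    return normal, tumour


def simulate_cells(cfg: SimConfig, ref: Reference) -> tuple[pd.DataFrame, SimTruth]:
    """Per-cell ref/alt allele counts plus ground truth.

    Per cell: an overdispersed (negative-binomial) total of informative
    reads, scattered multinomially over SNPs in proportion to gene
    expression weights; at each covered SNP the major-haplotype read
    count is beta-binomial with mean r_s(f) -- f from the cell's clone
    genotype, rho from the gene, eps from the site class -- and
    overdispersion ``phi``. Counts are reported as ref/alt through the
    recorded haplotype assignment.
    """
    rng = _rng(cfg, 2)
    snps = ref.snps
    eps_map = cfg.epsilon_by_class
    eps = snps["site_class"].map(lambda c: eps_map.get(c, 0.0)).to_numpy()
    rho_map = dict(zip(ref.rho_by_gene["gene"], ref.rho_by_gene["rho"]))
    rho = snps["gene"].map(lambda g: rho_map.get(g, 0.5)).to_numpy()
    w_map = dict(zip(ref.rho_by_gene["gene"], ref.rho_by_gene["weight"]))
    weights = snps["gene"].map(lambda g: w_map.get(g, 0.0)).to_numpy()
    p_snp = weights / weights.sum()

    genotypes = {
        "normal": CancerGenotype("normal", []),
        "cancer": CancerGenotype.from_segments("cancer", cfg.segments),
        "subclone": CancerGenotype.from_segments(
            "subclone", list(cfg.segments) + list(cfg.subclone_segments)
        ),
    }
    f_by_clone = {
        "normal": np.full(len(snps), 0.5),
        "cancer": _segment_f(snps, cfg.segments),
        "subclone": _segment_f(
            snps, list(cfg.segments) + list(cfg.subclone_segments)
        ),
    }
    r_by_clone = {
        # keep r inside (0,1): f=1 with eps=0 would give a degenerate beta
        clone: np.clip(
            expected_allelic_ratio(np.clip(f, 1e-12, 1.0), rho, eps),
            1e-12,
            1.0 - 1e-12,
        )
        for clone, f in f_by_clone.items()
    }

    clones = (
        ["cancer"] * cfg.n_cancer
        + ["subclone"] * cfg.n_subclone
        + ["normal"] * cfg.n_normal
    )
    cells = [f"cell_{i:05d}" for i in range(len(clones))]
    k = cfg.depth_dispersion
    mu = cfg.mean_informative_reads
    totals = rng.negative_binomial(k, k / (k + mu), size=len(cells))
    counts = rng.multinomial(totals, p_snp)  # cells x snps

    theta = (1.0 - cfg.phi) / cfg.phi
    alt_on_a = snps["alt_on_hap_a"].to_numpy()
    rows = []
    for ci, (cell, clone) in enumerate(zip(cells, clones)):
        nz = np.nonzero(counts[ci])[0]
        if len(nz) == 0:
            continue
        n_reads = counts[ci, nz]
        r = r_by_clone[clone][nz]
        if cfg.phi > 1e-9:
            p = rng.beta(r * theta, (1.0 - r) * theta)
        else:
            p = r
        hap_a = rng.binomial(n_reads, p)
        alt = np.where(alt_on_a[nz], hap_a, n_reads - hap_a)
        rows.append(
            pd.DataFrame(
                {
                    "cell": cell,
                    "chrom": snps["chrom"].to_numpy()[nz],
                    "pos": snps["pos"].to_numpy()[nz],
                    "ref": snps["ref"].to_numpy()[nz],
                    "alt": snps["alt"].to_numpy()[nz],
                    "ref_count": n_reads - alt,
                    "alt_count": alt,
                }
            )
        )
    counts_df = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=["cell", "chrom", "pos", "ref", "alt", "ref_count", "alt_count"]
        )
    )
    truth = SimTruth(
        cells=pd.DataFrame({"cell": cells, "clone": clones}),
        rho_by_gene=ref.rho_by_gene,
        phi=cfg.phi,
        genotypes=genotypes,
    )
    return counts_df, truth
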