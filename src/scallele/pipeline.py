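"""End-to-end orchestration of the four-step genotyping workflow.

Steps: (1) call heterozygous SNPs from normal DNA and clean the
copy-number segments; (2) phase SNPs in copy-number-imbalanced segments
from tumour DNA; (3) annotate, filter and orient the per-cell counts;
(4) calibrate the error/ASE/overdispersion parameters on normal cells
and compute each cell's posterior cancer-genotype probability.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import hetsnps, io, model, sc_counts
from .core import CancerGenotype, clean_segments

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Paths and model constants for a full run.

    The defaults are the published configuration: BAF window [0.2, 0.8],
    5% FDR for both binomial-test families, error rates 0.01/0.05, ASE
    high-count threshold 400, posterior thresholds 0.99/0.01.
    """

    segments: str
    registry: str
    normal_dna_counts: str
    tumour_dna_counts: str
    cell_counts: str
    out_dir: str
    gene_model: str | None = None  # BED12; absent -> all sites intergenic
    normal_cells: str | None = None  # one barcode per line
    imprinted: str | None = None  # one gene symbol per line
    baf_low: float = 0.2
    baf_high: float = 0.8
    fdr: float = 0.05
    epsilon: dict[str, float] = field(
        default_factory=lambda: dict(model.DEFAULT_EPSILON)
    )
    ase_spread: float | str = "fit"
    high_count_threshold: int = 400
    default_phi: float = model.DEFAULT_PHI
    thresh_hi: float = 0.99
    thresh_lo: float = 0.01
    clean_cn_segments: bool = True


def _read_lines(path: str) -> list[str]:
    return [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]


def run_pipeline(cfg: RunConfig) -> pd.DataFrame:
    """Run all four steps; write calls and a JSON summary to ``out_dir``.

    Returns the per-cell calls table. Raises :class:`PipelineError` with
    the failing stage's name on any error.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load-inputs"
    try:
        registry = io.read_registry(cfg.registry)
        segments = io.read_segments(cfg.segments)
        normal_dna = io.read_site_counts(cfg.normal_dna_counts)
        tumour_dna = io.read_site_counts(cfg.tumour_dna_counts)
        raw_cells = io.read_cell_counts(cfg.cell_counts)
        gene_model = (
            sc_counts.GeneModel.from_bed12(cfg.gene_model) if cfg.gene_model else None
        )
        normal_cell_ids = _read_lines(cfg.normal_cells) if cfg.normal_cells else []
        imprinted = _read_lines(cfg.imprinted) if cfg.imprinted else None
        if raw_cells.empty:
            raise ValueError("cell counts file contains no records")

        stage = "het-snps-and-segments"
        if cfg.clean_cn_segments:
            segments = clean_segments(segments, registry)
        hets = hetsnps.call_het_snps(
            normal_dna, baf_low=cfg.baf_low, baf_high=cfg.baf_high, fdr=cfg.fdr
        )
        het_keys = hets.loc[:, ["chrom", "pos"]]

        stage = "phase"
        tumour_at_hets = tumour_dna.merge(het_keys, on=["chrom", "pos"])
        phased = hetsnps.phase_segments(tumour_at_hets, segments, fdr=cfg.fdr)
        if phased.empty:
            raise ValueError("no SNPs could be phased in imbalanced segments")

        stage = "count-orient"
        ann = sc_counts.annotate_snps(phased, gene_model, imprinted)
        retained = sc_counts.filter_snps(raw_cells, ann)
        filtered = sc_counts.apply_site_filter(raw_cells, retained)
        phased_ann = phased.merge(
            retained.loc[:, ["chrom", "pos", "gene", "site_class"]],
            on=["chrom", "pos"],
        )
        oriented = sc_counts.orient_counts(filtered, phased_ann)
        oriented = oriented.merge(
            retained.loc[:, ["chrom", "pos", "gene", "site_class"]],
            on=["chrom", "pos"],
        )
        if oriented.empty:
            raise ValueError("no oriented counts left after filtering")

        stage = "calibrate"
        error = model.calibrate_error(defaults=cfg.epsilon)
        normal_oriented = (
            oriented[oriented["cell"].isin(normal_cell_ids)]
            if normal_cell_ids
            else None
        )
        ase = model.fit_ase(
            normal_oriented,
            spread=cfg.ase_spread,
            high_count_threshold=cfg.high_count_threshold,
        )
        phi = model.fit_overdispersion(
            normal_oriented, error, ase, default_phi=cfg.default_phi
        )
        params = model.ModelParams(error, ase, phi)

        stage = "call"
        genotype = CancerGenotype.from_segments("cancer", segments)
        if len(genotype) == 0:
            raise ValueError("no allelically informative copy-number segments")
        all_cells = sorted(raw_cells["cell"].unique())
        calls = model.call_cells(
            oriented,
            genotype,
            params,
            cells=all_cells,
            thresh_hi=cfg.thresh_hi,
            thresh_lo=cfg.thresh_lo,
        )
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    io.write_calls(calls, out / "calls.tsv")
    phased_out = phased.copy()
    io.write_vcf_sites(phased_out, out / "phased_snps.vcf", registry=registry)
    summary = {
        "n_cells": len(calls),
        "n_phased_snps": int(len(phased)),
        "n_retained_snps": int(len(retained)),
        "cells_per_label": calls["label"].value_counts().to_dict(),
        "mean_informative_reads": float(calls["n_informative_reads"].mean()),
        "ase_prior_spread": float(params.ase.prior_spread),
        "overdispersion_phi": float(params.overdispersion.phi),
        "epsilon": dict(params.error.epsilon_by_class),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    logger.info("pipeline complete: %s", summary["cells_per_label"])
    return calls
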