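"""Shared fixtures: seeded simulations reused across test modules.

The expensive published-depth simulations are session-scoped so the
classifier-calibration, evaluation and recovery tests share one run.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from scallele import hetsnps, model, sc_counts
from scallele.core import CopyNumberSegment, GenomicInterval
from scallele.simulate import SimConfig, simulate_bulk_dna, simulate_cells, simulate_reference

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def run_reference_pipeline(cfg: SimConfig):
    """Simulate a bundle and run phasing/orientation/calibration on it.

    Returns a dict with the simulated objects, the oriented counts with
    annotations, fitted parameters, and the truth table.
    """
    ref = simulate_reference(cfg)
    normal_dna, tumour_dna = simulate_bulk_dna(cfg, ref)
    cells, truth = simulate_cells(cfg, ref)

    hets = hetsnps.call_het_snps(normal_dna)
    tumour_at_hets = tumour_dna.merge(hets[["chrom", "pos"]], on=["chrom", "pos"])
    segments = list(cfg.segments) + list(cfg.subclone_segments)
    phased = hetsnps.phase_segments(tumour_at_hets, segments)

    ann = sc_counts.annotate_snps(phased, ref.gene_model, imprinted=())
    retained = sc_counts.filter_snps(cells, ann)
    filtered = sc_counts.apply_site_filter(cells, retained)
    oriented = sc_counts.orient_counts(filtered, phased).merge(
        retained[["chrom", "pos", "gene", "site_class"]], on=["chrom", "pos"]
    )

    normal_ids = set(truth.cells.loc[truth.cells["clone"] == "normal", "cell"])
    normal_oriented = oriented[oriented["cell"].isin(normal_ids)]
    error = model.calibrate_error(defaults=cfg.epsilon_by_class)
    ase = model.fit_ase(normal_oriented if len(normal_oriented) else None)
    phi = model.fit_overdispersion(
        normal_oriented if len(normal_oriented) else None, error, ase
    )
    return {
        "cfg": cfg,
        "ref": ref,
        "cells": cells,
        "truth": truth,
        "phased": phased,
        "oriented": oriented,
        "normal_oriented": normal_oriented,
        "params": model.ModelParams(error, ase, phi),
    }


@pytest.fixture(scope="session")
def study_sim():
    """Published-depth mixed population: 300 cancer + 200 normal cells at a
    mean of 1522 informative reads/cell; 30 Mb cnLoH + 50 Mb gain."""
    return run_reference_pipeline(SimConfig(seed=5))


@pytest.fixture(scope="session")
def normal_only_sim():
    """500 normal cells for parameter-recovery checks."""
    return run_reference_pipeline(SimConfig(seed=4, n_cancer=0, n_normal=500))


@pytest.fixture(scope="session")
def subclone_sim():
    """Tumour with a 100 Mb cnLoH subclone in 30% of cancer cells
    (897 major clone + 385 subclone), mirroring a two-clone tumour."""
    sub_seg = CopyNumberSegment(GenomicInterval("3", 0, 100_000_000), 2, 0)
    cfg = SimConfig(
        seed=8,
        n_cancer=897,
        n_subclone=385,
        n_normal=100,
        subclone_segments=(sub_seg,),
    )
    return run_reference_pipeline(cfg)
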