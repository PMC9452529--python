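"""Beta-binomial posterior classification of cancer vs normal genotypes.

The model compares two hypotheses for each cell. Under the *cancer*
hypothesis every copy-number-altered segment R has major-allele fraction
``f = a_R`` implied by the DNA copy numbers (1 for LoH, 2/3 for a
single-copy gain, ...); under the *normal* hypothesis ``f = 0.5``
everywhere. Three nuisance processes are calibrated from normal cells:

* a site-class error rate ``eps`` (defaults: exonic 0.01, intronic 0.05),
  estimated by counting non-reference reads at homozygous-reference sites;
* a per-gene allele-specific-expression (ASE) ratio ``rho`` with a
  Beta(mean 0.5) conjugate prior whose spread is set manually or fitted
  to highly expressed genes (> 400 counts by default);
* a single beta-binomial overdispersion ``phi`` in (0, 1), capturing
  extra-binomial variance from transcriptional bursting, fitted by
  maximum likelihood; ``theta = (1 - phi) / phi`` is the beta
  concentration, so ``phi -> 0`` recovers the binomial.

The expected major-allele read fraction at SNP s is

    r_s(f) = (f rho_s / (f rho_s + (1 - f)(1 - rho_s))) (1 - 2 eps_s) + eps_s

and the likelihood of (m_s, n_s) major/minor reads is beta-binomial with
mean r_s(f) and concentration theta. The cell-level posterior, with a
flat prior over the two hypotheses, is

    P(cancer | data) = P(data | cancer) / (P(data | cancer) + P(data | normal))

with cells called cancer above 0.99, normal below 0.01, else unassigned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.special import betaln, expit, gammaln
from scipy.stats import binom, norm

from .core import CancerGenotype

logger = logging.getLogger(__name__)

__all__ = [
    "ErrorModel",
    "ASEModel",
    "Overdispersion",
    "ModelParams",
    "calibrate_error",
    "fit_ase",
    "fit_overdispersion",
    "expected_allelic_ratio",
    "snp_log_likelihood",
    "genotype_log_likelihood",
    "normal_hypothesis",
    "cancer_posterior",
    "call_cells",
    "assign_subclones",
    "min_detectable_loh",
    "detectability_sweep",
    "DETECTABILITY_MODES",
]

DEFAULT_EPSILON = {"exonic": 0.01, "intronic": 0.05}
DEFAULT_ASE_SPREAD = 10.0
DEFAULT_PHI = 0.2
THRESH_HI = 0.99
THRESH_LO = 0.01


@dataclass(frozen=True)
class ErrorModel:
    """Site-class sequencing/alignment error rates eps in [0, 0.5)."""

    epsilon_by_class: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EPSILON)
    )

    def __post_init__(self) -> None:
        for cls, eps in self.epsilon_by_class.items():
            if not (0.0 <= eps < 0.5):
                raise ValueError(f"epsilon for {cls!r} must be in [0, 0.5), got {eps}")

    def epsilon(self, site_class: str) -> float:
        # unknown classes get the most pessimistic configured rate
        if site_class in self.epsilon_by_class:
            return self.epsilon_by_class[site_class]
        return max(self.epsilon_by_class.values())

    def epsilon_array(self, site_classes: Iterable[str]) -> np.ndarray:
        return np.array([self.epsilon(c) for c in site_classes])


@dataclass(frozen=True)
class ASEModel:
    """Per-gene allele-specific expression ratios with their Beta posterior.

    ``rho_by_gene`` holds posterior means; genes absent from the map get
    the prior mean 0.5 (both alleles equally likely).
    """

    prior_spread: float = DEFAULT_ASE_SPREAD
    rho_by_gene: Mapping[str, float] = field(default_factory=dict)
    posterior_by_gene: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def rho(self, gene: str) -> float:
        return self.rho_by_gene.get(gene, 0.5)

    def rho_array(self, genes: Iterable[str]) -> np.ndarray:
        return np.array([self.rho(g) for g in genes])


@dataclass(frozen=True)
class Overdispersion:
    """Beta-binomial overdispersion phi in (0, 1); theta = (1 - phi) / phi."""

    phi: float = DEFAULT_PHI

    def __post_init__(self) -> None:
        if not (0.0 < self.phi < 1.0):
            raise ValueError(f"phi must be in (0, 1), got {self.phi}")

    @property
    def theta(self) -> float:
        return (1.0 - self.phi) / self.phi


@dataclass(frozen=True)
class ModelParams:
    """Bundle of calibrated nuisance parameters for the classifier."""

    error: ErrorModel = field(default_factory=ErrorModel)
    ase: ASEModel = field(default_factory=ASEModel)
    overdispersion: Overdispersion = field(default_factory=Overdispersion)


def calibrate_error(
    hom_ref_sites: pd.DataFrame | None = None,
    defaults: Mapping[str, float] = DEFAULT_EPSILON,
) -> ErrorModel:
    """Estimate per-class error rates from homozygous-reference sites.

    ``hom_ref_sites`` needs columns ``site_class, ref_count, alt_count``
    where every site is truly homozygous reference, so alt reads are
    errors: eps = total non-reference reads / total reads per class.
    Classes without data (or no input at all) fall back to the defaults.
    """
    eps = dict(defaults)
    if hom_ref_sites is not None and len(hom_ref_sites):
        grouped = hom_ref_sites.groupby("site_class")[["ref_count", "alt_count"]].sum()
        for cls, row in grouped.iterrows():
            total = row["ref_count"] + row["alt_count"]
            if total <= 0:
                logger.warning("no reads for site class %r; keeping default", cls)
                continue
            eps[cls] = float(row["alt_count"] / total)
    return ErrorModel(eps)


def _fit_prior_spread(
    major: np.ndarray, minor: np.ndarray, lo: float = 1e-2, hi: float = 1e6
) -> float:
    """ML concentration of a mean-0.5 Beta prior from per-gene counts.

    Marginal (beta-binomial) likelihood of the aggregated per-gene counts
    under rho_g ~ Beta(c/2, c/2); optimized over log-concentration.
    """

    def nll(log_c: float) -> float:
        half = math.exp(log_c) / 2.0
        return -float(
            np.sum(betaln(major + half, minor + half) - betaln(half, half))
        )

    res = minimize_scalar(
        nll, bounds=(math.log(lo), math.log(hi)), method="bounded"
    )
    return float(math.exp(res.x))


def fit_ase(
    normal_counts: pd.DataFrame | None,
    spread: float | str = "fit",
    high_count_threshold: int = 400,
) -> ASEModel:
    """Fit per-gene ASE ratios from normal cells.

    Aggregates major/minor counts per gene across normal cells and
    applies a conjugate Beta update of the Beta(mean 0.5, ``spread``)
    prior; ``rho`` is the posterior mean. With ``spread="fit"`` the prior
    concentration is the maximum-likelihood value from genes with more
    than ``high_count_threshold`` total counts. Without normal cells
    every gene keeps rho = 0.5.
    """
    if normal_counts is None or len(normal_counts) == 0:
        logger.warning("no normal-cell counts: ASE ratios set to 0.5 for all genes")
        s = DEFAULT_ASE_SPREAD if spread == "fit" else float(spread)
        return ASEModel(prior_spread=s)
    per_gene = normal_counts.groupby("gene")[["major_count", "minor_count"]].sum()
    per_gene = per_gene[per_gene.index != ""]
    major = per_gene["major_count"].to_numpy(dtype=float)
    minor = per_gene["minor_count"].to_numpy(dtype=float)
    if spread == "fit":
        high = major + minor > high_count_threshold
        if high.sum() >= 2:
            s = _fit_prior_spread(major[high], minor[high])
        else:
            logger.warning(
                "fewer than 2 genes above %d counts; using default prior spread",
                high_count_threshold,
            )
            s = DEFAULT_ASE_SPREAD
    else:
        s = float(spread)
    a = major + s / 2.0
    b = minor + s / 2.0
    rho = a / (a + b)
    return ASEModel(
        prior_spread=s,
        rho_by_gene=dict(zip(per_gene.index, rho)),
        posterior_by_gene={g: (ai, bi) for g, ai, bi in zip(per_gene.index, a, b)},
    )


def expected_allelic_ratio(f, rho=0.5, eps=0.0):
    """Expected major-allele read fraction r_s(f); vectorized.

    ``f`` is the major-haplotype copy fraction of the segment, ``rho``
    the gene's ASE ratio, ``eps`` the site-class error rate. Returns
    values in [eps, 1 - eps].
    """
    f = np.asarray(f, dtype=float)
    rho = np.asarray(rho, dtype=float)
    eps = np.asarray(eps, dtype=float)
    if np.any((f <= 0) | (f > 1)):
        raise ValueError("f must lie in (0, 1]")
    if np.any((rho <= 0) | (rho >= 1)):
        raise ValueError("rho must lie in (0, 1)")
    if np.any((eps < 0) | (eps >= 0.5)):
        raise ValueError("eps must lie in [0, 0.5)")
    inner = f * rho / (f * rho + (1.0 - f) * (1.0 - rho))
    out = inner * (1.0 - 2.0 * eps) + eps
    return out if out.ndim else float(out)


def snp_log_likelihood(m, n, r, phi):
    """Log beta-binomial probability of m major / n minor reads; vectorized.

    Parameterized by the beta mean ``r`` and overdispersion ``phi``
    (concentration theta = (1 - phi)/phi). Includes the binomial
    coefficient C(m + n, m); (m, n) = (0, 0) gives log 1 = 0.
    """
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    r = np.asarray(r, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any((r <= 0) | (r >= 1)):
        raise ValueError("r must lie in (0, 1)")
    if np.any((phi <= 0) | (phi >= 1)):
        raise ValueError("phi must lie in (0, 1)")
    theta = (1.0 - phi) / phi
    a = r * theta
    b = (1.0 - r) * theta
    out = (
        gammaln(m + n + 1)
        - gammaln(m + 1)
        - gammaln(n + 1)
        + betaln(m + a, n + b)
        - betaln(a, b)
    )
    return out if out.ndim else float(out)


def fit_overdispersion(
    normal_counts: pd.DataFrame | None,
    error: ErrorModel,
    ase: ASEModel,
    default_phi: float = DEFAULT_PHI,
    bounds: tuple[float, float] = (1e-6, 1.0 - 1e-6),
) -> Overdispersion:
    """Maximum-likelihood beta-binomial overdispersion from normal cells.

    Normal cells have f = 0.5 everywhere, so each observation's expected
    ratio is r_s(0.5) with the calibrated error and ASE values; a single
    global phi maximizes the summed log-likelihood (bounded search).
    Without data the configured default is returned with a warning.
    """
    if normal_counts is None or len(normal_counts) == 0:
        logger.warning("no normal-cell counts: overdispersion set to %g", default_phi)
        return Overdispersion(default_phi)
    m = normal_counts["major_count"].to_numpy(dtype=float)
    n = normal_counts["minor_count"].to_numpy(dtype=float)
    r = expected_allelic_ratio(
        0.5,
        ase.rho_array(normal_counts["gene"]),
        error.epsilon_array(normal_counts["site_class"]),
    )
    informative = m + n > 1  # single-read observations carry no phi signal
    if not informative.any():
        logger.warning(
            "all normal-cell observations are single reads; likelihood is flat in "
            "phi, returning default %g",
            default_phi,
        )
        return Overdispersion(default_phi)

    def nll(phi: float) -> float:
        return -float(np.sum(snp_log_likelihood(m, n, r, phi)))

    res = minimize_scalar(nll, bounds=bounds, method="bounded")
    return Overdispersion(float(res.x))


def normal_hypothesis(segment_ids: Iterable[str]) -> dict[str, float]:
    """The normal genotype: f = 0.5 on every segment."""
    return {sid: 0.5 for sid in segment_ids}


def _as_fraction_map(hyp) -> dict[str, float]:
    if isinstance(hyp, CancerGenotype):
        return hyp.fraction_by_segment()
    return dict(hyp)


def _row_log_likelihoods(
    counts: pd.DataFrame, f_by_segment: Mapping[str, float], params: ModelParams
) -> np.ndarray:
    """Per-row log-likelihood under a hypothesis; rows outside it get 0."""
    f = counts["segment_id"].map(f_by_segment)
    inside = f.notna().to_numpy()
    out = np.zeros(len(counts))
    if not inside.any():
        return out
    sub = counts.loc[inside]
    genes = sub["gene"] if "gene" in sub.columns else pd.Series("", index=sub.index)
    classes = (
        sub["site_class"]
        if "site_class" in sub.columns
        else pd.Series("exonic", index=sub.index)
    )
    r = expected_allelic_ratio(
        f[inside].to_numpy(dtype=float),
        params.ase.rho_array(genes),
        params.error.epsilon_array(classes),
    )
    # f=1 with eps=0 gives r=1 exactly; nudge into the open interval the
    # beta-binomial needs (minor reads then carry ~27 nats against LoH)
    r = np.clip(r, 1e-12, 1.0 - 1e-12)
    out[inside] = snp_log_likelihood(
        sub["major_count"].to_numpy(dtype=float),
        sub["minor_count"].to_numpy(dtype=float),
        r,
        params.overdispersion.phi,
    )
    return out


def genotype_log_likelihood(
    cell_counts: pd.DataFrame, hyp, params: ModelParams
) -> float:
    """Log P(data | hypothesis) for one cell's per-SNP counts.

    ``hyp`` is a :class:`CancerGenotype` or a mapping segment_id -> f.
    SNPs outside the hypothesis segments are ignored: only copy-number
    changed regions inform the call.
    """
    return float(np.sum(_row_log_likelihoods(cell_counts, _as_fraction_map(hyp), params)))


def _label(posterior: np.ndarray, hi: float, lo: float, names) -> np.ndarray:
    labels = np.full(len(posterior), names[2], dtype=object)
    labels[posterior > hi] = names[0]
    labels[posterior < lo] = names[1]
    return labels


def call_cells(
    counts: pd.DataFrame,
    genotype,
    params: ModelParams,
    cells: Sequence[str] | None = None,
    thresh_hi: float = THRESH_HI,
    thresh_lo: float = THRESH_LO,
) -> pd.DataFrame:
    """Posterior cancer-genotype probability and label for every cell.

    ``counts`` is a long oriented table (cell, segment_id, gene,
    site_class, major_count, minor_count). The normal hypothesis is
    f = 0.5 on the same segments; the posterior assumes a flat prior.
    Cells listed in ``cells`` but absent from the table (no informative
    reads) get posterior 0.5 and label ``unassigned``.

    Returns columns ``cell, posterior_cancer, label, n_informative_reads,
    loglik_cancer, loglik_normal``.
    """
    f_cancer = _as_fraction_map(genotype)
    f_normal = normal_hypothesis(f_cancer)
    ll_c = _row_log_likelihoods(counts, f_cancer, params)
    ll_n = _row_log_likelihoods(counts, f_normal, params)
    in_hyp = counts["segment_id"].isin(f_cancer).to_numpy()
    reads = (counts["major_count"] + counts["minor_count"]).to_numpy() * in_hyp
    per_cell = (
        pd.DataFrame(
            {
                "cell": counts["cell"].to_numpy(),
                "loglik_cancer": ll_c,
                "loglik_normal": ll_n,
                "n_informative_reads": reads,
            }
        )
        .groupby("cell", as_index=False)
        .sum()
    )
    if cells is not None:
        per_cell = (
            per_cell.set_index("cell")
            .reindex(pd.Index(cells, name="cell"), fill_value=0.0)
            .reset_index()
        )
    # flat prior; expit of the log-likelihood difference is numerically stable
    post = expit(per_cell["loglik_cancer"] - per_cell["loglik_normal"])
    per_cell["posterior_cancer"] = post
    per_cell["label"] = _label(
        post.to_numpy(), thresh_hi, thresh_lo, ("cancer", "normal", "unassigned")
    )
    per_cell["n_informative_reads"] = per_cell["n_informative_reads"].astype(int)
    cols = [
        "cell",
        "posterior_cancer",
        "label",
        "n_informative_reads",
        "loglik_cancer",
        "loglik_normal",
    ]
    return per_cell.loc[:, cols]


def cancer_posterior(
    cell_counts: pd.DataFrame,
    genotype,
    params: ModelParams,
    thresh_hi: float = THRESH_HI,
    thresh_lo: float = THRESH_LO,
) -> tuple[float, str]:
    """Posterior P(cancer | data) and label for a single cell's counts."""
    ll_c = genotype_log_likelihood(cell_counts, genotype, params)
    f_normal = normal_hypothesis(_as_fraction_map(genotype))
    ll_n = genotype_log_likelihood(cell_counts, f_normal, params)
    post = float(expit(ll_c - ll_n))
    if post > thresh_hi:
        return post, "cancer"
    if post < thresh_lo:
        return post, "normal"
    return post, "unassigned"


def assign_subclones(
    counts: pd.DataFrame,
    subclone_hyp,
    major_clone_hyp,
    params: ModelParams,
    cells: Sequence[str] | None = None,
    thresh_hi: float = THRESH_HI,
    thresh_lo: float = THRESH_LO,
) -> pd.DataFrame:
    """Assign cancer cells to a subclone vs the major clone.

    The two genotype hypotheses must differ on at least one segment; the
    posterior is computed on the distinguishing segments only (shared
    segments cancel and carry no information). Cells with posterior
    > 0.99 for the subclone genotype are labelled ``subclone``, < 0.01
    ``major-clone``, otherwise ``ambiguous``.
    """
    f_sub = _as_fraction_map(subclone_hyp)
    f_major = _as_fraction_map(major_clone_hyp)
    all_ids = set(f_sub) | set(f_major)
    distinguishing = {
        sid
        for sid in all_ids
        if not math.isclose(f_sub.get(sid, 0.5), f_major.get(sid, 0.5))
    }
    if not distinguishing:
        raise ValueError("subclone and major-clone hypotheses are identical")
    f_sub_d = {sid: f_sub.get(sid, 0.5) for sid in distinguishing}
    f_major_d = {sid: f_major.get(sid, 0.5) for sid in distinguishing}
    ll_s = _row_log_likelihoods(counts, f_sub_d, params)
    ll_m = _row_log_likelihoods(counts, f_major_d, params)
    per_cell = (
        pd.DataFrame(
            {
                "cell": counts["cell"].to_numpy(),
                "loglik_subclone": ll_s,
                "loglik_major_clone": ll_m,
            }
        )
        .groupby("cell", as_index=False)
        .sum()
    )
    if cells is not None:
        per_cell = (
            per_cell.set_index("cell")
            .reindex(pd.Index(cells, name="cell"), fill_value=0.0)
            .reset_index()
        )
    post = expit(per_cell["loglik_subclone"] - per_cell["loglik_major_clone"])
    per_cell["posterior_subclone"] = post
    per_cell["label"] = _label(
        post.to_numpy(), thresh_hi, thresh_lo, ("subclone", "major-clone", "ambiguous")
    )
    return per_cell


# ---------------------------------------------------------------------------
# minimum detectable loss of heterozygosity
# ---------------------------------------------------------------------------

DETECTABILITY_MODES = ("posterior-threshold", "balanced-accuracy", "power-normal")


def _loh_log_lr(n_reads, eps: float, phi: float | None) -> float:
    """Log likelihood ratio of n all-major reads: LoH (f=1) vs diploid (f=0.5)."""
    r1 = 1.0 - eps
    if phi is None:
        return float(n_reads) * (math.log(r1) - math.log(0.5))
    return float(
        snp_log_likelihood(n_reads, 0.0, r1, phi)
        - snp_log_likelihood(n_reads, 0.0, 0.5, phi)
    )


def _betabinom_pmf(k: np.ndarray, n: int, r: float, phi: float) -> np.ndarray:
    return np.exp(snp_log_likelihood(k, n - k, r, phi))


def min_detectable_loh(
    reads_per_mb: float = 0.5,
    accuracy: float = 0.99,
    eps: float = 0.0,
    phi: float | None = None,
    mode: str = "posterior-threshold",
    integer_reads: bool = True,
    max_reads: int = 10_000,
) -> float:
    """Smallest LoH length (Mb) detectable in one transcriptome.

    ``reads_per_mb`` is the density of informative reads (reads covering
    phased heterozygous SNPs); a region of length L supplies
    ``n = L * reads_per_mb`` reads whose major-allele counts follow a
    binomial (or beta-binomial when ``phi`` is set) with success
    probability 1 - eps under LoH and 0.5 under the normal genotype.
    "Accuracy" admits several formalizations, exposed as modes:

    ``posterior-threshold``
        the cleanest all-major-reads bound: smallest n whose likelihood
        ratio reaches accuracy / (1 - accuracy), i.e. the flat-prior
        posterior of the LoH hypothesis reaches ``accuracy``. With
        eps = 0 and integer reads this is the smallest n with
        2**n > accuracy/(1 - accuracy) (n = 7, L = 14 Mb at defaults).
    ``balanced-accuracy``
        smallest integer n for which a read-count threshold exists with
        both misclassification rates at most 1 - accuracy (exact
        binomial / beta-binomial tail enumeration).
    ``power-normal``
        normal-approximation power calculation for separating
        Bin(n, 0.5) from Bin(n, 1 - eps) with two-sided level and power
        1 - accuracy: n = [z (sqrt(v0) + sqrt(v1))]^2 / (0.5 - eps)^2
        with z the two-sided (1 - accuracy) normal quantile; continuous
        in n. With ``phi`` the variances are inflated by the
        beta-binomial factor 1 + (n - 1) phi (solved by fixed point).

    Returns L in megabases. Doubling the read density halves L in every
    mode; increasing ``accuracy`` never shrinks L.
    """
    if reads_per_mb <= 0:
        raise ValueError("reads_per_mb must be positive")
    if not (0.5 < accuracy < 1.0):
        raise ValueError("accuracy must lie in (0.5, 1)")
    if mode not in DETECTABILITY_MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {DETECTABILITY_MODES}")

    alpha = 1.0 - accuracy
    log_odds = math.log(accuracy / alpha)
    r1 = 1.0 - eps

    if mode == "posterior-threshold":
        if integer_reads:
            for n in range(1, max_reads + 1):
                if _loh_log_lr(n, eps, phi) > log_odds:
                    return n / reads_per_mb
            raise RuntimeError("no read count below max_reads reaches the threshold")
        n_star = brentq(
            lambda x: _loh_log_lr(x, eps, phi) - log_odds, 1e-9, float(max_reads)
        )
        return float(n_star) / reads_per_mb

    if mode == "balanced-accuracy":
        for n in range(1, max_reads + 1):
            k = np.arange(n + 1)
            if phi is None:
                p_norm = binom.pmf(k, n, 0.5)
                p_loh = binom.pmf(k, n, r1)
            else:
                p_norm = _betabinom_pmf(k, n, 0.5, phi)
                p_loh = _betabinom_pmf(k, n, r1, phi)
            # classify LoH when majors >= threshold; scan thresholds
            fp = np.concatenate([[1.0], 1.0 - np.cumsum(p_norm)])  # P(X >= t | normal)
            fn = np.concatenate([[0.0], np.cumsum(p_loh)])  # P(X < t | LoH)
            if np.any((fp <= alpha) & (fn <= alpha)):
                return n / reads_per_mb
        raise RuntimeError("no read count below max_reads reaches the accuracy")

    # power-normal
    z = norm.ppf(1.0 - alpha / 2.0)
    delta = r1 - 0.5
    if delta <= 0:
        raise ValueError("eps too large: LoH and normal ratios coincide")

    def n_of(infl: float) -> float:
        v0 = 0.5 * 0.5 * infl
        v1 = r1 * (1.0 - r1) * infl
        return (z * (math.sqrt(v0) + math.sqrt(v1))) ** 2 / delta**2

    n = n_of(1.0)
    if phi is not None:
        for _ in range(200):  # fixed point for the variance inflation 1+(n-1)phi
            n_new = n_of(1.0 + (max(n, 1.0) - 1.0) * phi)
            if abs(n_new - n) < 1e-10:
                break
            n = n_new
        n = n_new
    return n / reads_per_mb


def detectability_sweep(
    reads_per_mb: float = 0.5,
    accuracy: float = 0.99,
    exonic_eps: float = DEFAULT_EPSILON["exonic"],
    phi: float | None = None,
) -> dict[str, float]:
    """Minimum detectable LoH (Mb) under each documented interpretation.

    Runs every mode with eps = 0 and with the default exonic error rate,
    keyed ``"<mode>"`` and ``"<mode>-eps"``. The ``power-normal-eps``
    entry (binomial sampling, 99% sensitivity and specificity, exonic
    error rate) is the headline figure; ``posterior-threshold`` with
    eps = 0 is the closed-form lower bound.
    """
    out: dict[str, float] = {}
    for mode in DETECTABILITY_MODES:
        out[mode] = min_detectable_loh(
            reads_per_mb, accuracy, eps=0.0, phi=phi, mode=mode
        )
        out[f"{mode}-eps"] = min_detectable_loh(
            reads_per_mb, accuracy, eps=exonic_eps, phi=phi, mode=mode
        )
    return out
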