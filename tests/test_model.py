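"""The beta-binomial classifier: calibration, likelihoods, posteriors."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import binom

from scallele.model import (
    ASEModel,
    ErrorModel,
    ModelParams,
    Overdispersion,
    assign_subclones,
    calibrate_error,
    call_cells,
    cancer_posterior,
    expected_allelic_ratio,
    fit_ase,
    fit_overdispersion,
    genotype_log_likelihood,
    min_detectable_loh,
    snp_log_likelihood,
)

TINY_PHI = 1e-8  # beta-binomial at phi -> 0 is binomial


def oriented(rows, seg="s1", gene="g1", site_class="exonic"):
    """Build a per-SNP oriented counts table for one or more cells."""
    return pd.DataFrame(
        [
            {
                "cell": r[0],
                "segment_id": seg,
                "gene": gene,
                "site_class": site_class,
                "major_count": r[1],
                "minor_count": r[2],
            }
            for r in rows
        ]
    )


def binom_params(eps=0.0, phi=TINY_PHI, rho=None):
    return ModelParams(
        ErrorModel({"exonic": eps, "intronic": eps}),
        ASEModel(rho_by_gene=rho or {}),
        Overdispersion(phi),
    )


class TestCalibrateError:
    def test_counts_non_reference_reads(self):
        sites = pd.DataFrame(
            {
                "site_class": ["exonic", "intronic"],
                "ref_count": [198, 95],
                "alt_count": [2, 5],
            }
        )
        em = calibrate_error(sites)
        assert em.epsilon("exonic") == pytest.approx(0.01)
        assert em.epsilon("intronic") == pytest.approx(0.05)

    def test_no_input_gives_defaults(self):
        em = calibrate_error()
        assert em.epsilon("exonic") == 0.01 and em.epsilon("intronic") == 0.05

    def test_zero_read_class_keeps_default(self, caplog):
        sites = pd.DataFrame(
            {"site_class": ["exonic"], "ref_count": [0], "alt_count": [0]}
        )
        with caplog.at_level("WARNING"):
            em = calibrate_error(sites)
        assert em.epsilon("exonic") == 0.01


class TestFitAse:
    def norm_counts(self, major, minor, gene="g1"):
        return pd.DataFrame(
            {"gene": [gene], "major_count": [major], "minor_count": [minor]}
        )

    def test_gene_without_reads_keeps_prior_mean(self):
        ase = fit_ase(self.norm_counts(500, 500), spread=10)
        assert ase.rho("unseen_gene") == 0.5

    def test_symmetric_data_stays_near_half(self):
        ase = fit_ase(self.norm_counts(500, 500), spread=10)
        assert ase.rho("g1") == pytest.approx(0.5, abs=0.01)

    def test_conjugate_beta_update(self):
        # Beta(5,5) prior + (800, 200) counts -> posterior mean 805/1010
        ase = fit_ase(self.norm_counts(800, 200), spread=10)
        assert ase.rho("g1") == pytest.approx(805 / 1010, abs=1e-9)

    def test_no_normal_cells_gives_uniform_model(self, caplog):
        with caplog.at_level("WARNING"):
            ase = fit_ase(None)
        assert ase.rho("anything") == 0.5

    def test_fitted_spread_recovers_prior_concentration(self):
        # genes' true rho drawn from Beta(15, 15) (concentration 30); with
        # high counts the ML prior spread should land near 30
        rng = np.random.default_rng(3)
        n_genes = 400
        rho = rng.beta(15, 15, size=n_genes)
        totals = rng.poisson(2000, size=n_genes)
        major = rng.binomial(totals, rho)
        df = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(n_genes)],
                "major_count": major,
                "minor_count": totals - major,
            }
        )
        ase = fit_ase(df, spread="fit")
        assert 20 < ase.prior_spread < 45


class TestExpectedAllelicRatio:
    @pytest.mark.parametrize(
        "f,rho,eps,expected",
        [
            (0.5, 0.5, 0.0, 0.5),
            (1.0, 0.5, 0.01, 0.99),
            (2 / 3, 0.5, 0.0, 2 / 3),
            (0.5, 0.8, 0.0, 0.8),  # pure ASE shift at balanced copy number
            (1.0, 0.5, 0.05, 0.95),
        ],
    )
    def test_closed_form(self, f, rho, eps, expected):
        assert expected_allelic_ratio(f, rho, eps) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            expected_allelic_ratio(0.0, 0.5, 0.0)
        with pytest.raises(ValueError):
            expected_allelic_ratio(0.5, 0.5, 0.6)

    @given(
        f=st.floats(0.01, 1.0),
        rho=st.floats(0.01, 0.99),
        eps=st.floats(0.0, 0.49),
    )
    def test_bounded_by_error_rate(self, f, rho, eps):
        r = expected_allelic_ratio(f, rho, eps)
        assert eps - 1e-12 <= r <= 1 - eps + 1e-12


class TestSnpLogLikelihood:
    def test_single_read_probability_is_r(self):
        for phi in (0.01, 0.3, 0.9):
            assert snp_log_likelihood(1, 0, 0.7, phi) == pytest.approx(math.log(0.7))

    def test_direct_evaluation_theta_one(self):
        # theta=1: C(2,1) B(1.5,1.5)/B(0.5,0.5) = 0.25
        assert snp_log_likelihood(1, 1, 0.5, 0.5) == pytest.approx(math.log(0.25))

    def test_empty_observation_is_certain(self):
        assert snp_log_likelihood(0, 0, 0.3, 0.2) == 0.0

    def test_binomial_limit(self):
        m, n = np.meshgrid(np.arange(21), np.arange(21))
        m, n = m.ravel(), n.ravel()
        for r in (0.1, 0.5, 0.9):
            ours = snp_log_likelihood(m, n, r, TINY_PHI)
            ref = binom.logpmf(m, m + n, r)
            assert np.max(np.abs(ours - ref)) < 1e-4

    @given(
        total=st.integers(1, 30),
        r=st.floats(0.05, 0.95),
        phi=st.floats(0.01, 0.95),
    )
    def test_normalizes_over_outcomes(self, total, r, phi):
        m = np.arange(total + 1)
        probs = np.exp(snp_log_likelihood(m, total - m, r, phi))
        assert probs.sum() == pytest.approx(1.0, abs=1e-8)


class TestFitOverdispersion:
    def test_binomial_data_fits_small_phi(self):
        rng = np.random.default_rng(0)
        major = rng.binomial(10, 0.5, size=10_000)
        df = pd.DataFrame(
            {
                "gene": "g",
                "site_class": "exonic",
                "major_count": major,
                "minor_count": 10 - major,
            }
        )
        od = fit_overdispersion(df, ErrorModel({"exonic": 0.0}), ASEModel())
        assert od.phi < 0.02

    def test_recovers_true_overdispersion(self):
        rng = np.random.default_rng(1)
        theta = (1 - 0.2) / 0.2
        p = rng.beta(0.5 * theta, 0.5 * theta, size=5000)
        major = rng.binomial(20, p)
        df = pd.DataFrame(
            {
                "gene": "g",
                "site_class": "exonic",
                "major_count": major,
                "minor_count": 20 - major,
            }
        )
        od = fit_overdispersion(df, ErrorModel({"exonic": 0.0}), ASEModel())
        assert 0.15 <= od.phi <= 0.25

    def test_single_read_likelihood_flat_returns_default(self, caplog):
        df = pd.DataFrame(
            {"gene": ["g"], "site_class": ["exonic"], "major_count": [1],
             "minor_count": [0]}
        )
        with caplog.at_level("WARNING"):
            od = fit_overdispersion(df, ErrorModel(), ASEModel(), default_phi=0.2)
        assert od.phi == 0.2
        assert "flat" in caplog.text

    def test_no_data_returns_default(self, caplog):
        with caplog.at_level("WARNING"):
            od = fit_overdispersion(None, ErrorModel(), ASEModel(), default_phi=0.3)
        assert od.phi == 0.3


class TestGenotypeLikelihoodAndPosterior:
    def test_zero_reads_gives_flat_posterior(self):
        counts = oriented([("c1", 0, 0)])
        post, label = cancer_posterior(counts, {"s1": 1.0}, binom_params(eps=0.01))
        assert post == pytest.approx(0.5)
        assert label == "unassigned"

    def test_loh_binomial_closed_form(self):
        # 20 major reads on an LoH segment, eps=0.01, phi -> 0:
        # posterior = 0.99^20 / (0.99^20 + 0.5^20)
        counts = oriented([("c1", 20, 0)])
        params = binom_params(eps=0.01)
        ll_cancer = genotype_log_likelihood(counts, {"s1": 1.0}, params)
        assert ll_cancer == pytest.approx(20 * math.log(0.99), abs=1e-3)
        ll_normal = genotype_log_likelihood(counts, {"s1": 0.5}, params)
        assert ll_normal == pytest.approx(20 * math.log(0.5), abs=1e-3)
        post, label = cancer_posterior(counts, {"s1": 1.0}, params)
        expected = 0.99**20 / (0.99**20 + 0.5**20)
        assert post == pytest.approx(expected, rel=1e-4)
        assert label == "cancer"

    def test_minor_reads_give_normal_call(self):
        counts = oriented([("c1", 0, 20)])
        post, label = cancer_posterior(counts, {"s1": 1.0}, binom_params(eps=0.01))
        expected = 0.01**20 / (0.01**20 + 0.5**20)
        assert post == pytest.approx(expected, rel=1e-3)
        assert label == "normal"

    def test_snps_outside_hypothesis_ignored(self):
        inside = oriented([("c1", 20, 0)])
        extra = oriented([("c1", 0, 50)], seg="elsewhere")
        params = binom_params(eps=0.01)
        assert genotype_log_likelihood(
            pd.concat([inside, extra]), {"s1": 1.0}, params
        ) == pytest.approx(genotype_log_likelihood(inside, {"s1": 1.0}, params))

    def test_swapping_counts_mirrors_hypothesis_ranking(self):
        params = binom_params(eps=0.0, rho={"g1": 0.5})
        fwd = oriented([("c1", 12, 3)])
        rev = oriented([("c1", 3, 12)])
        ll_f = genotype_log_likelihood(fwd, {"s1": 2 / 3}, params)
        ll_r = genotype_log_likelihood(rev, {"s1": 1 / 3}, params)
        assert ll_f == pytest.approx(ll_r)

    def test_posterior_plus_complement_is_one(self):
        counts = oriented([("c1", 5, 3)])
        params = binom_params(eps=0.01, phi=0.2)
        post, _ = cancer_posterior(counts, {"s1": 1.0}, params)
        ll_c = genotype_log_likelihood(counts, {"s1": 1.0}, params)
        ll_n = genotype_log_likelihood(counts, {"s1": 0.5}, params)
        post_normal = 1 / (1 + math.exp(ll_c - ll_n))
        assert post + post_normal == pytest.approx(1.0, abs=1e-12)

    @given(m=st.integers(0, 30))
    def test_posterior_monotone_in_major_reads(self, m):
        params = binom_params(eps=0.01, phi=0.2)
        p1, _ = cancer_posterior(oriented([("c1", m, 2)]), {"s1": 1.0}, params)
        p2, _ = cancer_posterior(oriented([("c1", m + 1, 2)]), {"s1": 1.0}, params)
        assert p2 >= p1

    def test_call_cells_includes_readless_cells(self):
        counts = oriented([("c1", 20, 0)])
        calls = call_cells(counts, {"s1": 1.0}, binom_params(eps=0.01),
                           cells=["c1", "c2"])
        c2 = calls.set_index("cell").loc["c2"]
        assert c2["label"] == "unassigned"
        assert c2["posterior_cancer"] == pytest.approx(0.5)
        assert c2["n_informative_reads"] == 0


class TestAssignSubclones:
    def test_strong_loh_evidence_assigns_subclone(self):
        # 15 major reads on the distinguishing cnLoH segment, eps=0, phi->0:
        # posterior = 1 / (1 + 0.5^15)
        counts = oriented([("c1", 15, 0)], seg="chr4")
        res = assign_subclones(counts, {"chr4": 1.0}, {"chr4": 0.5}, binom_params())
        assert res["posterior_subclone"].iloc[0] == pytest.approx(1 / (1 + 0.5**15))
        assert res["label"].iloc[0] == "subclone"

    def test_mixed_reads_ambiguous(self):
        counts = oriented([("c1", 4, 3)], seg="chr4")
        res = assign_subclones(
            counts, {"chr4": 1.0}, {"chr4": 0.5}, binom_params(eps=0.01, phi=0.2)
        )
        assert res["label"].iloc[0] == "ambiguous"

    def test_no_reads_on_distinguishing_segment_ambiguous(self):
        counts = oriented([("c1", 30, 0)], seg="shared")
        res = assign_subclones(
            counts,
            {"shared": 1.0, "chr4": 1.0},
            {"shared": 1.0, "chr4": 0.5},
            binom_params(),
            cells=["c1"],
        )
        assert res["label"].iloc[0] == "ambiguous"
        assert res["posterior_subclone"].iloc[0] == pytest.approx(0.5)

    def test_identical_hypotheses_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            assign_subclones(
                oriented([("c1", 1, 0)]), {"s1": 1.0}, {"s1": 1.0}, binom_params()
            )


class TestMinDetectableLoh:
    def test_posterior_threshold_closed_form(self):
        # smallest integer n with 2^n > 99 is 7 -> 14 Mb at 0.5 reads/Mb
        assert min_detectable_loh(0.5, 0.99, eps=0.0) == pytest.approx(14.0)

    def test_density_scale_invariance(self):
        for mode in ("posterior-threshold", "balanced-accuracy", "power-normal"):
            l1 = min_detectable_loh(0.5, 0.99, eps=0.01, mode=mode)
            l2 = min_detectable_loh(1.0, 0.99, eps=0.01, mode=mode)
            assert l1 == pytest.approx(2 * l2)

    def test_stricter_accuracy_needs_longer_region(self):
        for mode in ("posterior-threshold", "balanced-accuracy", "power-normal"):
            assert min_detectable_loh(0.5, 0.999, mode=mode) > min_detectable_loh(
                0.5, 0.99, mode=mode
            )

    def test_invalid_accuracy_rejected(self):
        with pytest.raises(ValueError):
            min_detectable_loh(0.5, 0.4)

    def test_overdispersion_never_shrinks_requirement(self):
        for mode in ("posterior-threshold", "power-normal"):
            base = min_detectable_loh(0.5, 0.99, eps=0.01, mode=mode)
            inflated = min_detectable_loh(0.5, 0.99, eps=0.01, phi=0.2, mode=mode)
            assert inflated >= base
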