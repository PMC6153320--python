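"""Bayes factors against a quadrature oracle, q-values, p-values, consensus."""

import math

import numpy as np
import pytest
from scipy import integrate, stats
from statsmodels.stats.multitest import multipletests

from dnmprior.core_io import ExtremeCountTable, GeneCounts
from dnmprior.tada import (
    ConfigurationError,
    GeneRates,
    GeneRateTable,
    RateSource,
    TadaGeneResult,
    TadaParams,
    attach_bh_qvalues,
    bayesian_qvalues,
    bh_adjust,
    class_bayes_factor,
    consensus_call,
    gene_bayes_factor,
    posterior_null_probability,
    read_rate_table,
    read_tada_results,
    run_tada,
    simulation_pvalues,
    write_rate_table,
    write_tada_results,
)

PARAMS = TadaParams()


def quadrature_bf(x: int, lam: float, gamma_bar: float, beta: float) -> float:
    """Independent oracle: integrate Poisson(x; lam*g) over the Gamma prior."""
    shape = gamma_bar * beta

    def integrand(g):
        return stats.poisson.pmf(x, lam * g) * stats.gamma.pdf(g, shape, scale=1 / beta)

    # the integrand is proportional to a Gamma(x + shape, beta + lam) density,
    # so integrate over that posterior's bulk and anchor quad at its mode
    post = stats.gamma(x + shape, scale=1.0 / (beta + lam))
    upper = float(post.ppf(1 - 1e-15))
    mode = max((x + shape - 1) / (beta + lam), 0.0)
    marginal, _ = integrate.quad(
        integrand, 0.0, upper, points=[mode], epsabs=1e-300, epsrel=1e-12, limit=400
    )
    return marginal / stats.poisson.pmf(x, lam)


class TestClassBayesFactor:
    def test_degenerate_prior_gives_bf_one(self):
        # gamma_bar = 1 + eps with huge beta pins the relative risk at ~1
        bf = class_bayes_factor(3, 0.02, gamma_bar=1.0000001, beta=1e6)
        assert bf == pytest.approx(1.0, rel=1e-3)

    def test_x_zero_small_lambda_tends_to_one(self):
        assert class_bayes_factor(0, 1e-12, 20, 1) == pytest.approx(1.0, rel=1e-6)

    def test_lambda_zero_conventions(self):
        assert class_bayes_factor(0, 0.0, 20, 1) == 1.0
        with pytest.raises(ValueError, match="impossible"):
            class_bayes_factor(1, 0.0, 20, 1)

    def test_reference_value_against_quadrature(self):
        # two LoF DNMs at lambda = 2*1000*1e-5
        bf = class_bayes_factor(2, 0.02, 20, 1)
        assert bf == pytest.approx(277.16, abs=0.01)
        assert bf == pytest.approx(quadrature_bf(2, 0.02, 20, 1), rel=1e-6)

    @pytest.mark.parametrize("x", [0, 1, 3, 6])
    @pytest.mark.parametrize("lam", [1e-4, 1e-2, 1.0])
    @pytest.mark.parametrize("gamma_bar", [2.0, 20.0])
    @pytest.mark.parametrize("beta", [0.2, 1.0, 5.0])
    def test_closed_form_equals_quadrature(self, x, lam, gamma_bar, beta):
        closed = class_bayes_factor(x, lam, gamma_bar, beta)
        oracle = quadrature_bf(x, lam, gamma_bar, beta)
        assert closed == pytest.approx(oracle, rel=1e-6)

    def test_monotone_in_x_for_risk_prior(self):
        for lam in (1e-4, 1e-2, 1.0):
            bfs = [class_bayes_factor(x, lam, 20, 1) for x in range(8)]
            assert all(b2 >= b1 for b1, b2 in zip(bfs, bfs[1:]))

    def test_log_space_finite_at_large_counts(self):
        from dnmprior.tada import log_class_bayes_factor

        assert math.isfinite(log_class_bayes_factor(10_000, 1.0, 20, 1))


class TestGeneBayesFactor:
    def test_multiplicativity_and_zero_counts(self):
        # at tiny lambda, the zero-count Bayes factor per class tends to 1
        rates = GeneRates(mu_lof=1e-7, mu_dmis=1e-7)
        res = gene_bayes_factor("G", GeneCounts(), rates, 100, PARAMS)
        assert res.bf_total == pytest.approx(res.bf_lof * res.bf_dmis)
        assert res.bf_total == pytest.approx(1.0, abs=0.05)

    def test_class_product_matches_per_class_oracle(self):
        rates = GeneRates(mu_lof=1e-5, mu_dmis=1e-5)
        counts = GeneCounts(n_lof=2, n_dmis=1)
        res = gene_bayes_factor("G", counts, rates, 1000, PARAMS)
        lam = 0.02
        expected = quadrature_bf(2, lam, PARAMS.gamma_bar_lof, PARAMS.beta_lof) * \
            quadrature_bf(1, lam, PARAMS.gamma_bar_dmis, PARAMS.beta_dmis)
        assert res.bf_total == pytest.approx(expected, rel=1e-6)
        assert res.posterior_null == pytest.approx(
            posterior_null_probability(res.bf_total, PARAMS.pi)
        )

    def test_missing_gene_reported_not_dropped(self):
        counts = ExtremeCountTable()
        counts["ABSENT"] = GeneCounts(n_lof=1, n_total_dnms=1)
        counts["G1"] = GeneCounts(n_lof=1, n_total_dnms=1)
        rates = GeneRateTable(
            source=RateSource.GC, rates={"G1": GeneRates(1e-5, 1e-5)}
        )
        results, skipped = run_tada(counts, rates, 1000, PARAMS)
        assert skipped == ["ABSENT"]
        assert [r.gene for r in results] == ["G1"]


class TestBayesianQvalues:
    def _result(self, gene, bf):
        return TadaGeneResult(
            gene=gene, x_lof=0, x_dmis=0, lambda_lof=0.01, lambda_dmis=0.01,
            bf_lof=bf, bf_dmis=1.0, bf_total=bf,
            posterior_null=posterior_null_probability(bf, PARAMS.pi),
        )

    def test_single_gene(self):
        out = bayesian_qvalues([self._result("A", 50.0)], PARAMS.pi)
        assert out[0].q_bayes == pytest.approx(out[0].posterior_null)

    def test_all_ties_share_worst_q(self):
        out = bayesian_qvalues([self._result(g, 10.0) for g in "ABC"], PARAMS.pi)
        qs = [r.q_bayes for r in out]
        assert qs[0] == qs[1] == qs[2]
        assert qs[0] == pytest.approx(posterior_null_probability(10.0, PARAMS.pi))

    def test_running_mean_hand_oracle(self):
        # genes with BF 100, 10, 1 at pi = 0.05: q_k is the running mean of
        # posterior null probabilities down the BF ranking
        bfs = [100.0, 10.0, 1.0]
        posts = [posterior_null_probability(b, 0.05) for b in bfs]
        expected = [
            posts[0],
            (posts[0] + posts[1]) / 2,
            (posts[0] + posts[1] + posts[2]) / 3,
        ]
        results = [self._result(g, b) for g, b in zip("ABC", bfs)]
        out = bayesian_qvalues(results[::-1], 0.05)  # input order worst-first
        got = {r.gene: r.q_bayes for r in out}
        assert got["A"] == pytest.approx(expected[0])
        assert got["B"] == pytest.approx(expected[1])
        assert got["C"] == pytest.approx(expected[2])
        ranked = sorted(out, key=lambda r: -r.bf_total)
        assert all(
            a.q_bayes <= b.q_bayes + 1e-15 for a, b in zip(ranked, ranked[1:])
        )


class TestSimulationPvalues:
    def _result(self, gene, x_lof, lam=0.02):
        bf = class_bayes_factor(x_lof, lam, PARAMS.gamma_bar_lof, PARAMS.beta_lof)
        return TadaGeneResult(
            gene=gene, x_lof=x_lof, x_dmis=0, lambda_lof=lam, lambda_dmis=0.0,
            bf_lof=bf, bf_dmis=1.0, bf_total=bf,
            posterior_null=posterior_null_probability(bf, PARAMS.pi),
        )

    def test_minimal_bf_gives_p_one(self):
        # x = 0 attains the smallest possible BF, so every null draw ties or beats it
        out = simulation_pvalues([self._result("G", 0)], PARAMS)
        assert out[0].p_value == 1.0

    def test_p_floor_plus_one_correction(self):
        out = simulation_pvalues([self._result("G", 50)], PARAMS)
        assert out[0].p_value >= 1 / (PARAMS.n_null_samples + 1)

    def test_order_independent_per_gene_streams(self):
        results = [self._result("A", 2), self._result("B", 1)]
        fwd = simulation_pvalues(results, PARAMS)
        rev = simulation_pvalues(results[::-1], PARAMS)
        assert {r.gene: r.p_value for r in fwd} == {r.gene: r.p_value for r in rev}

    def test_reproducible_for_fixed_seed(self):
        res = [self._result("A", 2)]
        p1 = simulation_pvalues(res, PARAMS)[0].p_value
        p2 = simulation_pvalues(res, PARAMS)[0].p_value
        assert p1 == p2


class TestBhAdjust:
    def test_single_p(self):
        assert bh_adjust([0.02]) == [pytest.approx(0.02)]

    def test_step_up_brute_force_example(self):
        # q_(i) = min_{j >= i} p_(j) * m / j on sorted p
        got = bh_adjust([0.01, 0.04, 0.03, 0.02])
        assert got == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_matches_statsmodels_on_random_p(self, rng):
        p = rng.uniform(1e-6, 1.0, size=40)
        ours = bh_adjust(p)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(ours, ref)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestConsensus:
    def _results_for(self, qs: dict[str, float]):
        return [
            TadaGeneResult(
                gene=g, x_lof=1, x_dmis=0, lambda_lof=0.01, lambda_dmis=0.01,
                bf_lof=1, bf_dmis=1, bf_total=1, posterior_null=0.5,
                p_value=q, q_bh=q, q_bayes=q,
            )
            for g, q in qs.items()
        ]

    def _counts(self, n_dnms: int):
        table = ExtremeCountTable()
        table["G"] = GeneCounts(n_lof=n_dnms, n_total_dnms=n_dnms)
        return table

    def _per_source(self, qs):
        return {
            src: self._results_for({"G": q})
            for src, q in zip(RateSource, qs)
        }

    def test_three_of_four_with_multiple_dnms_is_high_confidence(self):
        per_source = self._per_source([0.05, 0.08, 0.09, 0.2])
        (res,) = consensus_call(per_source, self._counts(3))
        assert res.n_sources_significant == 3
        assert res.high_confidence

    def test_two_sources_insufficient(self):
        per_source = self._per_source([0.05, 0.08, 0.2, 0.2])
        (res,) = consensus_call(per_source, self._counts(3))
        assert not res.high_confidence

    def test_single_dnm_blocks_high_confidence(self):
        per_source = self._per_source([0.01, 0.01, 0.01, 0.01])
        (res,) = consensus_call(per_source, self._counts(1))
        assert res.n_sources_significant == 4
        assert not res.high_confidence
        assert not res.candidate_03

    def test_relaxed_tier_at_q_03(self):
        per_source = self._per_source([0.15, 0.2, 0.25, 0.5])
        (res,) = consensus_call(per_source, self._counts(2))
        assert not res.high_confidence
        assert res.candidate_03

    def test_gene_missing_from_source_counts_as_not_significant(self):
        per_source = self._per_source([0.05, 0.05, 0.05, 0.05])
        per_source[RateSource.DM] = self._results_for({"OTHER": 0.05})
        (g, other) = sorted(
            consensus_call(per_source, self._counts(3)), key=lambda r: r.gene
        )
        assert g.gene == "G" and g.n_sources_significant == 3
        assert other.q_by_source[RateSource.GC] is None

    def test_min_sources_exceeding_sources_is_config_error(self):
        per_source = self._per_source([0.05, 0.05, 0.05, 0.05])
        with pytest.raises(ConfigurationError):
            consensus_call(per_source, self._counts(3), min_sources=5)

    def test_q_method_switch(self):
        results = self._results_for({"G": 0.05})
        for r in results:
            r.q_bayes = 0.5  # bayes q would not pass
        per_source = {src: results for src in RateSource}
        (res_bh,) = consensus_call(per_source, self._counts(2), q_method="bh")
        (res_bayes,) = consensus_call(per_source, self._counts(2), q_method="bayes")
        assert res_bh.high_confidence and not res_bayes.high_confidence


class TestRateTableIO:
    def test_round_trip(self, tmp_path):
        table = GeneRateTable(
            source=RateSource.SC,
            rates={"G1": GeneRates(1e-5, 2e-5), "G2": GeneRates(3e-6, 4e-6)},
        )
        path = tmp_path / "rates.tsv"
        write_rate_table(table, path)
        back = read_rate_table(path, "SC")
        assert back.rates["G1"].mu_lof == pytest.approx(1e-5)
        assert back.rates["G2"].mu_dmis == pytest.approx(4e-6)

    def test_total_rate_split(self, tmp_path):
        path = tmp_path / "total.tsv"
        path.write_text("gene\tmu_total\nG1\t1e-5\n")
        table = read_rate_table(path, "MF", lof_split=0.1, dmis_split=0.3)
        assert table.rates["G1"].mu_lof == pytest.approx(1e-6)
        assert table.rates["G1"].mu_dmis == pytest.approx(3e-6)

    def test_results_round_trip(self, tmp_path):
        counts = ExtremeCountTable()
        counts["G1"] = GeneCounts(n_lof=2, n_dmis=1, n_total_dnms=3)
        rates = GeneRateTable(
            source=RateSource.GC,
            rates={"G1": GeneRates(1e-5, 1e-5), "G2": GeneRates(2e-5, 1e-5)},
        )
        results, _ = run_tada(counts, rates, 1000, PARAMS)
        results = bayesian_qvalues(results, PARAMS.pi)
        results = simulation_pvalues(results, PARAMS)
        results = attach_bh_qvalues(results)
        path = tmp_path / "tada.tsv"
        write_tada_results(results, path)
        back = {r.gene: r for r in read_tada_results(path)}
        for r in results:
            assert back[r.gene].bf_total == pytest.approx(r.bf_total, rel=1e-4)
            assert back[r.gene].p_value == pytest.approx(r.p_value, rel=1e-4)
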