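"""Effectiveness normalisation, binomial expectations and gene enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import emsmap as em
from emsmap.io_formats import MutationDataset
from emsmap.screen_stats import count_pvalue, poisson_binomial_pmf


def cohort_with_mean(mean_events, n_strains, label):
    rows = [
        (f"{label}{s}", "chrI", i, "G", "A", "SNV")
        for s in range(n_strains)
        for i in range(mean_events)
    ]
    df = pd.DataFrame(rows, columns=["strain", "chrom", "pos", "ref", "alt", "variant_class"])
    return MutationDataset(df, batch_label=label, n_strains=n_strains)


class TestEffectiveness:
    def test_equal_means_give_unit_alpha(self):
        a = cohort_with_mean(50, 3, "a")
        b = cohort_with_mean(50, 4, "b")
        eff = em.batch_effectiveness(a, b)
        assert eff.alpha_1 == pytest.approx(1.0)

    def test_published_cohort_ratio(self):
        # baseline mean 360 vs batch mean 272 events per strain
        eff = em.batch_effectiveness(
            cohort_with_mean(360, 2, "mmp"), cohort_with_mean(272, 2, "dpy")
        )
        assert eff.alpha_1 == pytest.approx(272 / 360)
        assert eff.alpha_1 == pytest.approx(0.7556, abs=1e-4)

    def test_exact_ratio_identity(self):
        eff = em.batch_effectiveness(
            cohort_with_mean(7, 3, "a"), cohort_with_mean(13, 5, "b"), alpha_0=2.0
        )
        assert eff.alpha_1 / eff.alpha_0 == pytest.approx(eff.n_bar_1 / eff.n_bar_0)

    def test_empty_batch_is_error(self):
        a = cohort_with_mean(10, 2, "a")
        empty = MutationDataset(pd.DataFrame(columns=["strain"]), n_strains=2)
        with pytest.raises(ValueError):
            em.batch_effectiveness(a, empty)
        with pytest.raises(ValueError):
            em.batch_effectiveness(empty, a)


class TestExpectations:
    def test_seq_probability_arithmetic(self):
        m = em.MutProbMap({"chrI": np.full(1000, 0.001)})
        assert em.seq_probability(m, "chrI", 0, 1000) == pytest.approx(1.0)
        assert em.seq_probability(m, "chrI", 10, 10) == 0.0

    def test_split_gene_additivity(self):
        rng = np.random.default_rng(0)
        m = em.MutProbMap({"chrI": rng.uniform(0, 1e-4, 5000)})
        gene = em.GeneModel("g", "chrI", [(100, 600), (1200, 1500), (4000, 4800)])
        per_interval = sum(
            em.seq_probability(m, "chrI", s, e) for s, e in gene.intervals
        )
        base_by_base = sum(
            m.values["chrI"][p] for s, e in gene.intervals for p in range(s, e)
        )
        assert em.gene_probability(m, gene) == pytest.approx(per_interval, rel=1e-12)
        assert per_interval == pytest.approx(base_by_base, rel=1e-9)

    def test_expected_count_scaling(self):
        m = em.MutProbMap({"chrI": np.full(1000, 0.001)})
        assert em.expected_count(m, ("chrI", 0, 1000), 38) == pytest.approx(38.0)
        assert em.expected_count(m, ("chrI", 0, 1000), 1) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            em.expected_count(m, ("chrI", 0, 1000), 0)

    def test_interval_outside_map_is_error(self):
        m = em.MutProbMap({"chrI": np.zeros(100)})
        with pytest.raises(ValueError):
            em.seq_probability(m, "chrI", 0, 200)
        with pytest.raises(ValueError):
            em.seq_probability(m, "chrX", 0, 10)

    def test_monte_carlo_mean_matches_expectation(self):
        # 1000 simulated cohorts of independent Bernoulli trials per base
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 5e-3, 200)
        n_strains, n_cohorts = 5, 1000
        counts = rng.binomial(n_strains, p, size=(n_cohorts, len(p))).sum(axis=1)
        E = n_strains * p.sum()
        se = counts.std(ddof=1) / np.sqrt(n_cohorts)
        assert abs(counts.mean() - E) < 3 * se

    def test_alpha_linearity(self):
        rng = np.random.default_rng(2)
        m = em.MutProbMap({"chrI": rng.uniform(0, 1e-4, 3000)})
        gene = em.GeneModel("g", "chrI", [(50, 2950)])
        e1 = em.expected_count(m.rescaled(1.0), gene, 38)
        e2 = em.expected_count(m.rescaled(2.0), gene, 38)
        assert e2 == pytest.approx(2 * e1, rel=1e-12)


class TestBackgroundRemoval:
    def make_pool(self, carrier_counts, n_strains=38):
        rows = []
        for var_idx, k in enumerate(carrier_counts):
            for s in range(k):
                rows.append((f"s{s}", "chrI", 100 + var_idx, "G", "A", "SNV"))
        df = pd.DataFrame(rows, columns=["strain", "chrom", "pos", "ref", "alt", "variant_class"])
        return MutationDataset(df, n_strains=n_strains)

    def test_threshold_rule(self):
        pool = self.make_pool([10, 1])  # 10/38 = 26% >= 25%; 1/38 kept
        clean = em.remove_background(pool, share_frac=0.25)
        assert set(clean.df["pos"]) == {101}

    def test_boundary_share_one(self):
        pool = self.make_pool([38, 37])
        clean = em.remove_background(pool, share_frac=1.0)
        assert set(clean.df["pos"]) == {101}

    def test_strain_count_preserved(self):
        pool = self.make_pool([10, 1])
        assert em.remove_background(pool, 0.25).n_strains == 38

    def test_requires_two_strains(self):
        pool = self.make_pool([1], n_strains=1)
        with pytest.raises(ValueError):
            em.remove_background(pool, 0.25)


class TestPValues:
    def test_exact_poisson_binomial_agrees_with_poisson_limit(self):
        # 1-kb toy gene with E = 1.0: for tiny per-base p the exact count
        # distribution is essentially Poisson, so both p-values agree
        n = 38
        p = np.full(1000, 1.0 / (1000 * n))
        E = n * p.sum()
        assert E == pytest.approx(1.0)
        p_exact = count_pvalue(12, E, p, n, method="exact")
        p_pois = count_pvalue(12, E, method="poisson")
        assert p_exact == pytest.approx(p_pois, rel=1e-3)
        # the upper tail at 12 events for mean 1 is astronomically small
        assert p_pois < 1e-9

    def test_doubling_tail_matches_hand_formula(self):
        for obs, mean in [(12, 1.0), (0, 3.0), (3, 3.0), (9, 2.5)]:
            expect = min(
                1.0,
                2 * min(stats.poisson.cdf(obs, mean), stats.poisson.sf(obs - 1, mean)),
            )
            got = count_pvalue(obs, mean, method="poisson", tail="doubling")
            assert got == pytest.approx(expect, rel=1e-12)

    def test_observation_at_expectation_not_significant(self):
        for tail in ("midp", "doubling"):
            assert count_pvalue(3, 3.0, method="poisson", tail=tail) > 0.5

    def test_one_sided_midp(self):
        mean, obs = 2.0, 6
        expect = stats.poisson.sf(obs - 1, mean) - 0.5 * stats.poisson.pmf(obs, mean)
        got = count_pvalue(obs, mean, method="poisson", tail="midp", alternative="greater")
        assert got == pytest.approx(expect, rel=1e-9)

    def test_poisson_binomial_pmf_moments(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 0.01, 50)
        n = 7
        pmf = poisson_binomial_pmf(p, n)
        k = np.arange(len(pmf))
        assert pmf.sum() == pytest.approx(1.0)
        assert (pmf * k).sum() == pytest.approx(n * p.sum(), rel=1e-6)
        var = (pmf * k**2).sum() - (pmf * k).sum() ** 2
        assert var == pytest.approx((n * p * (1 - p)).sum(), rel=1e-4)


def brute_force_bh(p):
    """Benjamini-Hochberg step-up, straight from the definition."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestEnrichment:
    @pytest.fixture(scope="class")
    def screen_setup(self, toy_genome, toy_truth, toy_genes, toy_cohort):
        causal = list(toy_genes.values())[len(toy_genes) // 3]
        pool = em.simulate_screen(
            toy_truth, causal, n_selected=38, n_background=4, seed=33, genes=toy_genes
        )
        clean = em.remove_background(pool, 0.25)
        tmap = em.MutProbMap({c: v.copy() for c, v in toy_truth.true_p.items()})
        alpha = em.batch_effectiveness(toy_cohort, clean).alpha_1
        res = em.gene_enrichment(clean, toy_genes, tmap, alpha_1=alpha)
        return causal, res

    def test_causal_gene_ranks_first(self, screen_setup):
        causal, res = screen_setup
        assert res.iloc[0]["gene_id"] == causal.gene_id
        assert res.iloc[0]["significant"]

    def test_fold_change_identity(self, screen_setup):
        _, res = screen_setup
        np.testing.assert_allclose(
            res["fold_change"] * res["expected"], res["observed"], rtol=1e-12
        )

    def test_only_mutated_genes_tested(self, screen_setup):
        _, res = screen_setup
        assert (res["observed"] > 0).all()

    def test_q_values_match_brute_force_bh(self, screen_setup):
        _, res = screen_setup
        np.testing.assert_allclose(
            res["q_value"], brute_force_bh(res["p_value"]), rtol=1e-12
        )
        assert (res["q_value"] >= res["p_value"] - 1e-15).all()

    def test_high_impact_causal_hits_per_strain(self, toy_truth, toy_genes):
        causal = list(toy_genes.values())[5]
        pool = em.simulate_screen(toy_truth, causal, n_selected=20, seed=44, genes=toy_genes)
        prof = em.impact_profile(pool, causal)
        # every selected strain carries at least one high-impact causal hit
        assert len(prof.per_strain_high_impact) == 20
        assert prof.high_impact >= 20


class TestImpactProfile:
    def make_pool(self, impacts, variant_classes=None):
        n = len(impacts)
        vc = variant_classes or ["SNV"] * n
        rows = [
            (f"s{i}", "chrI", 100 + i, "G", "AA" if vc[i] == "InDel" else "A", vc[i], impacts[i])
            for i in range(n)
        ]
        df = pd.DataFrame(
            rows, columns=["strain", "chrom", "pos", "ref", "alt", "variant_class", "impact"]
        )
        return MutationDataset(df, n_strains=n)

    def test_high_impact_counting(self):
        pool = self.make_pool(["missense", "missense", "missense", "synonymous"])
        gene = em.GeneModel("g", "chrI", [(50, 200)])
        prof = em.impact_profile(pool, gene)
        assert prof.high_impact == 3
        assert prof.counts == {"missense": 3, "synonymous": 1}

    def test_indel_is_high_impact(self):
        pool = self.make_pool([None, "synonymous"], ["InDel", "SNV"])
        prof = em.impact_profile(pool, em.GeneModel("g", "chrI", [(50, 200)]))
        assert prof.high_impact == 1 and prof.counts["InDel"] == 1

    def test_empty_gene(self):
        pool = self.make_pool(["missense"])
        prof = em.impact_profile(pool, em.GeneModel("g", "chrI", [(5000, 6000)]))
        assert prof.high_impact == 0 and prof.counts == {}

    def test_unknown_annotation_becomes_other(self):
        pool = self.make_pool(["frameshift_wat"])
        prof = em.impact_profile(pool, em.GeneModel("g", "chrI", [(50, 200)]))
        assert prof.counts == {"other": 1}
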