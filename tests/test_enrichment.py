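"""Enrichment regression, bi-allelic expectations, down-sampling, power."""

import itertools

import numpy as np
import pytest
from scipy import stats

import biphase as bp
from biphase.enrichment import (
    _expected_table,
    association_power,
    poisson_gene_set_enrichment,
)


def brute_force_biallelic_probs(qs):
    """Exact P(hom), P(CH) by enumerating all 4^k haplotype-pair states."""
    p_hom = p_ch = 0.0
    k = len(qs)
    for h1 in itertools.product([0, 1], repeat=k):
        for h2 in itertools.product([0, 1], repeat=k):
            pr = 1.0
            for q, a, b in zip(qs, h1, h2):
                pr *= (q if a else 1 - q) * (q if b else 1 - q)
            hom = any(a and b for a, b in zip(h1, h2))
            if hom:
                p_hom += pr
            elif any(h1) and any(h2):
                p_ch += pr
    return p_hom, p_ch


class TestAnalyticProbability:
    def test_single_site(self):
        p_hom, p_ch = bp.analytic_biallelic_probability([0.01])
        assert p_hom == pytest.approx(1e-4)
        assert p_ch == 0.0

    def test_two_sites_first_order(self):
        p_hom, p_ch = bp.analytic_biallelic_probability([0.01, 0.01])
        assert p_ch == pytest.approx(2e-4, rel=0.02)

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_matches_exhaustive_enumeration(self, k):
        rng = np.random.default_rng(k)
        qs = rng.uniform(0.01, 0.4, k)
        p_hom, p_ch = bp.analytic_biallelic_probability(qs)
        e_hom, e_ch = brute_force_biallelic_probs(qs)
        assert p_hom == pytest.approx(e_hom, rel=1e-10)
        assert p_ch == pytest.approx(e_ch, rel=1e-10, abs=1e-12)

    def test_invalid_maf(self):
        with pytest.raises(ValueError):
            bp.analytic_biallelic_probability([0.0, 0.1])
        with pytest.raises(ValueError):
            bp.analytic_biallelic_probability([0.6])


class TestExpectedCounts:
    def test_single_site_expectation(self):
        out = bp.expected_biallelic_counts([0.01], n_samples=10000, seed=1)
        assert out["hom"] == pytest.approx(1.0, abs=1.5)
        assert out["ch"] == 0.0

    def test_zero_maf_zero_counts(self):
        assert bp.expected_biallelic_counts([0.0, 0.0], 1000) == {
            "hom": 0.0,
            "ch": 0.0,
        }

    def test_agrees_with_analytic_across_genes(self):
        rng = np.random.default_rng(2)
        sim_h, ana_h, sim_c, ana_c = [], [], [], []
        n = 4000
        for g in range(20):
            qs = 10 ** rng.uniform(-2.5, -1.0, rng.integers(1, 6))
            p_hom, p_ch = bp.analytic_biallelic_probability(qs)
            out = bp.expected_biallelic_counts(qs, n, seed=g)
            sim_h.append(out["hom"]), ana_h.append(n * p_hom)
            sim_c.append(out["ch"]), ana_c.append(n * p_ch)
        r_h = stats.pearsonr(sim_h, ana_h).statistic
        r_c = stats.pearsonr(sim_c, ana_c).statistic
        assert r_h > 0.99 and r_c > 0.99


class TestPoissonEnrichment:
    def _simulate(self, rr, n_genes=2000, seed=0):
        rng = np.random.default_rng(seed)
        in_set = (rng.random(n_genes) < 0.2).astype(float)
        mu_rate = 10 ** rng.uniform(-8, -6, n_genes)
        lam = 5e6 * mu_rate * np.where(in_set == 1, rr, 1.0)
        counts = rng.poisson(lam)
        return counts, in_set, mu_rate

    def test_recovers_doubled_rate(self):
        counts, in_set, mu = self._simulate(2.0, seed=1)
        res = poisson_gene_set_enrichment(counts, in_set, mu)
        assert res.ci_low <= 2.0 <= res.ci_high
        assert res.rate_ratio == pytest.approx(2.0, rel=0.2)

    def test_null_coverage(self):
        covered = 0
        n_sim = 60
        for s in range(n_sim):
            counts, in_set, mu = self._simulate(1.0, n_genes=600, seed=100 + s)
            res = poisson_gene_set_enrichment(counts, in_set, mu)
            covered += res.ci_low <= 1.0 <= res.ci_high
        lo = stats.binom.ppf(0.005, n_sim, 0.95)
        assert covered >= lo

    def test_offset_mode_close_to_covariate_mode(self):
        counts, in_set, mu = self._simulate(1.5, seed=2)
        a = poisson_gene_set_enrichment(counts, in_set, mu)
        b = poisson_gene_set_enrichment(counts, in_set, mu, rate_as_offset=True)
        assert a.rate_ratio == pytest.approx(b.rate_ratio, rel=0.25)

    def test_zero_stratum_flagged_unbounded(self):
        counts = np.r_[np.zeros(10), np.random.default_rng(3).poisson(2, 50)]
        in_set = np.r_[np.ones(10), np.zeros(50)]
        mu = np.full(60, 1e-7)
        with pytest.warns(UserWarning, match="unbounded"):
            res = poisson_gene_set_enrichment(counts, in_set, mu)
        assert res.ci_low == 0.0

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            poisson_gene_set_enrichment([1, 2], [1, 0], [1e-7, 1e-7])

    def test_essential_set_bonferroni_constant(self):
        assert 0.05 / 6 == pytest.approx(0.0083, abs=5e-5)


class TestDownsampling:
    def _carriers(self, n=400, m=30, seed=4):
        rng = np.random.default_rng(seed)
        classes = np.zeros((n, m), dtype=np.int8)
        from biphase.caller import CH, HOM

        classes[rng.random((n, m)) < 0.01] = CH
        classes[rng.random((n, m)) < 0.004] = HOM
        return bp.CarrierTable(
            classes=classes,
            genes=np.array([f"G{j}" for j in range(m)]),
            sample_ids=np.array([f"S{i}" for i in range(n)]),
            hom_and_ch=np.zeros((n, m), bool),
        )

    def test_full_size_without_resampling_is_exact(self):
        t = self._carriers()
        curve = bp.downsample_curve(t, [t.classes.shape[0]], resample=False)
        from biphase.caller import CH

        expect = ((t.classes == CH).any(axis=0)).sum()
        row = curve[curve["carrier_class"] == "CH"].iloc[0]
        assert row["mean"] == expect == row["q025"] == row["q975"]

    def test_mean_curve_monotone(self):
        t = self._carriers()
        curve = bp.downsample_curve(t, [0, 50, 150, 400], n_boot=60, seed=5)
        for _, sub in curve.groupby("carrier_class"):
            means = sub.sort_values("size")["mean"].to_numpy()
            assert (np.diff(means) >= -1e-9).all()

    def test_band_covers_truth_expectation(self):
        t = self._carriers(seed=6)
        curve = bp.downsample_curve(t, [200], n_boot=150, seed=7)
        from biphase.caller import CH

        member = t.classes == CH
        # expected unique genes at size 200 with replacement
        p_gene = 1 - (1 - member.mean(axis=0)) ** 200
        expect = p_gene.sum()
        row = curve[curve["carrier_class"] == "CH"].iloc[0]
        assert row["q025"] - 1 <= expect <= row["q975"] + 1

    def test_oversized_request_rejected(self):
        t = self._carriers()
        with pytest.raises(ValueError):
            bp.downsample_curve(t, [10_000])


class TestPowerSolver:
    def test_or_one_gives_alpha_power(self):
        assert association_power(0.001, 100000, 0.02, 1.0, 0.05) == pytest.approx(
            0.05, abs=1e-9
        )

    def test_paper_case_grid(self):
        assert round(0.02 * 176_587) == 3532

    def test_monotone_in_inputs(self):
        base = bp.detectable_or_at_power(2e-4, 176_587, 0.02, 1.68e-7)
        assert base > 1
        assert bp.detectable_or_at_power(4e-4, 176_587, 0.02, 1.68e-7) < base
        assert bp.detectable_or_at_power(2e-4, 400_000, 0.02, 1.68e-7) < base
        assert bp.detectable_or_at_power(2e-4, 176_587, 0.05, 1.68e-7) < base

    def test_infeasible_returns_inf(self):
        assert bp.detectable_or_at_power(1e-7, 1000, 0.02, 1.68e-7) == np.inf

    def test_monte_carlo_rejection_near_target_power(self):
        f, n, prev, alpha = 5e-4, 50_000, 0.05, 1e-4
        or_ = bp.detectable_or_at_power(f, n, prev, alpha, power=0.8)
        rng = np.random.default_rng(8)
        table = _expected_table(f, n, prev, or_)
        p1 = table[0, 0] / table[0].sum()
        p0 = table[1, 0] / table[1].sum()
        crit = stats.chi2.ppf(1 - alpha, 1)
        n_rep = 1500
        rej = 0
        carriers = rng.binomial(n, f, n_rep)
        for c in rng.binomial(n, f, n_rep):
            a = rng.binomial(c, p1)
            b = rng.binomial(n - c, p0)
            obs = np.array([[a, c - a], [b, n - c - b]])
            chi2 = stats.chi2_contingency(obs, correction=False)[0]
            rej += chi2 >= crit
        assert rej / n_rep == pytest.approx(0.8, abs=0.05)
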