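"""Score test, saddlepoint tails, scans, conditioning and utilities."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import biphase as bp
from biphase.assoc import (
    AssocConfig,
    fit_null_model,
    saddlepoint_pvalue,
    score_test_components,
)
from biphase.caller import EncodedGenotypes


def _encodings(recessive, additive=None, genes=None):
    recessive = np.asarray(recessive)
    additive = recessive if additive is None else np.asarray(additive)
    n, m = recessive.shape
    genes = genes or [f"G{j}" for j in range(m)]
    return EncodedGenotypes(
        recessive=recessive,
        additive=additive,
        genes=np.array(genes),
        sample_ids=np.array([f"S{i}" for i in range(n)]),
    )


class TestScoreTest:
    def test_monomorphic_rejected(self):
        y = np.array([0, 1, 0, 1], float)
        with pytest.raises(ValueError, match="monomorphic"):
            bp.logistic_score_test(np.zeros(4), y)

    def test_agrees_with_chi_square_trend_on_2x2(self):
        # carriers: 8 cases / 2 controls; non-carriers: 92 / 898
        y = np.r_[np.ones(100), np.zeros(900)]
        g = np.zeros(1000)
        g[:8] = 2
        g[100:102] = 2
        t = bp.logistic_score_test(g, y)
        chi2, p_trend, *_ = stats.chi2_contingency(
            np.array([[8, 2], [92, 898]]), correction=False
        )
        # score strength T^2/V equals the Pearson/trend statistic on a 2x2
        assert t.score**2 / t.variance == pytest.approx(chi2, rel=0.10)

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(0)
        n = 500
        y = np.r_[np.ones(250), np.zeros(250)]
        g = (rng.random(n) < 0.1) * 2.0
        g[y == 1] += (rng.random(250) < 0.05) * 2.0
        g = np.clip(g, 0, 2)
        t = bp.logistic_score_test(g, y)
        obs = abs(t.score)
        n_perm = 20000
        count = 0
        for _ in range(n_perm):
            yp = rng.permutation(y)
            count += abs(g @ (yp - yp.mean())) >= obs - 1e-12
        p_perm = count / n_perm
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(t.p - p_perm) < 4 * se + 0.005

    def test_covariate_projection_reduces_variance(self):
        rng = np.random.default_rng(1)
        n = 2000
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(float)
        g = np.clip(x + rng.normal(size=n), 0, None)
        null_x = fit_null_model(y, x)
        null_0 = fit_null_model(y)
        _, v_x = score_test_components(g[:, None], null_x)
        _, v_0 = score_test_components(g[:, None], null_0)
        assert v_x[0] < v_0[0]


class TestSaddlepoint:
    def test_zero_score_is_one(self):
        y = np.r_[np.ones(50), np.zeros(50)]
        null = fit_null_model(y)
        g = np.zeros(100)
        g[:10] = 2
        g[50:60] = 2  # perfectly balanced: score 0
        p, ok = saddlepoint_pvalue(0.0, g, null)
        assert ok and p == pytest.approx(1.0, abs=1e-6)

    def test_balanced_common_genotype_agrees_with_normal(self):
        rng = np.random.default_rng(2)
        n = 4000
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        hits = 0
        for _ in range(10):
            g = rng.binomial(2, 0.3, n).astype(float)
            g[y == 1] += rng.random(n // 2) < 0.04
            g = np.clip(g, 0, 2)
            t = bp.logistic_score_test(g, y)
            if t.spa_used:
                hits += 1
                assert t.p == pytest.approx(t.p_normal, rel=0.05)
        assert hits > 0

    @pytest.mark.parametrize("carriers,case_carriers", [(10, 10), (20, 8), (15, 6)])
    def test_extreme_imbalance_matches_fisher_within_2x(
        self, carriers, case_carriers
    ):
        n = 20000
        y = np.zeros(n)
        y[:200] = 1  # 1% prevalence
        g = np.zeros(n)
        g[np.flatnonzero(y == 1)[:case_carriers]] = 2
        g[np.flatnonzero(y == 0)[: carriers - case_carriers]] = 2
        t = bp.logistic_score_test(g, y)
        fisher = stats.hypergeom.sf(case_carriers - 1, n, 200, carriers)
        assert fisher / t.p_normal > 10  # normal approximation badly off
        assert 0.5 <= fisher / t.p <= 2.0


class TestScans:
    def _null_setup(self, n=4000, m=30, seed=3):
        rng = np.random.default_rng(seed)
        rec = (rng.random((n, m)) < 0.004) * 2
        pheno = pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(n)],
                "trait_1": (rng.random(n) < 0.1).astype(float),
            }
        )
        return _encodings(rec.astype(np.int8)), pheno

    def test_carrier_floor_enforced(self):
        enc, pheno = self._null_setup()
        enc.recessive[:, 0] = 0
        enc.recessive[:4, 0] = 2  # 4 carriers: below the floor of 5
        res = bp.run_recessive_scan(enc, pheno, ["trait_1"])
        assert "G0" not in set(res["gene"])

    def test_missing_phenotype_excluded_from_floor(self):
        enc, pheno = self._null_setup()
        enc.recessive[:, 1] = 0
        enc.recessive[:6, 1] = 2
        pheno.loc[:1, "trait_1"] = np.nan  # 2 of the 6 carriers unmeasured
        res = bp.run_recessive_scan(enc, pheno, ["trait_1"])
        assert "G1" not in set(res["gene"])

    def test_additive_haplotype_floor(self):
        enc, pheno = self._null_setup()
        enc.additive = np.zeros_like(enc.additive)
        enc.additive[:9, 2] = 1  # 9 disrupted haplotypes < 10
        enc.additive[:10, 3] = 1
        res = bp.run_additive_scan(enc, pheno, ["trait_1"])
        genes = set(res["gene"])
        assert "G2" not in genes and "G3" in genes

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(4)
        n, m = 8000, 200
        rec = ((rng.random((n, m)) < 0.005) * 2).astype(np.int8)
        pheno = pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(n)],
                "trait_1": (rng.random(n) < 0.1).astype(float),
            }
        )
        res = bp.run_recessive_scan(_encodings(rec), pheno, ["trait_1"])
        ps = res["p_value"].to_numpy()
        k = (ps < 0.05).sum()
        lo, hi = stats.binom.ppf([0.005, 0.995], len(ps), 0.05)
        assert lo <= k <= hi

    def test_bonferroni_attr_attached(self):
        enc, pheno = self._null_setup()
        res = bp.run_recessive_scan(enc, pheno, ["trait_1"])
        expect = 0.05 / (res["gene"].nunique() * 1)
        assert res.attrs["bonferroni"] == pytest.approx(expect)

    def test_model_match_power_ordering(self):
        """The matched encoding yields the smaller p most of the time."""
        rng = np.random.default_rng(5)
        n = 4000
        add_wins = rec_wins = 0
        n_seeds = 30
        for _ in range(n_seeds):
            add = rng.choice([0, 1, 2], size=n, p=[0.9, 0.08, 0.02])
            rec = np.where(add == 2, 2, 0)
            # additive architecture
            risk = 1 / (1 + np.exp(-(-2.5 + 0.8 * add)))
            y_add = (rng.random(n) < risk).astype(float)
            # recessive architecture (hets at baseline risk)
            risk = 1 / (1 + np.exp(-(-2.5 + 1.6 * (add == 2))))
            y_rec = (rng.random(n) < risk).astype(float)
            pa = bp.logistic_score_test(add.astype(float), y_add).p
            pr = bp.logistic_score_test(rec.astype(float), y_add).p
            add_wins += pa <= pr
            pa = bp.logistic_score_test(add.astype(float), y_rec).p
            pr = bp.logistic_score_test(rec.astype(float), y_rec).p
            rec_wins += pr <= pa
        assert add_wins >= 0.8 * n_seeds
        assert rec_wins >= 0.8 * n_seeds


class TestConditioning:
    def test_self_conditioning_absorbs_signal(self):
        rng = np.random.default_rng(6)
        n = 3000
        g = (rng.random(n) < 0.05) * 2.0
        y = (rng.random(n) < 1 / (1 + np.exp(-(-2 + 1.5 * (g > 0))))).astype(float)
        t0 = bp.logistic_score_test(g, y)
        t1, used = bp.conditional_test(g, y, None, {"self": g})
        assert t0.p < 0.01
        assert t1.p > 0.9
        assert used == ("self",)

    def test_collinear_conditioning_column_dropped(self):
        rng = np.random.default_rng(7)
        n = 1000
        g = (rng.random(n) < 0.1) * 2.0
        y = (rng.random(n) < 0.3).astype(float)
        with pytest.warns(UserWarning, match="collinear"):
            _, used = bp.conditional_test(
                g, y, None, {"a": g, "b": 2 * g + 0.0}
            )
        assert used == ("a",)

    def test_ld_proxy_abrogation(self):
        """Signal driven by a correlated common variant vanishes on conditioning."""
        rng = np.random.default_rng(8)
        hits = 0
        n_seeds = 20
        for s in range(n_seeds):
            rng = np.random.default_rng(100 + s)
            n = 4000
            common = rng.binomial(2, 0.3, n).astype(float)
            # rare recessive genotype enriched on the common background (LD proxy)
            p_carrier = 0.002 + 0.012 * (common == 2)
            g = (rng.random(n) < p_carrier) * 2.0
            risk = 1 / (1 + np.exp(-(-2.3 + 0.8 * common)))
            y = (rng.random(n) < risk).astype(float)
            t0 = bp.logistic_score_test(g, y)
            t1, _ = bp.conditional_test(g, y, None, {"common": common})
            if t0.p > 0.05 or t1.p > 0.05:
                hits += t1.p > 0.05
            else:
                hits += 0
        assert hits >= 0.8 * n_seeds

    def test_independent_column_is_stable(self):
        rng = np.random.default_rng(9)
        n = 5000
        g = (rng.random(n) < 0.02) * 2.0
        y = (rng.random(n) < 1 / (1 + np.exp(-(-2.2 + 1.2 * (g > 0))))).astype(float)
        t0 = bp.logistic_score_test(g, y)
        t1, _ = bp.conditional_test(g, y, None, {"noise": rng.normal(size=n)})
        assert abs(np.log10(t1.p) - np.log10(t0.p)) < 1.0


class TestIterativeConditionalScan:
    def test_no_signal_empty(self):
        rng = np.random.default_rng(10)
        n = 2000
        D = rng.binomial(2, 0.3, (n, 5)).astype(float)
        y = (rng.random(n) < 0.2).astype(float)
        assert bp.iterative_conditional_scan(D, np.arange(5), y) == []

    def test_single_planted_signal_recovered(self):
        found = 0
        n_seeds = 10
        for s in range(n_seeds):
            rng = np.random.default_rng(200 + s)
            n = 4000
            D = rng.binomial(2, 0.3, (n, 8)).astype(float)
            risk = 1 / (1 + np.exp(-(-1.5 + 0.9 * D[:, 3])))
            y = (rng.random(n) < risk).astype(float)
            sel = bp.iterative_conditional_scan(D, np.arange(8), y)
            found += sel[:1] == [3]
        assert found >= 9

    def test_two_independent_signals_recovered(self):
        rng = np.random.default_rng(11)
        n = 6000
        D = rng.binomial(2, 0.3, (n, 6)).astype(float)
        risk = 1 / (1 + np.exp(-(-2.0 + 0.8 * D[:, 1] + 0.8 * D[:, 4])))
        y = (rng.random(n) < risk).astype(float)
        sel = bp.iterative_conditional_scan(D, np.arange(6), y)
        assert {1, 4} <= set(sel)

    def test_empty_region(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        assert bp.iterative_conditional_scan(np.empty((20, 0)), np.array([]), y) == []


class TestAnalyticUtilities:
    def test_bonferroni_paper_grids(self):
        assert bp.bonferroni_threshold(0.05, 952, 311) == pytest.approx(
            1.69e-7, rel=5e-3
        )
        assert bp.bonferroni_threshold(0.05, 16363, 311) == pytest.approx(
            9.8e-9, rel=5e-3
        )
        assert bp.bonferroni_threshold(0.05, 1, 1) == 0.05
        with pytest.raises(ValueError):
            bp.bonferroni_threshold(0.05, 0, 10)

    def test_effective_sample_size(self):
        assert bp.effective_sample_size(1000, 1000) == 2000
        assert bp.effective_sample_size(2500, 2500) == 5000
        assert bp.effective_sample_size(100, 1e8) == pytest.approx(400, rel=1e-4)

    def test_one_sided_sign_test(self):
        assert bp.one_sided_sign_test(12, 12) == pytest.approx(2.44e-4, rel=1e-2)
        assert bp.one_sided_sign_test(11, 12) == pytest.approx(3.17e-3, rel=1e-2)
        assert bp.one_sided_sign_test(0, 5) == 1.0

    def test_prs_maf_filter(self):
        assert bp.prs_maf_filter(1e6, 1e6) == 0.01
        assert bp.prs_maf_filter(100, 5000, floor=0.0) == pytest.approx(0.02)
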