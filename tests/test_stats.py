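import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from foragedecomp.stats import (classify_effect, count_module_expression,
                                fisher_exact, fit_genotype_glm,
                                fit_imprinting_glm, keystone_tests,
                                link_modules_to_keystones, profile_fisher,
                                tally_significance_dependence,
                                variance_filter)


def fisher_2x2_oracle(t):
    """Two-sided Fisher p by explicit hypergeometric enumeration."""
    t = np.asarray(t)
    a, r1, c1, n = t[0, 0], t[0].sum(), t[:, 0].sum(), t.sum()
    support = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = {k: hypergeom.pmf(k, n, c1, r1) for k in support}
    return float(sum(p for p in pmf.values() if p <= pmf[a] * (1 + 1e-7)))


class TestModuleCounts:
    def _assignments(self):
        return pd.DataFrame({
            "mouse": ["m1"] * 3 + ["m2"] * 2,
            "module": [7, 7, 7, 7, 3],
            "phase": ["foraging"] * 5,
        })

    def _metadata(self):
        return pd.DataFrame(
            {"genotype": ["wildtype"] * 3, "cross": ["maternal"] * 3,
             "sex": ["male"] * 3}, index=["m1", "m2", "m3"])

    def test_counts_tallied_per_mouse(self):
        mcm = count_module_expression(self._assignments(), self._metadata(),
                                      phase="foraging")
        assert mcm.counts.loc["m1", 7] == 3
        assert mcm.counts.loc["m2", 3] == 1

    def test_mouse_without_excursions_gets_zero_row(self):
        mcm = count_module_expression(self._assignments(), self._metadata(),
                                      phase="foraging")
        assert (mcm.counts.loc["m3"] == 0).all()

    def test_total_conserved(self):
        a = self._assignments()
        mcm = count_module_expression(a, self._metadata(), phase="foraging")
        assert mcm.counts.to_numpy().sum() == len(a)

    def test_unknown_mouse_rejected(self):
        a = self._assignments()
        a.loc[0, "mouse"] = "ghost"
        with pytest.raises(ValueError, match="unknown"):
            count_module_expression(a, self._metadata(), phase="foraging")


class TestVarianceFilter:
    def test_constant_modules_dropped(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.poisson(4, size=(20, 10)),
                          columns=list(range(10)))
        df[[2, 5, 9]] = 3  # three constant columns
        filtered, retained = variance_filter(df, min_variance=0.1)
        assert len(retained) == 7
        assert not {2, 5, 9} & set(retained)

    def test_zero_threshold_keeps_all(self):
        df = pd.DataFrame(np.ones((5, 4)))
        filtered, retained = variance_filter(df, min_variance=0.0)
        assert len(retained) == 4

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            variance_filter(pd.DataFrame(np.ones((3, 2))), min_variance=-1)


class TestGenotypeGlm:
    def test_deviance_closed_form(self):
        """Two-group Poisson deviance matches 2*sum(y*log(y/yhat))."""
        y = np.array([2, 4, 6, 3, 5, 10, 12, 8, 9, 11], dtype=float)
        g = ["wildtype"] * 5 + ["Th het"] * 5
        res = fit_genotype_glm(y, g)
        mu = np.where(np.array(g) == "wildtype", y[:5].mean(), y[5:].mean())
        dev = 2 * np.sum(y * np.log(y / mu) - (y - mu))
        null_mu = y.mean()
        null_dev = 2 * np.sum(y * np.log(y / null_mu) - (y - null_mu))
        from scipy.stats import chi2
        expected_p = chi2.sf(null_dev - dev, 1)
        assert res.term_p["genotype"] == pytest.approx(expected_p, rel=1e-6)

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(0)
        detected = 0
        for _ in range(20):
            y = np.concatenate([rng.poisson(2, 30), rng.poisson(8, 30)])
            res = fit_genotype_glm(y, ["a"] * 30 + ["b"] * 30)
            detected += res.term_p["genotype"] < 1e-6
        assert detected == 20

    def test_identical_counts_give_p_one(self):
        res = fit_genotype_glm(np.full(20, 5.0), ["a"] * 10 + ["b"] * 10)
        assert res.term_p["genotype"] == pytest.approx(1.0)

    def test_all_zero_counts_flagged(self):
        res = fit_genotype_glm(np.zeros(20), ["a"] * 10 + ["b"] * 10)
        assert res.term_p["genotype"] == 1.0
        assert any("degenerate" in f for f in res.flags)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            fit_genotype_glm(np.ones(5), ["a"] * 5)

    def test_gof_passes_for_poisson_data(self):
        rng = np.random.default_rng(1)
        passes = 0
        for _ in range(20):
            y = np.concatenate([rng.poisson(5, 30), rng.poisson(7, 30)])
            passes += fit_genotype_glm(y, ["a"] * 30 + ["b"] * 30).gof_pass
        assert passes >= 17  # nominal 5% GOF failure rate


class TestImprintingGlm:
    def _cohort(self, rate_fn, n=25, seed=0):
        rng = np.random.default_rng(seed)
        y, cr, gt = [], [], []
        for c in ("maternal", "paternal"):
            for g in ("wildtype", "Th het", "Ddc het", "ThDdc het"):
                y.append(rng.poisson(rate_fn(c, g), n))
                cr += [c] * n
                gt += [g] * n
        return np.concatenate(y), cr, gt

    def test_planted_interaction_detected(self):
        y, cr, gt = self._cohort(
            lambda c, g: 8.0 if (c, g) == ("maternal", "Th het") else 4.0)
        res = fit_imprinting_glm(y, cr, gt)
        assert res.term_p["cross:genotype"] < 0.05

    def test_pure_cross_effect_lands_on_cross_term(self):
        y, cr, gt = self._cohort(lambda c, g: 8.0 if c == "maternal" else 4.0)
        res = fit_imprinting_glm(y, cr, gt)
        assert res.term_p["cross"] < 1e-6

    def test_empty_cell_flags_interaction_inestimable(self):
        y = np.concatenate([np.random.default_rng(0).poisson(4, 25)] * 3)
        cr = ["maternal"] * 25 + ["paternal"] * 50
        gt = ["wildtype"] * 50 + ["Th het"] * 25  # maternal x Th het empty
        res = fit_imprinting_glm(y, cr, gt)
        assert any("confounded" in f for f in res.flags)
        assert np.isnan(res.term_p["cross:genotype"])

    @pytest.mark.parametrize("p_cross,p_geno,p_int,expected", [
        (0.01, 0.5, 0.5, {"generalized parental"}),
        (0.5, 0.01, 0.5, {"genetic"}),
        (0.5, 0.5, 0.01, {"putative imprinting"}),
        (0.01, 0.01, 0.5, {"generalized parental", "genetic"}),
        (0.01, 0.01, 0.01, {"putative imprinting"}),
        (0.5, 0.5, 0.5, set()),
        (0.5, 0.5, float("nan"), set()),
    ])
    def test_effect_classification_decision_table(self, p_cross, p_geno,
                                                  p_int, expected):
        assert classify_effect(p_cross, p_geno, p_int) == frozenset(expected)


class TestFisherExact:
    def test_published_module_tally(self):
        """Males (22 maternal, 15 paternal) vs females (0, 14)."""
        res = fisher_exact([[22, 15], [0, 14]])
        assert res.p < 0.0001
        assert res.p == pytest.approx(fisher_2x2_oracle([[22, 15], [0, 14]]),
                                      abs=1e-6)

    def test_published_keystone_tally(self):
        res = tally_significance_dependence([[7, 2], [0, 14]])
        assert res.p == pytest.approx(1.47e-4, abs=2e-6)

    def test_independent_table_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]]).p == pytest.approx(1.0)

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            t = rng.integers(0, 25, size=(2, 2)) + np.eye(2, dtype=int)
            assert fisher_exact(t).p == pytest.approx(
                fisher_2x2_oracle(t), abs=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [3, 4]])

    def test_monte_carlo_close_to_exact_on_small_rxc(self):
        t = np.array([[8, 2, 1], [1, 6, 2], [2, 1, 9]])
        from scipy.stats import chi2_contingency
        mc = fisher_exact(t, mc_iterations=20000, seed=0)
        assert mc.method == "monte_carlo"
        # strong dependence: both routes highly significant
        assert mc.p < 0.005
        assert chi2_contingency(t)[1] < 0.005

    def test_monte_carlo_reproducible(self):
        t = [[5, 1, 2], [2, 6, 1], [1, 2, 7]]
        a = fisher_exact(t, mc_iterations=2000, seed=3)
        b = fisher_exact(t, mc_iterations=2000, seed=3)
        assert a.p == b.p


class TestProfileFisher:
    def test_identical_profiles_not_significant(self):
        t = np.tile([[20, 20]], (10, 1))
        assert profile_fisher(t, mc_iterations=2000, seed=0).p > 0.5

    def test_enriched_module_detected(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(40, size=(50, 2))
        base[7, 0] *= 10  # one module 10x enriched in the het column
        assert profile_fisher(base, mc_iterations=5000, seed=1).p < 0.01

    def test_scaling_both_columns_preserves_conclusion(self):
        """On clearly dependent or clearly proportional profiles, doubling
        every count leaves the reject/accept conclusion unchanged."""
        rng = np.random.default_rng(1)
        agree, total = 0, 0
        for i in range(10):
            enriched = rng.poisson(40, size=(15, 2)) + 1
            enriched[i, 0] *= 5
            proportional = np.tile(rng.poisson(40, size=(15, 1)) + 1, (1, 2))
            for t in (enriched, proportional):
                p1 = profile_fisher(t, mc_iterations=2000, seed=i).p
                p2 = profile_fisher(t * 2, mc_iterations=2000, seed=i).p
                agree += (p1 < 0.05) == (p2 < 0.05)
                total += 1
        assert agree / total >= 0.95


class TestKeystoneTests:
    def _data(self, effect=0.0, seed=0, n=12):
        rng = np.random.default_rng(seed)
        genos = ["wildtype", "Th het", "Ddc het", "ThDdc het"]
        rows, g = [], []
        for geno in genos:
            shift = effect if geno != "wildtype" else 0.0
            rows += list(rng.normal(shift, 1.0, n))
            g += [geno] * n
        df = pd.DataFrame({"feat": rows})
        return df, g, ["maternal"] * len(g), ["male"] * len(g)

    def test_bonferroni_triples_raw_p(self):
        df, g, cr, sx = self._data()
        out = keystone_tests(df, g, cr, sx)
        out = out[out["feature"] == "feat"]
        np.testing.assert_allclose(out["contrast_p_bonferroni"],
                                   np.minimum(1.0, out["contrast_p"] * 3))

    def test_large_shift_detected(self):
        df, g, cr, sx = self._data(effect=3.0)
        out = keystone_tests(df, g, cr, sx)
        assert (out["contrast_p_bonferroni"] < 0.01).all()

    def test_familywise_error_controlled(self):
        rng = np.random.default_rng(3)
        fw = 0
        n_sim = 200
        for _ in range(n_sim):
            df, g, cr, sx = self._data(effect=0.0, seed=rng.integers(2**31))
            out = keystone_tests(df, g, cr, sx)
            fw += (out["contrast_p_bonferroni"] < 0.05).any()
        assert fw / n_sim <= 0.07  # Bonferroni keeps FWER <= 0.05

    def test_singleton_group_flagged(self):
        df = pd.DataFrame({"feat": [1.0, 2.0, 3.0]})
        out = keystone_tests(df, ["wildtype", "wildtype", "Th het"],
                             ["maternal"] * 3, ["male"] * 3)
        assert (out["flag"] != "").any()


class TestModuleKeystoneLinks:
    def test_perfect_linear_relation(self):
        counts = pd.DataFrame({"mod1": np.arange(10)}, index=range(10))
        keys = pd.DataFrame({"tfc": 2.0 * np.arange(10)}, index=range(10))
        out = link_modules_to_keystones(counts, keys)
        row = out.iloc[0]
        assert row["pearson_r"] == pytest.approx(1.0)
        assert row["slope_sign"] == 1
        assert row["p"] < 1e-9

    def test_negative_association_sign(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(5, 30).astype(float)
        counts = pd.DataFrame({"mod1": x}, index=range(30))
        keys = pd.DataFrame({"f": -x + rng.normal(0, 0.1, 30)},
                            index=range(30))
        assert link_modules_to_keystones(counts, keys)["slope_sign"].iloc[0] == -1

    def test_null_association_calibrated(self):
        rng = np.random.default_rng(1)
        hits, total = 0, 0
        for _ in range(50):
            counts = pd.DataFrame({"m": rng.poisson(5, 30)}, index=range(30))
            keys = pd.DataFrame({"f": rng.normal(size=30)}, index=range(30))
            out = link_modules_to_keystones(counts, keys)
            hits += int(out["significant"].iloc[0])
            total += 1
        assert hits / total <= 0.15

    def test_zero_variance_pair_skipped(self):
        counts = pd.DataFrame({"m": [3, 3, 3, 3]}, index=range(4))
        keys = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0]}, index=range(4))
        assert len(link_modules_to_keystones(counts, keys)) == 0
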