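import numpy as np
import pandas as pd
import pytest
from scipy.stats import f_oneway, ttest_ind

from allohybrid.phenostats import (
    one_way_anova,
    phenotype_report,
    quasibinomial_glm,
    tukey_hsd_letters,
    tukey_rejections,
)
from allohybrid.simulate import SimulationConfig, simulate_phenotypes
from tests.oracles import anova_ss_naive


class TestOneWayAnova:
    def test_identical_groups_give_zero_f(self):
        res = one_way_anova(np.array([1, 2, 3, 1, 2, 3.0]),
                            np.array(["a"] * 3 + ["b"] * 3))
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(0)
        v = np.concatenate([rng.normal(0, 1, 8), rng.normal(0.7, 1.3, 11)])
        g = np.array(["x"] * 8 + ["y"] * 11)
        t = ttest_ind(v[:8], v[8:]).statistic
        assert one_way_anova(v, g).F == pytest.approx(t ** 2, abs=1e-10)

    def test_matches_naive_ss_oracle_and_scipy(self):
        rng = np.random.default_rng(1)
        v = rng.normal(0, 2, 40)
        g = rng.choice(["a", "b", "c", "d"], 40)
        res = one_way_anova(v, g)
        F_ref, df_b, df_w = anova_ss_naive(v, g)
        assert res.F == pytest.approx(F_ref, abs=1e-10)
        assert (res.df_between, res.df_within) == (df_b, df_w)
        sp = f_oneway(*[v[g == lab] for lab in np.unique(g)])
        assert res.F == pytest.approx(sp.statistic, rel=1e-12)
        assert res.pvalue == pytest.approx(sp.pvalue, rel=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova(np.array([1.0, 2.0]), np.array(["a", "a"]))
        with pytest.raises(ValueError):
            one_way_anova(np.array([5.0, 5.0, 5.0, 5.0]),
                          np.array(["a", "a", "b", "b"]))


class TestTukeyLetters:
    def test_well_separated_groups_all_distinct(self):
        rng = np.random.default_rng(2)
        v = np.concatenate([rng.normal(mu, 1, 10) for mu in (0, 40, 80)])
        g = np.repeat(["lo", "mid", "hi"], 10)
        res = tukey_hsd_letters(v, g)
        assert sorted(res.letters.values()) == ["a", "b", "c"]
        assert res.letters["hi"] == "a"  # highest mean gets the first letter

    def test_letters_consistent_with_pairwise_matrix(self):
        # shared letter <=> non-significant pair, on many random datasets
        rng = np.random.default_rng(3)
        for _ in range(50):
            k = rng.integers(3, 7)
            v = np.concatenate([rng.normal(rng.uniform(0, 3), 1, 8)
                                for _ in range(k)])
            g = np.repeat([f"grp{i}" for i in range(k)], 8)
            res = tukey_hsd_letters(v, g)
            for row in res.pairwise.itertuples():
                shared = set(res.letters[row.group1]) & set(res.letters[row.group2])
                assert bool(shared) == (not row.significant)

    def test_letter_assignment_deterministic(self):
        rng = np.random.default_rng(4)
        v = rng.normal(0, 1, 30)
        g = np.repeat(["a", "b", "c"], 10)
        r1 = tukey_hsd_letters(v, g)
        r2 = tukey_hsd_letters(v.copy(), g.copy())
        assert r1.letters == r2.letters

    def test_rejections_agree_with_letter_significance(self):
        rng = np.random.default_rng(5)
        v = np.concatenate([rng.normal(mu, 1, 6) for mu in (0, 0.5, 3.0)])
        g = np.repeat(["a", "b", "c"], 6)
        rej = tukey_rejections(v, g, alpha=0.05)
        res = tukey_hsd_letters(v, g, alpha=0.05)
        assert list(rej) == list(res.pairwise["significant"])


class TestQuasibinomialGlm:
    def _obs(self, num, den, hyb, tet, lane=None):
        d = {"numerator": num, "denominator": den,
             "is_hybrid": np.asarray(hyb, dtype=bool),
             "is_tetraploid": np.asarray(tet, dtype=bool)}
        if lane is not None:
            d["lane"] = lane
        return pd.DataFrame(d)

    def test_matches_frozen_car_anova_oracle(self):
        # fixture regenerated from seed 7; reference values computed
        # independently with R glm(quasibinomial) + car::Anova(type=2, F)
        rng = np.random.default_rng(7)
        n = 28
        hyb = np.tile([0, 0, 1, 1], 7)
        tet = np.tile([0, 1, 0, 1], 7)
        lane = np.tile(["a", "b", "c", "a", "b", "c", "a"], 4)
        den = rng.integers(400, 800, n)
        logit = -0.5 + 0.8 * hyb - 0.4 * tet + 0.9 * hyb * tet + (lane == "b") * 0.3
        num = rng.binomial(den, 1 / (1 + np.exp(-logit)))
        fit = quasibinomial_glm(
            self._obs(num, den, hyb, tet, lane),
            ["is_hybrid", "is_tetraploid", "lane", "is_hybrid:is_tetraploid"])
        assert fit.dispersion == pytest.approx(0.9192266424, abs=1e-6)
        expected_F = {"is_hybrid": 1537.82063, "is_tetraploid": 9.43418,
                      "lane": 41.78558, "is_hybrid:is_tetraploid": 220.36493}
        for row in fit.anova_table.itertuples():
            assert row.F == pytest.approx(expected_F[row.term], rel=1e-5)
        expected_coef = [-0.4928410415, 0.7426137261, -0.3691619331,
                         0.2948617494, -0.0511790563, 0.9160195139]
        expected_se = [0.0335065107, 0.0418794292, 0.0441077128,
                       0.0379296176, 0.0367904060, 0.0619786451]
        assert np.allclose(fit.coefficients.to_numpy(), expected_coef, atol=1e-8)
        assert np.allclose(fit.std_errors.to_numpy(), expected_se, atol=1e-8)

    def test_quasi_scaling_only_affects_uncertainty(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        obs = self._obs(rng.integers(10, 90, 20), np.full(20, 100),
                        np.tile([0, 1], 10), np.repeat([0, 1], 10))
        fit = quasibinomial_glm(obs, ["is_hybrid", "is_tetraploid"])
        X = np.column_stack([np.ones(20), obs["is_hybrid"], obs["is_tetraploid"]])
        plain = sm.GLM(np.column_stack([obs["numerator"],
                                        obs["denominator"] - obs["numerator"]]),
                       X, family=sm.families.Binomial()).fit()
        assert np.allclose(fit.coefficients.to_numpy(), plain.params, atol=1e-10)
        ratio = fit.std_errors.to_numpy() / plain.bse
        assert np.allclose(ratio, np.sqrt(fit.dispersion), atol=1e-10)

    def test_dispersion_near_one_for_plain_binomial_data(self):
        # chi^2_67 / 67 lies in (0.7, 1.4) with probability ~0.95; demand
        # at least 0.90 over 200 replicates (3 MC standard errors of slack)
        phis = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            den = np.full(70, 600)
            hyb = r.integers(0, 2, 70)
            tet = r.integers(0, 2, 70)
            num = r.binomial(den, 1 / (1 + np.exp(-(0.3 * hyb - 0.2 * tet))))
            fit = quasibinomial_glm(self._obs(num, den, hyb, tet),
                                    ["is_hybrid", "is_tetraploid"])
            phis.append(fit.dispersion)
        inside = np.mean([(0.7 < p < 1.4) for p in phis])
        assert inside >= 0.9
        assert 0.9 < np.median(phis) < 1.1

    def test_invalid_observations_rejected(self):
        with pytest.raises(ValueError):
            quasibinomial_glm(self._obs([5], [0], [0], [0]), ["is_hybrid"])
        with pytest.raises(ValueError):
            quasibinomial_glm(self._obs([7], [5], [0], [0]), ["is_hybrid"])


class TestPhenotypeReport:
    def test_full_report_on_generator_defaults(self):
        cfg = SimulationConfig()
        pheno = simulate_phenotypes(cfg, np.random.default_rng(12))
        report = phenotype_report(pheno)
        assert set(report["anova"]) == {"stem_length", "flowering_time",
                                        "pollen_per_flower"}
        for res in report["anova"].values():
            assert len(res.letters) == 7
        viab = report["glm"]["pollen_viability"]
        assert viab.dispersion > 1.0  # beta-binomial overdispersion visible
        # fitted group viability close to the configured map
        agg = pheno.groupby("group")[["pollen_viable", "pollen_examined"]].sum()
        for g, p_true in cfg.pheno_viability_by_group.items():
            p_hat = agg.loc[g, "pollen_viable"] / agg.loc[g, "pollen_examined"]
            assert abs(p_hat - p_true) < 0.05
        assert "alloh_vs_f2_viability" in report["glm"]
        assert report["selfed_seed_set"]["Cg2"] == 0.0
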