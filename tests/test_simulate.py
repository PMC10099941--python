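import numpy as np
import pandas as pd
import pytest

from allohybrid.simulate import (
    HYBRID_MODES,
    SimulationConfig,
    assign_gene_truth,
    simulate_experiment,
    simulate_phenotypes,
)


class TestDesignShapes:
    def test_full_factorial_sample_and_phenotype_counts(self, small_experiment):
        # 7 groups x 6 lines x 2 tissues sequenced; 7 x 6 x 6 phenotyped
        assert len(small_experiment.samples) == 84
        assert len(small_experiment.phenotypes) == 252
        per_tissue = small_experiment.samples.groupby("tissue").size()
        assert (per_tissue == 42).all()

    def test_lane_assignment_is_balanced_block(self, small_experiment):
        cells = small_experiment.samples.groupby(
            ["group", "tissue", "lane"], observed=True).size()
        assert (cells == 2).all()

    def test_library_sizes_exactly_conserved(self, small_experiment):
        # multinomial allocation: column totals equal the drawn library sizes,
        # which concentrate around the configured log-normal
        totals = small_experiment.counts.values.sum(axis=0)
        assert (totals > 0).all()
        assert np.abs(np.log(totals.mean()) - np.log(1e6)) < 0.2


class TestDeterminism:
    def test_same_seed_bit_identical(self, small_config):
        a = simulate_experiment(small_config)
        b = simulate_experiment(small_config)
        pd.testing.assert_frame_equal(a.counts.values, b.counts.values)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_different_seed_differs(self, small_config, small_experiment):
        other = simulate_experiment(small_config.with_(rng_seed=8))
        assert not other.counts.values.equals(small_experiment.counts.values)


class TestGeneTruth:
    def test_expected_means_respect_hybrid_modes(self, small_experiment):
        t = small_experiment.truth
        mid = (t["log2_mean_Co2"] + t["log2_mean_Cg2"]) / 2
        add = t["hybrid_mode"].isin(["additive", "conserved"])
        assert (t.loc[add, "log2_mean_F2"] == mid[add]).all()
        eld1 = t["hybrid_mode"] == "ELD_P1"
        assert (t.loc[eld1, "log2_mean_F2"] == t.loc[eld1, "log2_mean_Co2"]).all()
        up = t["hybrid_mode"] == "TRE_up"
        hi = t[["log2_mean_Co2", "log2_mean_Cg2"]].max(axis=1)
        assert np.allclose(t.loc[up, "log2_mean_F2"], hi[up] + 1.5)

    def test_wgd_null_makes_tetraploids_match_diploids(self, small_experiment):
        t = small_experiment.truth
        assert (t["log2_mean_Co4"] == t["log2_mean_Co2"]).all()
        assert (t["log2_mean_Cg4"] == t["log2_mean_Cg2"]).all()
        assert (t["log2_mean_Allo-d"] == t["log2_mean_F2"]).all()
        assert (t["log2_mean_Allo-h"] == t["log2_mean_F2"]).all()

    def test_eld_requires_parental_divergence(self, small_experiment):
        t = small_experiment.truth
        eld = t["hybrid_mode"].isin(["ELD_P1", "ELD_P2", "additive"])
        assert (t.loc[eld, "parental_log2fc"].abs() >= 1.0).all()

    def test_realized_mode_fractions_concentrate(self):
        cfg = SimulationConfig(n_genes=20000, rng_seed=3)
        truth = assign_gene_truth(cfg, np.random.default_rng(3))
        n = cfg.n_genes
        for mode in ("ELD_P1", "ELD_P2", "additive"):
            p = cfg.hybrid_mode_fractions[mode]
            realized = (truth["hybrid_mode"] == mode).mean()
            assert abs(realized - p) <= 3 * np.sqrt(p * (1 - p) / n)
        ped = (truth["parental_log2fc"] != 0).mean()
        assert abs(ped - cfg.pi_ped) <= 3 * np.sqrt(0.25 * 0.75 / n)

    def test_single_mode_fractions(self):
        cfg = SimulationConfig(
            n_genes=500, rng_seed=1, pi_ped=1.0,
            hybrid_mode_fractions={m: (1.0 if m == "additive" else 0.0)
                                   for m in HYBRID_MODES})
        truth = assign_gene_truth(cfg, np.random.default_rng(1))
        assert (truth["hybrid_mode"] == "additive").all()
        mid = (truth["log2_mean_Co2"] + truth["log2_mean_Cg2"]) / 2
        assert (truth["log2_mean_F2"] == mid).all()


class TestConfigValidation:
    def test_bad_simplex_rejected(self):
        with pytest.raises(ValueError, match="must sum to 1"):
            SimulationConfig(hybrid_mode_fractions={"additive": 0.5, "conserved": 0.6})

    def test_degenerate_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=0)
        with pytest.raises(ValueError):
            SimulationConfig(groups=())

    def test_proportion_out_of_range_rejected(self):
        bad = dict(SimulationConfig().pheno_viability_by_group)
        bad["F2"] = 1.3
        with pytest.raises(ValueError):
            SimulationConfig(pheno_viability_by_group=bad)


class TestPhenotypes:
    def test_counts_bounded_and_consistent(self, small_experiment):
        ph = small_experiment.phenotypes
        assert (ph["pollen_viable"] <= ph["pollen_examined"]).all()
        assert (ph["seeds_normal"] <= ph["seeds_total"]).all()
        assert (ph["pollen_examined"] >= 600).all()  # >= 300 grains x 2 flowers

    def test_perfect_viability_is_deterministic(self):
        cfg = SimulationConfig(
            pheno_viability_by_group={g: 1.0 for g in SimulationConfig().groups})
        ph = simulate_phenotypes(cfg, np.random.default_rng(0))
        assert (ph["pollen_viable"] == ph["pollen_examined"]).all()

    def test_group_proportions_recovered(self, small_experiment):
        ph = small_experiment.phenotypes
        cfg_map = SimulationConfig().pheno_viability_by_group
        agg = ph.groupby("group")[["pollen_viable", "pollen_examined"]].sum()
        for g, row in agg.iterrows():
            p_hat = row["pollen_viable"] / row["pollen_examined"]
            # beta-binomial SE with rho = 0.02 across 36 individuals x 2 flowers
            p = cfg_map[g]
            se = np.sqrt(p * (1 - p) * 0.02 / 72) + np.sqrt(p * (1 - p) / row["pollen_examined"])
            assert abs(p_hat - p) < 4 * se
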