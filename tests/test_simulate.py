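"""Synthetic cohort generator: invariants, planted structure, determinism."""

import numpy as np
import pandas as pd
import pytest

from methdriver import preprocess, stats
from methdriver.datatypes import GROUP_COPD, GROUP_CTRL
from methdriver.simulate import SimConfig, shuffle_samples, simulate


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("n_ctrl", -1),
        ("probes_per_gene", 0),
        ("frac_model2", 1.5),
        ("frac_positive_cis", -0.1),
        ("noise_sd", -2.0),
    ])
    def test_invalid_field_named_in_error(self, field, value):
        cfg = SimConfig(**{field: value})
        with pytest.raises(ValueError, match=field):
            cfg.validate()

    def test_downstream_budget_checked(self):
        cfg = SimConfig(n_genes=50, n_key_regulators=2,
                        downstream_counts=[30, 30])
        with pytest.raises(ValueError, match="downstream_counts"):
            cfg.validate()


class TestGeneratedData:
    def test_group_sizes_are_52_and_100(self, default_cohort):
        meth, expr = default_cohort[0], default_cohort[1]
        for m in (meth, expr):
            counts = m.groups.value_counts()
            assert counts[GROUP_CTRL] == 52
            assert counts[GROUP_COPD] == 100

    def test_beta_in_unit_interval_and_expression_finite(self, default_cohort):
        meth, expr = default_cohort[0], default_cohort[1]
        b = meth.values.to_numpy()
        assert b.min() >= 0.0 and b.max() <= 1.0
        assert np.isfinite(expr.values.to_numpy()).all()

    def test_trio_models_partition(self, default_cohort):
        truth = default_cohort[6]
        assert set(truth.trios["model"]) <= {"I", "II", "III"}
        assert not truth.trios.duplicated(
            ["probe_id", "cis_gene", "trans_gene"]).any()

    def test_trios_reference_generated_features(self, default_cohort):
        meth, expr, truth = (default_cohort[0], default_cohort[1],
                             default_cohort[6])
        t = truth.trios
        assert t["probe_id"].isin(meth.feature_ids).all()
        assert t["cis_gene"].isin(expr.feature_ids).all()
        assert t["trans_gene"].isin(expr.feature_ids).all()

    def test_seed_reproducibility(self):
        a = simulate(SimConfig(seed=9, n_genes=60, n_ctrl=15, n_copd=20,
                               n_background_regulators=10,
                               downstream_counts=[8, 8], n_key_regulators=2))
        b = simulate(SimConfig(seed=9, n_genes=60, n_ctrl=15, n_copd=20,
                               n_background_regulators=10,
                               downstream_counts=[8, 8], n_key_regulators=2))
        pd.testing.assert_frame_equal(a[0].values, b[0].values)
        pd.testing.assert_frame_equal(a[1].values, b[1].values)
        pd.testing.assert_frame_equal(a[6].trios, b[6].trios)


class TestPlantedSignal:
    def test_noiseless_chain_gives_perfect_rank_correlation(self):
        """With all noise removed, regulator methylation and downstream
        expression are perfectly monotonically related."""
        cfg = SimConfig(seed=2, n_ctrl=20, n_copd=30, n_genes=40,
                        n_key_regulators=1, downstream_counts=[10],
                        n_background_regulators=0, frac_model2=0.0,
                        n_confounded=0, noise_sd=0.0, frac_cis=0.0,
                        covariate_effects=(0.0, 0.0, 0.0),
                        trait_missing_frac=0.0)
        meth, expr, probes, genes, cov, phen, truth = simulate(cfg)
        trios = truth.trios[truth.trios["model"] == "I"]
        assert len(trios) > 0
        for rec in trios.itertuples():
            r = stats.spearman(meth.values.loc[rec.probe_id],
                               expr.values.loc[rec.trans_gene])
            assert abs(r.rho) == pytest.approx(1.0)

    def test_null_shift_leaves_island_means_equal(self):
        cfg = SimConfig(seed=4, hypermeth_shift=0.0, n_genes=300,
                        n_key_regulators=0, downstream_counts=[],
                        n_background_regulators=0, frac_model2=0.0,
                        n_confounded=0)
        meth, expr, probes, genes, cov, phen, truth = simulate(cfg)
        island_probes = probes.loc[probes["cpg_island"], "probe_id"]
        sub = meth.values.loc[island_probes]
        copd = meth.groups == GROUP_COPD
        diff = sub.loc[:, copd.values].mean().mean() - sub.loc[:, ~copd.values].mean().mean()
        assert abs(diff) < 0.02  # Monte-Carlo error only

    def test_hypermethylation_shift_raises_island_beta_in_copd(self,
                                                               default_cohort):
        meth, probes = default_cohort[0], default_cohort[2]
        island_probes = probes.loc[probes["cpg_island"], "probe_id"]
        sub = meth.values.loc[island_probes]
        copd = meth.groups == GROUP_COPD
        assert (sub.loc[:, copd.values].mean().mean()
                > sub.loc[:, ~copd.values].mean().mean() + 0.02)

    def test_severity_trait_signs(self, default_cohort):
        """DLCO falls and BODE rises with the same underlying severity:
        the two traits are negatively correlated."""
        phen = default_cohort[5]
        r = stats.spearman(phen["DLCO"], phen["BODE"])
        assert r.rho < -0.2
        r2 = stats.spearman(phen["BODE"], phen["emphysema_pct"])
        assert r2.rho > 0.2


class TestShuffleSamples:
    def test_zero_swaps_is_identity(self, small_cohort):
        expr = small_cohort[1]
        shuffled, pairing = shuffle_samples(expr, 0, seed=1)
        pd.testing.assert_frame_equal(shuffled.values, expr.values)
        assert all(u == v for u, v in pairing.items())

    def test_two_swaps_is_one_transposition(self, small_cohort):
        expr = small_cohort[1]
        shuffled, pairing = shuffle_samples(expr, 2, seed=1)
        moved = [s for s in expr.sample_ids
                 if not shuffled.values[s].equals(expr.values[s])]
        assert len(moved) == 2
        changed = [u for u, v in pairing.items() if u != v]
        assert len(changed) == 2

    def test_seeded_determinism(self, small_cohort):
        expr = small_cohort[1]
        a, pa = shuffle_samples(expr, 10, seed=5)
        b, pb = shuffle_samples(expr, 10, seed=5)
        pd.testing.assert_frame_equal(a.values, b.values)
        assert pa == pb

    def test_too_many_swaps_rejected(self, small_cohort):
        expr = small_cohort[1]
        with pytest.raises(ValueError, match="n_swaps"):
            shuffle_samples(expr, expr.n_samples + 1, seed=0)

    def test_single_swap_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="derangement"):
            shuffle_samples(small_cohort[1], 1, seed=0)
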