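"""Probe mapping, covariate adjustment, differential analysis, FDR."""

import numpy as np
import pandas as pd
import pytest

from methdriver import preprocess
from methdriver.datatypes import (
    FDRReport, GROUP_COPD, GROUP_CTRL, MODALITY_EXPR, MODALITY_METH, OmicsMatrix,
)
from methdriver.simulate import SimConfig, simulate


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])


def _probes(rows):
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "cpg_island"])


class TestMapProbes:
    def test_boundary_strictly_below_10kb(self):
        genes = _genes([("gA", "chr1", 100_000, "+")])
        probes = _probes([("near", "chr1", 100_000 + 9_999, True),
                          ("edge", "chr1", 100_000 + 10_000, True)])
        mapped = preprocess.map_probes(probes, genes)
        assert mapped.loc[mapped.probe_id == "near", "gene_id"].iloc[0] == "gA"
        assert mapped.loc[mapped.probe_id == "edge", "gene_id"].isna().iloc[0]

    def test_equidistant_tie_resolved_lexicographically_and_flagged(self):
        genes = _genes([("gB", "chr1", 10_000, "+"), ("gA", "chr1", 20_000, "+")])
        probes = _probes([("mid", "chr1", 15_000, False)])
        mapped = preprocess.map_probes(probes, genes)
        row = mapped.iloc[0]
        assert row["gene_id"] == "gA"
        assert bool(row["tie"])

    def test_distance_is_strand_signed(self):
        genes = _genes([("plus", "chr1", 10_000, "+"),
                        ("minus", "chr2", 10_000, "-")])
        probes = _probes([("p", "chr1", 11_000, False),
                          ("m", "chr2", 11_000, False)])
        mapped = preprocess.map_probes(probes, genes).set_index("probe_id")
        assert mapped.loc["p", "tss_distance"] == 1_000    # downstream of +
        assert mapped.loc["m", "tss_distance"] == -1_000   # upstream of -

    def test_nearest_of_several(self):
        genes = _genes([("far", "chr1", 1_000, "+"), ("close", "chr1", 30_000, "+")])
        probes = _probes([("p", "chr1", 28_000, False)])
        mapped = preprocess.map_probes(probes, genes)
        assert mapped.iloc[0]["gene_id"] == "close"


class TestAdjustCovariates:
    @pytest.fixture
    def matrix_and_covariates(self):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(40)]
        age = rng.normal(60, 10, 40)
        sex = rng.choice(["F", "M"], 40)
        cov = pd.DataFrame({"age": age, "sex": sex}, index=samples)
        values = pd.DataFrame(rng.normal(size=(15, 40)), columns=samples,
                              index=[f"f{i}" for i in range(15)])
        return OmicsMatrix(values, MODALITY_EXPR), cov

    def test_feature_means_preserved(self, matrix_and_covariates):
        matrix, cov = matrix_and_covariates
        adjusted = preprocess.adjust_covariates(matrix, cov)
        np.testing.assert_allclose(adjusted.values.mean(axis=1),
                                   matrix.values.mean(axis=1), atol=1e-10)

    def test_idempotent(self, matrix_and_covariates):
        matrix, cov = matrix_and_covariates
        once = preprocess.adjust_covariates(matrix, cov)
        twice = preprocess.adjust_covariates(once, cov)
        np.testing.assert_allclose(once.values.to_numpy(),
                                   twice.values.to_numpy(), atol=1e-10)

    def test_perfect_covariate_fit_leaves_constant(self, matrix_and_covariates):
        matrix, cov = matrix_and_covariates
        feature = 2.0 * cov["age"].to_numpy() + 5.0
        values = pd.DataFrame([feature], index=["lin"], columns=matrix.sample_ids)
        adjusted = preprocess.adjust_covariates(
            OmicsMatrix(values, MODALITY_EXPR), cov)
        np.testing.assert_allclose(adjusted.values.loc["lin"].to_numpy(),
                                   np.full(40, feature.mean()), atol=1e-8)

    def test_null_covariate_changes_little(self):
        rng = np.random.default_rng(1)
        samples = [f"s{i}" for i in range(200)]
        cov = pd.DataFrame({"junk": rng.normal(size=200)}, index=samples)
        values = pd.DataFrame(rng.normal(size=(5, 200)), columns=samples,
                              index=list("abcde"))
        matrix = OmicsMatrix(values, MODALITY_EXPR)
        adjusted = preprocess.adjust_covariates(matrix, cov)
        delta = np.abs(adjusted.values.to_numpy() - values.to_numpy())
        assert delta.max() < 0.5  # only the noise of one fitted coefficient

    def test_collinear_column_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        samples = [f"s{i}" for i in range(30)]
        age = rng.normal(60, 5, 30)
        cov = pd.DataFrame({"age": age, "age_months": age * 12}, index=samples)
        values = pd.DataFrame(rng.normal(size=(3, 30)), columns=samples,
                              index=list("xyz"))
        with pytest.warns(UserWarning, match="collinear"):
            preprocess.adjust_covariates(OmicsMatrix(values, MODALITY_EXPR), cov)


class TestDifferential:
    def _matrix(self, ctrl, copd, modality=MODALITY_EXPR):
        ctrl = np.atleast_2d(ctrl)
        copd = np.atleast_2d(copd)
        samples = ([f"c{i}" for i in range(ctrl.shape[1])]
                   + [f"d{i}" for i in range(copd.shape[1])])
        groups = pd.Series([GROUP_CTRL] * ctrl.shape[1]
                           + [GROUP_COPD] * copd.shape[1], index=samples)
        values = pd.DataFrame(np.hstack([ctrl, copd]), columns=samples,
                              index=[f"f{i}" for i in range(ctrl.shape[0])])
        return OmicsMatrix(values, modality, groups)

    def test_identical_constant_groups_give_p_one(self):
        m = self._matrix(np.full((1, 5), 3.0), np.full((1, 5), 3.0))
        res = preprocess.differential(m)
        assert res.loc[0, "p"] == 1.0
        assert res.loc[0, "direction"] == "none"

    def test_strong_separation_is_significant(self):
        rng = np.random.default_rng(3)
        m = self._matrix(rng.normal(0, 1, (1, 50)), rng.normal(3, 1, (1, 50)))
        res = preprocess.differential(m)
        assert res.loc[0, "p"] < 1e-10
        assert res.loc[0, "direction"] == "up"

    def test_label_swap_keeps_p_flips_direction(self):
        rng = np.random.default_rng(4)
        ctrl, copd = rng.normal(0, 1, (1, 20)), rng.normal(1, 1, (1, 20))
        m = self._matrix(ctrl, copd)
        res = preprocess.differential(m)
        swapped = self._matrix(copd, ctrl)
        res_sw = preprocess.differential(swapped)
        assert res.loc[0, "p"] == pytest.approx(res_sw.loc[0, "p"])
        assert {res.loc[0, "direction"], res_sw.loc[0, "direction"]} == {"up", "down"}

    def test_methylation_directions_are_hyper_hypo(self):
        m = self._matrix(np.array([[0.2] * 5 + [0.21, 0.19, 0.2, 0.2, 0.2]])[:, :5],
                         np.array([[0.8, 0.79, 0.81, 0.8, 0.8]]),
                         modality=MODALITY_METH)
        res = preprocess.differential(m)
        assert res.loc[0, "direction"] == "hyper"


class TestPermutationFDR:
    def test_formula_on_reported_counts(self):
        """mean permuted 518 over observed 362,095 gives 0.0014 at two
        significant figures."""
        rep = FDRReport(threshold=1e-4, n_observed=362_095,
                        permuted_counts=[518] * 5)
        assert rep.fdr == pytest.approx(518 / 362_095)
        assert float(f"{rep.fdr:.2g}") == 0.0014

    def test_all_zero_permuted_counts_give_zero(self):
        rep = FDRReport(0.01, 100, [0, 0, 0])
        assert rep.fdr == 0.0

    def test_zero_observed_is_undefined_not_infinite(self):
        rep = FDRReport(0.01, 0, [3, 5])
        assert rep.undefined and rep.fdr is None

    def test_null_simulation_fdr_at_least_half(self):
        cfg = SimConfig(seed=6, hypermeth_shift=0.0, n_genes=250,
                        n_key_regulators=0, downstream_counts=[],
                        n_background_regulators=0, frac_model2=0.0,
                        n_confounded=0)
        meth = simulate(cfg)[0]
        rep = preprocess.permutation_fdr_differential(meth, p_threshold=0.01,
                                                      n_perm=100, seed=1)
        assert rep.fdr is None or rep.fdr >= 0.5

    def test_signal_fdr_small_and_counts_monotone_in_threshold(self,
                                                               default_cohort):
        meth = default_cohort[0]
        reps = [preprocess.permutation_fdr_differential(
                    meth, p_threshold=t, n_perm=20, seed=2)
                for t in (0.05, 0.01, 0.001)]
        assert reps[1].fdr < 0.5
        for tight, loose in zip(reps[1:], reps[:-1]):
            assert tight.n_observed <= loose.n_observed
            assert tight.mean_permuted <= loose.mean_permuted

    def test_seeded_reports_reproducible(self, small_cohort):
        meth = small_cohort[0]
        a = preprocess.permutation_fdr_differential(meth, n_perm=10, seed=3)
        b = preprocess.permutation_fdr_differential(meth, n_perm=10, seed=3)
        assert a.permuted_counts == b.permuted_counts


class TestFilterProbes:
    @pytest.fixture
    def mapped(self, small_cohort):
        return preprocess.map_probes(small_cohort[2], small_cohort[3])

    def test_island_filter(self, mapped):
        out = preprocess.filter_probes(mapped, require_island=True)
        assert out["cpg_island"].all()

    def test_tss_window(self, mapped):
        out = preprocess.filter_probes(mapped, tss_window=1_000)
        assert (out["tss_distance"].abs() < 1_000).all()

    def test_min_probes_per_gene(self, mapped):
        thin = mapped.groupby("gene_id", group_keys=False).head(1)
        out = preprocess.filter_probes(
            pd.concat([mapped, thin]).drop_duplicates("probe_id"),
            min_probes_per_gene=2)
        assert (out.groupby("gene_id")["probe_id"].count() >= 2).all()
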