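"""Overlap statistics and severity-trait screens."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from methdriver import enrichment, preprocess
from methdriver.datatypes import GeneSet, RegulatorSummary
from methdriver.simulate import SimConfig, simulate


class TestOverlapTest:
    def test_hand_enumerated_example(self):
        """N=10, |query|=4, |reference|=5, k=4: p = C(5,4)C(5,0)/C(10,4) = 5/210."""
        res = enrichment.overlap_test(GeneSet("q", set("abcd")),
                                      GeneSet("r", set("abcde")), 10)
        assert res.p == pytest.approx(5 / 210)
        assert res.overlap == 4

    def test_no_overlap_in_huge_universe_is_near_one(self):
        res = enrichment.overlap_test(GeneSet("q", {"a", "b"}),
                                      GeneSet("r", {"c", "d"}), 100_000)
        assert res.p > 0.999

    def test_equals_one_sided_fisher(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            N = int(rng.integers(20, 500))
            K = int(rng.integers(1, N // 2))
            n = int(rng.integers(1, N // 2))
            k = int(rng.integers(max(0, K + n - N), min(K, n) + 1))
            q = GeneSet("q", {f"g{i}" for i in range(n)})
            r = GeneSet("r", {f"g{i}" for i in range(k)}
                        | {f"h{i}" for i in range(K - k)})
            p_hyper = enrichment.overlap_test(q, r, N).p
            table = [[k, n - k], [K - k, N - K - n + k]]
            _, p_fisher = sps.fisher_exact(table, alternative="greater")
            assert p_hyper == pytest.approx(p_fisher, abs=1e-12)

    def test_p_nonincreasing_in_overlap(self):
        N, K, n = 1000, 60, 40
        ps = []
        for k in range(0, 21, 5):
            q = GeneSet("q", {f"g{i}" for i in range(k)}
                        | {f"x{i}" for i in range(n - k)})
            r = GeneSet("r", {f"g{i}" for i in range(k)}
                        | {f"y{i}" for i in range(K - k)})
            ps.append(enrichment.overlap_test(q, r, N).p)
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_inconsistent_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            enrichment.overlap_test(GeneSet("q", set("abcdefgh")),
                                    GeneSet("r", set("ijklmnop")), 10)


class TestTraitSignatures:
    @pytest.fixture(scope="class")
    def cohort(self):
        # 200 samples: the scale at which driver genes are reliably captured
        cfg = SimConfig(seed=3, n_ctrl=70, n_copd=130, n_genes=300,
                        n_key_regulators=2, downstream_counts=[40, 50],
                        n_background_regulators=60, trait_missing_frac=0.0)
        return simulate(cfg)

    def test_driver_genes_captured(self, cohort):
        meth, expr, probes, genes, cov, phen, truth = cohort
        adj = preprocess.adjust_covariates(expr, cov)
        sigs, reports, flagged = enrichment.trait_signatures(adj, phen, seed=1)
        driver = truth.trait_drivers["BODE"]
        downstream = truth.downstream[driver]
        captured = len(downstream & sigs["BODE"].genes) / len(downstream)
        assert captured >= 0.8
        assert not flagged

    def test_constant_trait_gives_empty_signature(self, cohort):
        expr = cohort[1]
        phen = pd.DataFrame({"flat": 1.0},
                            index=expr.sample_ids)
        sigs, _, _ = enrichment.trait_signatures(expr, phen, n_perm=1, seed=0)
        assert len(sigs["flat"]) == 0

    def test_sparse_trait_flagged_and_empty(self, cohort):
        expr = cohort[1]
        y = pd.Series(np.nan, index=expr.sample_ids)
        y.iloc[:5] = [1.0, 2.0, 3.0, 4.0, 5.0]
        sigs, _, flagged = enrichment.trait_signatures(
            expr, pd.DataFrame({"thin": y}), n_perm=1, seed=0)
        assert "thin" in flagged and len(sigs["thin"]) == 0

    def test_permuted_trait_signature_near_nominal_size(self, cohort):
        expr = cohort[1]
        rng = np.random.default_rng(4)
        phen = pd.DataFrame({"noise": rng.normal(size=expr.n_samples)},
                            index=expr.sample_ids)
        sigs, _, _ = enrichment.trait_signatures(expr, phen, p_max=0.01,
                                                 n_perm=1, seed=0)
        assert len(sigs["noise"]) <= 0.03 * expr.n_features

    def test_bit_reproducible(self, cohort):
        expr, phen = cohort[1], cohort[5]
        a = enrichment.trait_signatures(expr, phen, n_perm=2, seed=5)
        b = enrichment.trait_signatures(expr, phen, n_perm=2, seed=5)
        assert {t: s.genes for t, s in a[0].items()} == {t: s.genes
                                                         for t, s in b[0].items()}
        assert all(a[1][t].permuted_counts == b[1][t].permuted_counts
                   for t in a[1])


class TestDownstreamScreen:
    @staticmethod
    def _summary(downstream):
        return RegulatorSummary(
            pd.DataFrame({"gene_id": list(downstream),
                          "n_downstream": [len(v) for v in downstream.values()]}),
            {k: frozenset(v) for k, v in downstream.items()})

    def test_survivors_shrink_as_p_max_decreases(self):
        rng = np.random.default_rng(6)
        universe = [f"g{i}" for i in range(500)]
        sigs = {t: GeneSet(t, set(rng.choice(universe, 60, replace=False)))
                for t in ("A", "B")}
        downstream = {f"r{i}": set(rng.choice(universe, 50, replace=False))
                      for i in range(20)}
        summary = self._summary(downstream)
        prev = None
        for p_max in (0.5, 0.05, 0.005):
            _, surv = enrichment.downstream_signature_screen(summary, sigs,
                                                             500, p_max=p_max)
            if prev is not None:
                assert set(surv) <= set(prev)
            prev = surv

    def test_empty_signature_cell_is_one(self):
        summary = self._summary({"r": {"a", "b"}})
        sigs = {"T": GeneSet("T", set())}
        pmat, surv = enrichment.downstream_signature_screen(summary, sigs, 100)
        assert pmat.loc["r", "T"] == 1.0 and surv == []


class TestCollectionEnrichment:
    def test_oversized_set_skipped(self):
        universe = [f"g{i}" for i in range(3000)]
        big = GeneSet("big", set(universe[:2000]))
        small = GeneSet("small", set(universe[:20]))
        res = enrichment.geneset_collection_enrichment(
            GeneSet("q", set(universe[:20])), [big, small], universe)
        assert [r.reference for r in res] == ["small"]

    def test_query_identical_to_set_is_minimum_p(self):
        universe = [f"g{i}" for i in range(1000)]
        rng = np.random.default_rng(7)
        target = GeneSet("target", set(universe[:20]))
        others = [GeneSet(f"s{i}", set(rng.choice(universe, 20, replace=False)))
                  for i in range(10)]
        res = enrichment.geneset_collection_enrichment(
            GeneSet("q", target.genes), [target] + others, universe)
        assert res[0].reference == "target"

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            enrichment.geneset_collection_enrichment(
                GeneSet("q", set()), [GeneSet("s", {"a"})], ["a", "b"])
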