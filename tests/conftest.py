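"""Shared fixtures: simulated cohorts at the default study conditions.

The expensive artifacts (a full seed-1 cohort analysed end to end) are
session-scoped so several tests can interrogate the same run.
"""

from __future__ import annotations

import numpy as np
import pytest

from methdriver import association, causality, preprocess, regulators
from methdriver.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def default_cohort():
    """Default study conditions: 52+100 samples, 500 genes, 5 hubs, seed 1."""
    return simulate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_analysis(default_cohort):
    """Seed-1 cohort taken through mapping, adjustment, association and
    trio classification (identity sample pairing)."""
    meth, expr, probes, genes, covariates, phenotypes, truth = default_cohort
    mapped = preprocess.map_probes(probes, genes)
    adj_meth = preprocess.adjust_covariates(meth, covariates)
    adj_expr = preprocess.adjust_covariates(expr, covariates)
    cis = association.find_cis_pairs(adj_meth, adj_expr, mapped)
    cand = association.find_trans_pairs(adj_meth, adj_expr, mapped, cis)
    trios = causality.classify_trios(cand, adj_meth, adj_expr)
    summary = regulators.summarize_regulators(trios, model="I")
    return {
        "meth": meth, "expr": expr, "probes": probes, "genes": genes,
        "covariates": covariates, "phenotypes": phenotypes, "truth": truth,
        "mapped": mapped, "adj_meth": adj_meth, "adj_expr": adj_expr,
        "cis": cis, "candidates": cand, "trios": trios, "summary": summary,
    }


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for fast structural tests."""
    cfg = SimConfig(seed=7, n_ctrl=30, n_copd=50, n_genes=120,
                    n_key_regulators=2, downstream_counts=[15, 25],
                    n_background_regulators=30, n_confounded=5)
    return simulate(cfg)


def trio_key(df, trans_col="trans_gene"):
    return set(zip(df["probe_id"], df["cis_gene"], df[trans_col]))
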