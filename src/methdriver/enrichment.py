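"""Severity-trait screens and gene-set overlap statistics.

Three screens single out regulators of disease severity:

1. *Trait expression signatures*: genes whose expression Spearman-
   correlates with a severity trait (p < 0.01), with a permutation FDR
   from five whole-matrix expression permutations.
2. *Regulator methylation screen*: each key regulator's mean promoter
   beta against every trait (p < 0.05), reporting regulators significant
   for all five traits.
3. *Downstream-signature overlap*: each regulator's downstream target set
   against each trait signature by the upper-tail hypergeometric test
   (equivalent to one-sided Fisher's exact), reporting regulators whose
   downstream genes overlap every signature.

A generic gene-set-collection enrichment (hypergeometric per set, sets
larger than 1500 genes skipped as non-specific) rounds out the module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import association, stats
from .datatypes import EnrichmentResult, FDRReport, GeneSet, OmicsMatrix, TRAITS

MIN_TRAIT_N = 10
DEFAULT_MAX_SET_SIZE = 1500


def _trait_signature_sizes(expr_values: np.ndarray, genes, phenotypes: pd.DataFrame,
                           samples, p_max: float):
    """Per-trait signature gene lists for one expression matrix."""
    out = {}
    for trait in phenotypes.columns:
        y = phenotypes[trait].reindex(samples).to_numpy(dtype=float)
        mask = np.isfinite(y)
        if mask.sum() < MIN_TRAIT_N:
            out[trait] = []
            continue
        rho = stats.spearman_cross(expr_values[:, mask], y[mask][None, :])[:, 0]
        p = stats.spearman_pvalues(rho, int(mask.sum()))
        out[trait] = [g for g, pv in zip(genes, p) if pv < p_max]
    return out


def trait_signatures(expr: OmicsMatrix, phenotypes: pd.DataFrame,
                     p_max: float = 0.01, n_perm: int = 5, seed: int = 0):
    """Per-trait expression signatures with permutation FDRs.

    Spearman of every gene against every trait over the samples with a
    non-missing trait value (pairwise deletion, minimum 10); the signature
    is the genes with p < ``p_max``.  FDR per trait comes from ``n_perm``
    permutations of the expression sample columns.  Traits with too few
    observations yield an empty, flagged signature.

    Returns (signatures: dict trait -> GeneSet, reports: dict trait ->
    FDRReport, flagged: list of traits with insufficient data).
    """
    samples = expr.sample_ids
    vals = expr.values.to_numpy(dtype=float)
    obs = _trait_signature_sizes(vals, expr.feature_ids, phenotypes, samples, p_max)
    flagged = [t for t in phenotypes.columns
               if phenotypes[t].reindex(samples).notna().sum() < MIN_TRAIT_N]
    rng = np.random.default_rng(seed)
    perm_counts = {t: [] for t in phenotypes.columns}
    for _ in range(n_perm):
        eperm = association.permute_expression(expr, rng)
        pvals = eperm.values.to_numpy(dtype=float)
        sizes = _trait_signature_sizes(pvals, expr.feature_ids, phenotypes,
                                       samples, p_max)
        for t in phenotypes.columns:
            perm_counts[t].append(len(sizes[t]))
    signatures = {t: GeneSet(name=t, genes=frozenset(obs[t]),
                             description=f"expression signature p<{p_max}")
                  for t in phenotypes.columns}
    reports = {t: FDRReport(threshold=p_max, n_observed=len(obs[t]),
                            permuted_counts=perm_counts[t])
               for t in phenotypes.columns}
    return signatures, reports, flagged


def regulator_trait_screen(meth: OmicsMatrix, regulators: list,
                           annotation: pd.DataFrame, phenotypes: pd.DataFrame,
                           p_max: float = 0.05, probe_level: bool = False):
    """Promoter methylation of each regulator against each severity trait.

    A regulator's promoter methylation is summarised as the mean beta
    across its mapped probes (with ``probe_level`` a regulator counts as
    significant for a trait if any single probe is).  Returns
    (table with columns regulator, trait, rho, p, significant;
    list of regulators significant for all five traits).
    """
    ann = annotation[annotation["gene_id"].isin(regulators)]
    rows = []
    all5 = []
    for reg in regulators:
        probe_ids = ann.loc[ann["gene_id"] == reg, "probe_id"]
        probe_ids = [p for p in probe_ids if p in meth.feature_ids]
        if not probe_ids:
            continue
        sub = meth.values.loc[probe_ids]
        profiles = sub.to_numpy() if probe_level else sub.mean(axis=0).to_numpy()[None, :]
        hit_all = True
        for trait in phenotypes.columns:
            y = phenotypes[trait].reindex(meth.sample_ids).to_numpy(dtype=float)
            best = (np.nan, 1.0)
            for prof in profiles:
                r = stats.spearman(prof, y)
                if r.p < best[1]:
                    best = (r.rho, r.p)
            rows.append({"regulator": reg, "trait": trait,
                         "rho": best[0], "p": best[1],
                         "significant": best[1] < p_max})
            hit_all &= best[1] < p_max
        if hit_all:
            all5.append(reg)
    table = pd.DataFrame(rows, columns=["regulator", "trait", "rho", "p",
                                        "significant"])
    return table, all5


def overlap_test(query: GeneSet, reference: GeneSet,
                 universe_size: int) -> EnrichmentResult:
    """Upper-tail hypergeometric overlap test P(X >= k).

    With universe N, reference size K and query size n, the p-value is
    the one-sided Fisher's exact p of the 2x2 overlap table.
    """
    nq, nr = len(query), len(reference)
    k = len(query.genes & reference.genes)
    if universe_size < nq + nr - k:
        raise ValueError("universe smaller than the union of the two sets")
    if nq == 0:
        raise ValueError("query gene set is empty")
    p = float(sps.hypergeom.sf(k - 1, universe_size, nr, nq))
    expected = nq * nr / universe_size
    return EnrichmentResult(query=query.name, reference=reference.name,
                            universe_size=universe_size, query_size=nq,
                            reference_size=nr, overlap=k, expected=expected,
                            p=min(p, 1.0))


def downstream_signature_screen(summary, signatures: dict, universe_size: int,
                                p_max: float = 0.05):
    """Overlap of each regulator's downstream set with each trait signature.

    Empty signatures contribute p = 1 for their cell.  Returns (p-value
    matrix regulators x traits, list of regulators significant for ALL
    traits).
    """
    regs = list(summary.downstream)
    traits = list(signatures)
    pmat = pd.DataFrame(1.0, index=pd.Index(regs, name="regulator"), columns=traits)
    for reg in regs:
        qset = GeneSet(reg, summary.downstream[reg])
        if len(qset) == 0:
            continue
        for trait in traits:
            ref = signatures[trait]
            if len(ref) == 0:
                pmat.loc[reg, trait] = 1.0
                continue
            pmat.loc[reg, trait] = overlap_test(qset, ref, universe_size).p
    survivors = [r for r in regs if (pmat.loc[r] < p_max).all()]
    return pmat, survivors


def geneset_collection_enrichment(query: GeneSet, collection: list,
                                  universe: list,
                                  max_set_size: int = DEFAULT_MAX_SET_SIZE):
    """Hypergeometric enrichment of a query set against a collection.

    Collection sets larger than ``max_set_size`` (raw size) are skipped as
    non-specific; the remainder are intersected with the universe before
    testing.  Results are sorted by p-value.
    """
    if len(query) == 0:
        raise ValueError("query gene set is empty")
    uni = frozenset(universe)
    q = GeneSet(query.name, query.genes & uni)
    if len(q) == 0:
        raise ValueError("query has no genes in the universe")
    out = []
    for gs in collection:
        if len(gs) > max_set_size:
            continue
        ref = GeneSet(gs.name, gs.genes & uni, gs.description)
        if len(ref) == 0:
            continue
        out.append(overlap_test(q, ref, len(uni)))
    return sorted(out, key=lambda r: r.p)
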