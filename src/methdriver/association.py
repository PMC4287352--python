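"""Cis and trans methylation-expression pair detection.

A *cis* pair associates a promoter probe's beta values with the expression
of its assigned gene; a *trans* pair associates the probe with the
expression of any other gene.  All association is Spearman correlation
with a t-approximation p-value.  Trans testing is anchored: only probes
that already carry a significant cis pair are scanned against the rest of
the transcriptome, and each hit is emitted as a candidate
(probe, cis gene, trans gene) trio for the causality stage.  FDRs are
estimated by permuting the sample columns of the whole expression matrix
(methylation untouched).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import FDRReport, OmicsMatrix
from . import stats

DEFAULT_P_CIS = 0.01
DEFAULT_P_TRANS = 1e-5


def _aligned(meth: OmicsMatrix, expr: OmicsMatrix):
    shared = [s for s in meth.sample_ids if s in set(expr.sample_ids)]
    if len(shared) < stats.MIN_N:
        raise ValueError("fewer than 5 shared samples between matrices")
    return meth.values[shared], expr.values[shared]


def find_cis_pairs(meth: OmicsMatrix, expr: OmicsMatrix, annotation: pd.DataFrame,
                   p_max: float = DEFAULT_P_CIS) -> pd.DataFrame:
    """One Spearman test per (probe, its assigned gene); keep p < p_max.

    Unmapped probes, and probes whose gene is absent from the expression
    matrix, are never tested.  Returns columns probe_id, gene_id, rho, p,
    relation (= "cis").
    """
    M, E = _aligned(meth, expr)
    ann = annotation[annotation["gene_id"].notna()]
    ann = ann[ann["probe_id"].isin(M.index) & ann["gene_id"].isin(E.index)]
    if ann.empty:
        return pd.DataFrame(columns=["probe_id", "gene_id", "rho", "p", "relation"])
    probe_vals = M.loc[ann["probe_id"]].to_numpy()
    gene_vals = E.loc[ann["gene_id"]].to_numpy()
    rho = stats.spearman_paired(probe_vals, gene_vals)
    p = stats.spearman_pvalues(rho, M.shape[1])
    out = pd.DataFrame({
        "probe_id": ann["probe_id"].to_numpy(),
        "gene_id": ann["gene_id"].to_numpy(),
        "rho": rho,
        "p": p,
        "relation": "cis",
    })
    return out[out["p"] < p_max].reset_index(drop=True)


def find_trans_pairs(meth: OmicsMatrix, expr: OmicsMatrix, annotation: pd.DataFrame,
                     cis_anchor: pd.DataFrame,
                     p_max: float = DEFAULT_P_TRANS) -> pd.DataFrame:
    """Scan cis-anchored probes against every other gene's expression.

    Only probes present in ``cis_anchor`` are tested, each against all
    genes except the probe's own assigned gene.  Returns candidate trios
    with columns probe_id, cis_gene, gene_id (the trans gene), rho, p,
    relation (= "trans").
    """
    if cis_anchor.empty:
        raise ValueError("cis_anchor is empty; run find_cis_pairs first")
    M, E = _aligned(meth, expr)
    anchor = cis_anchor.drop_duplicates("probe_id")
    anchor = anchor[anchor["probe_id"].isin(M.index)]
    probe_ids = anchor["probe_id"].to_numpy()
    own_gene = anchor["gene_id"].to_numpy()
    if len(probe_ids) == 0:
        return pd.DataFrame(columns=["probe_id", "cis_gene", "gene_id", "rho", "p",
                                     "relation"])
    rho = stats.spearman_cross(M.loc[probe_ids].to_numpy(), E.to_numpy())
    p = stats.spearman_pvalues(rho, M.shape[1])
    gene_index = {g: i for i, g in enumerate(E.index)}
    for k, g in enumerate(own_gene):
        if g in gene_index:
            p[k, gene_index[g]] = np.inf  # a gene is never its own trans partner
    hit_i, hit_j = np.where(p < p_max)
    out = pd.DataFrame({
        "probe_id": probe_ids[hit_i],
        "cis_gene": own_gene[hit_i],
        "gene_id": E.index.to_numpy()[hit_j],
        "rho": rho[hit_i, hit_j],
        "p": p[hit_i, hit_j],
        "relation": "trans",
    })
    return out.reset_index(drop=True)


def permute_expression(expr: OmicsMatrix, rng: np.random.Generator) -> OmicsMatrix:
    """One random permutation of the sample columns of the whole matrix.

    Sample labels (and their group assignments) stay in place; the data
    columns move beneath them.
    """
    perm = rng.permutation(expr.n_samples)
    values = pd.DataFrame(expr.values.to_numpy()[:, perm],
                          index=expr.feature_ids, columns=expr.sample_ids)
    return OmicsMatrix(values, expr.modality, expr.groups)


def permutation_fdr_pairs(meth: OmicsMatrix, expr: OmicsMatrix,
                          annotation: pd.DataFrame,
                          p_cis: float = DEFAULT_P_CIS,
                          p_trans: float = DEFAULT_P_TRANS,
                          n_perm: int = 5, seed: int = 0,
                          which: str = "trans") -> FDRReport:
    """Permutation FDR for pair detection.

    Each permutation shuffles the expression sample columns once, reruns
    the full detection (cis anchoring, then the trans scan when
    ``which="trans"``) and counts surviving pairs.
    """
    cis = find_cis_pairs(meth, expr, annotation, p_max=p_cis)
    if which == "cis":
        observed = len(cis)
        threshold = p_cis
    else:
        observed = 0 if cis.empty else len(
            find_trans_pairs(meth, expr, annotation, cis, p_max=p_trans))
        threshold = p_trans
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(n_perm):
        eperm = permute_expression(expr, rng)
        cis_p = find_cis_pairs(meth, eperm, annotation, p_max=p_cis)
        if which == "cis":
            counts.append(len(cis_p))
        elif cis_p.empty:
            counts.append(0)
        else:
            counts.append(len(find_trans_pairs(meth, eperm, annotation, cis_p,
                                               p_max=p_trans)))
    return FDRReport(threshold=threshold, n_observed=observed,
                     permuted_counts=counts)
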