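"""Trio causality test: Model I (M -> C -> T) versus Model II (T -> M -> C).

For a candidate trio of promoter methylation M, its cis gene expression C
and a trans gene expression T, the chain of association tests is combined
with a residual-based conditional-independence test:

* Model I requires a significant M-C association, a significant C-T
  association, and *independence* of M from T once C is regressed out
  (M and T conditionally independent given the mediator C).
* Model II mirrors the chain with roles reversed: a significant T-M
  association and independence of T from C given M.

Mediation regressions are ordinary least squares on the raw values; the
independence test itself is Spearman, keeping the procedure nonparametric
at the decision points.  A trio can satisfy neither model (``none``); if
it satisfies both, the direction with the larger conditional-independence
p-value (stronger mediation evidence) wins and the trio is flagged
ambiguous.  FDRs per model are estimated by permuting the expression
matrix columns and re-deriving candidates and verdicts from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import association, stats
from .datatypes import FDRReport, OmicsMatrix

TRIO_COLUMNS = ["probe_id", "cis_gene", "trans_gene", "p_cis", "p_trans", "p_ct",
                "p_indep_i", "p_indep_ii", "p_indep", "model", "ambiguous"]


@dataclass(frozen=True)
class CausalityThresholds:
    """Decision thresholds for the trio test.

    ``p_assoc`` bounds the association step of the tested chain (C-T for
    Model I, M-T for Model II); ``p_indep`` is the floor the
    conditional-independence p-value must exceed; ``p_cis`` bounds the
    M-C anchor association.
    """

    p_assoc: float = 1e-4
    p_indep: float = 0.01
    p_cis: float = 0.01


def conditional_independence(m, c, t, direction: str) -> float:
    """Residual-based conditional-independence p-value.

    direction "I": regress T on C (OLS), test Spearman(M, residuals).
    direction "II": regress C on M (OLS), test Spearman(T, residuals).
    Zero-variance residuals (perfect mediation) give p = 1.
    """
    m = np.asarray(m, dtype=float)
    c = np.asarray(c, dtype=float)
    t = np.asarray(t, dtype=float)
    if direction == "I":
        resid = stats.ols_residuals(t, c)
        probe_side = m
    elif direction == "II":
        resid = stats.ols_residuals(c, m)
        probe_side = t
    else:
        raise ValueError(f"direction must be 'I' or 'II', got {direction!r}")
    if np.allclose(resid, 0.0, atol=1e-12):
        return 1.0
    return stats.spearman(probe_side, resid).p


def classify_trio(m, c, t, thresholds: CausalityThresholds | None = None) -> dict:
    """Classify one (M, C, T) trio as Model I, Model II or none.

    Returns a dict with all five p-values and the verdict; degenerate
    vectors yield model "none".
    """
    th = thresholds or CausalityThresholds()
    r_cis = stats.spearman(m, c)
    r_ct = stats.spearman(c, t)
    r_mt = stats.spearman(m, t)
    out = {"p_cis": r_cis.p, "p_trans": r_mt.p, "p_ct": r_ct.p,
           "p_indep_i": np.nan, "p_indep_ii": np.nan, "p_indep": np.nan,
           "model": "none", "ambiguous": False}
    if r_cis.note != "ok" or r_ct.note != "ok" or r_mt.note != "ok":
        return out
    ci1 = conditional_independence(m, c, t, "I")
    ci2 = conditional_independence(m, c, t, "II")
    out["p_indep_i"], out["p_indep_ii"] = ci1, ci2
    model1 = (r_cis.p < th.p_cis) and (r_ct.p < th.p_assoc) and (ci1 > th.p_indep)
    model2 = (r_mt.p < th.p_assoc) and (ci2 > th.p_indep)
    if model1 and model2:
        out["model"] = "I" if ci1 >= ci2 else "II"
        out["ambiguous"] = True
    elif model1:
        out["model"] = "I"
    elif model2:
        out["model"] = "II"
    out["p_indep"] = {"I": ci1, "II": ci2, "none": np.nan}[out["model"]]
    return out


def classify_trios(candidates: pd.DataFrame, meth: OmicsMatrix, expr: OmicsMatrix,
                   thresholds: CausalityThresholds | None = None) -> pd.DataFrame:
    """Classify every candidate trio; returns the full trio table."""
    th = thresholds or CausalityThresholds()
    if candidates.empty:
        return pd.DataFrame(columns=TRIO_COLUMNS)
    shared = [s for s in meth.sample_ids if s in set(expr.sample_ids)]
    M = meth.values[shared]
    E = expr.values[shared]
    rows = []
    for rec in candidates.itertuples(index=False):
        probe, cis_gene = rec.probe_id, rec.cis_gene
        trans_gene = getattr(rec, "gene_id", None) or getattr(rec, "trans_gene")
        m = M.loc[probe].to_numpy()
        c = E.loc[cis_gene].to_numpy()
        t = E.loc[trans_gene].to_numpy()
        res = classify_trio(m, c, t, th)
        res.update({"probe_id": probe, "cis_gene": cis_gene,
                    "trans_gene": trans_gene})
        rows.append(res)
    return pd.DataFrame(rows, columns=TRIO_COLUMNS)


def run_causality(candidates: pd.DataFrame, meth: OmicsMatrix, expr: OmicsMatrix,
                  annotation: pd.DataFrame,
                  thresholds: CausalityThresholds | None = None,
                  scan_p_cis: float = association.DEFAULT_P_CIS,
                  scan_p_trans: float = association.DEFAULT_P_TRANS,
                  n_perm: int = 5, seed: int = 0):
    """Classify all candidates and estimate per-model permutation FDRs.

    Each permutation shuffles the expression sample columns once, then
    re-derives candidate trios (cis anchoring + trans scan at the same
    thresholds that produced ``candidates``) and re-classifies them; the
    FDR for a model is mean(permuted call count) / observed call count.
    """
    th = thresholds or CausalityThresholds()
    trios = classify_trios(candidates, meth, expr, th)
    observed = {mdl: int((trios["model"] == mdl).sum()) for mdl in ("I", "II")}
    rng = np.random.default_rng(seed)
    perm_counts = {"I": [], "II": []}
    for _ in range(n_perm):
        eperm = association.permute_expression(expr, rng)
        cis_p = association.find_cis_pairs(meth, eperm, annotation, p_max=scan_p_cis)
        if cis_p.empty:
            cand_p = pd.DataFrame(columns=["probe_id", "cis_gene", "gene_id"])
        else:
            cand_p = association.find_trans_pairs(meth, eperm, annotation, cis_p,
                                                  p_max=scan_p_trans)
        trios_p = classify_trios(cand_p, meth, eperm, th)
        for mdl in ("I", "II"):
            perm_counts[mdl].append(int((trios_p["model"] == mdl).sum()))
    reports = {
        mdl: FDRReport(threshold=th.p_assoc, n_observed=observed[mdl],
                       permuted_counts=perm_counts[mdl])
        for mdl in ("I", "II")
    }
    return trios, reports
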