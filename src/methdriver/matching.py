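"""Iterative methylation <-> expression sample alignment.

Multi-omics cohorts occasionally carry mislabelled samples; before any
integrative analysis the two assays must be aligned per individual.  The
matcher exploits the cis methylation-expression signal: a sample's
promoter methylation profile over cis-linked probes correlates with its
own expression profile over the corresponding genes far more strongly
than with any other sample's.

The procedure is self-consistent and deterministic:

1. seed with the nominal pairing (shared sample ids);
2. detect cis probe-gene pairs at Spearman p < ``p_cis`` under the
   current pairing;
3. score every (methylation sample u, expression sample v) by the
   Spearman correlation across those cis pairs between u's probe betas
   and v's gene expressions;
4. accept u <-> v when it is the mutual best in its row and column and
   its score exceeds the row mean by ``z_min`` row standard deviations;
5. repeat with the updated pairing until the mapping is stable or
   ``max_iter`` iterations.

Samples that cannot be unambiguously matched (no mutual best, low score
separation, or an exact tie such as duplicated columns) are dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import stats
from .datatypes import MatchReport, OmicsMatrix

_TIE_EPS = 1e-12


def _cis_pair_features(meth: OmicsMatrix, expr: OmicsMatrix,
                       annotation: pd.DataFrame, pairing: dict, p_cis: float):
    """Cis (probe, gene) pairs significant under the current pairing.

    Returns the probe ids, gene ids and the sign of each pair's cis
    correlation (needed to orient profiles: promoter methylation may
    correlate with expression in either direction).
    """
    ann = annotation[annotation["gene_id"].notna()]
    ann = ann[ann["probe_id"].isin(meth.feature_ids)
              & ann["gene_id"].isin(expr.feature_ids)]
    if ann.empty or not pairing:
        return [], [], np.array([])
    mcols = list(pairing.keys())
    ecols = [pairing[u] for u in mcols]
    M = meth.values.loc[ann["probe_id"], mcols].to_numpy()
    E = expr.values.loc[ann["gene_id"], ecols].to_numpy()
    rho = stats.spearman_paired(M, E)
    p = stats.spearman_pvalues(rho, len(mcols))
    keep = p < p_cis
    return (list(ann["probe_id"][keep]), list(ann["gene_id"][keep]),
            np.sign(rho[keep]))


def _score_matrix(meth: OmicsMatrix, expr: OmicsMatrix, probes, genes, signs):
    """Cross-sample match scores over the cis pairs.

    Each feature is rank-transformed across its own samples (removing
    per-feature baselines), expression rows are flipped by the sign of
    their pair's cis correlation, and every (meth sample, expr sample)
    couple is scored by the Spearman correlation of the two oriented
    rank profiles across the pairs.  Rows = meth samples, cols = expr
    samples.
    """
    M, _ = stats._rank_standardize(meth.values.loc[probes].to_numpy())
    E, _ = stats._rank_standardize(expr.values.loc[genes].to_numpy())
    E = E * signs[:, None]
    return stats.spearman_cross(M.T, E.T)


def match_samples(meth: OmicsMatrix, expr: OmicsMatrix, annotation: pd.DataFrame,
                  p_cis: float = 0.01, max_iter: int = 25,
                  z_min: float = 3.0) -> MatchReport:
    """Align methylation samples to expression samples.

    Requires at least 20 shared nominal sample ids to seed the first
    iteration; aborts with a diagnostic if no cis pairs are found at the
    seed pairing (signal too weak to match on).
    """
    shared = [s for s in meth.sample_ids if s in set(expr.sample_ids)]
    if len(shared) < 20:
        raise ValueError(f"need >= 20 shared nominal samples to seed matching, "
                         f"got {len(shared)}")
    pairing = {s: s for s in shared}
    msamples = list(meth.sample_ids)
    esamples = list(expr.sample_ids)

    iterations = 0
    scores = None
    for iterations in range(1, max_iter + 1):
        probes, genes, signs = _cis_pair_features(meth, expr, annotation, pairing,
                                                  p_cis)
        if not probes:
            if iterations == 1:
                raise ValueError("no cis probe-gene pairs at the seed pairing; "
                                 "signal too weak to match samples")
            break
        scores = _score_matrix(meth, expr, probes, genes, signs)
        new_pairing, _ = _extract_matches(scores, msamples, esamples, z_min)
        if new_pairing == pairing:
            break
        pairing = new_pairing
        if not pairing:
            break

    if scores is None:
        raise ValueError("matching produced no score matrix")
    final_pairing, drop_reasons = _extract_matches(scores, msamples, esamples, z_min)

    rows = []
    row_mean = scores.mean(axis=1)
    row_sd = scores.std(axis=1, ddof=1)
    for u, v in final_pairing.items():
        i, j = msamples.index(u), esamples.index(v)
        z = (scores[i, j] - row_mean[i]) / row_sd[i] if row_sd[i] > 0 else np.inf
        rows.append({"meth_sample": u, "expr_sample": v,
                     "score": scores[i, j], "z": z})
    pairs = pd.DataFrame(rows, columns=["meth_sample", "expr_sample", "score", "z"])

    dropped_rows = []
    matched_m = set(final_pairing)
    matched_e = set(final_pairing.values())
    for u in msamples:
        if u not in matched_m:
            dropped_rows.append({"sample": u, "axis": "methylation",
                                 "reason": drop_reasons.get(("m", u), "unmatched")})
    for v in esamples:
        if v not in matched_e:
            dropped_rows.append({"sample": v, "axis": "expression",
                                 "reason": drop_reasons.get(("e", v), "unmatched")})
    dropped = pd.DataFrame(dropped_rows, columns=["sample", "axis", "reason"])
    return MatchReport(pairs=pairs, dropped=dropped, iterations=iterations)


def _extract_matches(scores: np.ndarray, msamples, esamples, z_min: float):
    """Mutual-best matches passing the row z-score criterion.

    Exact score ties for a row or column maximum (e.g. duplicated
    columns) are unresolvable and the samples involved are dropped.
    """
    n_m, n_e = scores.shape
    row_best = scores.argmax(axis=1)
    col_best = scores.argmax(axis=0)
    row_mean = scores.mean(axis=1)
    row_sd = scores.std(axis=1, ddof=1)
    pairing = {}
    reasons = {}
    for i in range(n_m):
        j = row_best[i]
        row = scores[i]
        if (np.abs(row - row[j]) < _TIE_EPS).sum() > 1:
            reasons[("m", msamples[i])] = "ambiguous tie in row"
            continue
        col = scores[:, j]
        if (np.abs(col - col[col_best[j]]) < _TIE_EPS).sum() > 1:
            reasons[("m", msamples[i])] = "ambiguous tie in column"
            reasons[("e", esamples[j])] = "ambiguous tie in column"
            continue
        if col_best[j] != i:
            reasons[("m", msamples[i])] = "not mutual best"
            continue
        if row_sd[i] <= 0 or (row[j] - row_mean[i]) / row_sd[i] < z_min:
            reasons[("m", msamples[i])] = "score separation below z_min"
            continue
        pairing[msamples[i]] = esamples[j]
    return pairing, reasons
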