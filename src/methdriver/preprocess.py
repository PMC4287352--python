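"""Probe-to-gene mapping, covariate adjustment, probe filtering and
case/control differential analysis with permutation FDR.

Probes are assigned to the gene with the nearest transcription start site
when the distance is strictly below 10 kb; distances are strand-signed
(positive = downstream of the TSS).  Covariate adjustment regresses each
feature on the covariate design and keeps "means plus residuals", so
feature means are preserved exactly and the operation is idempotent.
Differential testing is a two-sample t-test (pooled variance by default,
Welch behind a flag) whose false discovery rate is estimated by permuting
the group labels.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import (
    FDRReport,
    GROUP_COPD,
    GROUP_CTRL,
    MODALITY_ADJ,
    MODALITY_EXPR,
    MODALITY_METH,
    OmicsMatrix,
)

DEFAULT_MAX_DIST = 10_000


def map_probes(probes: pd.DataFrame, genes: pd.DataFrame,
               max_dist: int = DEFAULT_MAX_DIST) -> pd.DataFrame:
    """Assign each probe to the gene with the nearest TSS on its chromosome.

    Assignment requires |probe position - TSS| strictly less than
    ``max_dist``; a probe exactly at the boundary stays unassigned.
    Equidistant ties go to the lexicographically smaller gene_id and are
    flagged in the ``tie`` column.  The stored distance is strand-signed:
    positive means the probe lies downstream of the TSS.
    """
    out = probes.copy()
    out["gene_id"] = None
    out["tss_distance"] = np.nan
    out["tie"] = False
    for chrom, gsub in genes.groupby("chrom"):
        psel = out["chrom"] == chrom
        if not psel.any():
            continue
        gsub = gsub.sort_values(["tss", "gene_id"]).reset_index(drop=True)
        tss = gsub["tss"].to_numpy()
        pos = out.loc[psel, "pos"].to_numpy()
        right = np.searchsorted(tss, pos)
        left = np.clip(right - 1, 0, len(tss) - 1)
        right = np.clip(right, 0, len(tss) - 1)
        d_left = np.abs(pos - tss[left])
        d_right = np.abs(pos - tss[right])
        assigned_gene = []
        assigned_dist = []
        assigned_tie = []
        for k in range(len(pos)):
            cand = {left[k]: d_left[k], right[k]: d_right[k]}
            best = min(cand.values())
            winners = sorted(gsub.loc[i, "gene_id"] for i, d in cand.items() if d == best)
            tie = len(winners) > 1
            gid = winners[0]
            if best < max_dist:
                grow = gsub[gsub["gene_id"] == gid].iloc[0]
                raw = pos[k] - grow["tss"]
                signed = int(raw if grow["strand"] == "+" else -raw)
                assigned_gene.append(gid)
                assigned_dist.append(signed)
                assigned_tie.append(tie)
            else:
                assigned_gene.append(None)
                assigned_dist.append(np.nan)
                assigned_tie.append(False)
        out.loc[psel, "gene_id"] = assigned_gene
        out.loc[psel, "tss_distance"] = assigned_dist
        out.loc[psel, "tie"] = assigned_tie
    return out


def _design_matrix(covariates: pd.DataFrame, samples) -> np.ndarray:
    cov = covariates.reindex(samples)
    if cov.isna().any().any():
        missing = cov.index[cov.isna().any(axis=1)][0]
        raise ValueError(f"covariates missing for sample {missing!r}")
    numeric = cov.select_dtypes(include=[np.number])
    categorical = cov.select_dtypes(exclude=[np.number])
    parts = [np.ones((len(cov), 1))]
    if not numeric.empty:
        parts.append(numeric.to_numpy(dtype=float))
    if not categorical.empty:
        dummies = pd.get_dummies(categorical, drop_first=True)
        parts.append(dummies.to_numpy(dtype=float))
    X = np.hstack(parts)
    # drop collinear columns (keep the intercept and earliest columns)
    keep = [0]
    rank = 1
    for j in range(1, X.shape[1]):
        r = np.linalg.matrix_rank(X[:, keep + [j]])
        if r > rank:
            keep.append(j)
            rank = r
        else:
            warnings.warn("dropping collinear covariate column from design",
                          stacklevel=2)
    return X[:, keep]


def adjust_covariates(matrix: OmicsMatrix, covariates: pd.DataFrame) -> OmicsMatrix:
    """Remove covariate effects feature-by-feature, keeping means.

    Each feature is regressed (OLS) on the covariate design; the output is
    the feature mean plus the residuals, so the mean of every adjusted
    feature equals the raw feature mean and re-adjusting changes nothing.
    Categorical covariates are dummy-coded; collinear design columns are
    dropped with a warning.  The output modality is ``adjusted`` (values
    are no longer bounded for methylation input).
    """
    X = _design_matrix(covariates, matrix.sample_ids)
    Y = matrix.values.to_numpy(dtype=float).T  # samples x features
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    adjusted = matrix.values.mean(axis=1).to_numpy()[:, None] + resid.T
    values = pd.DataFrame(adjusted, index=matrix.feature_ids,
                          columns=matrix.sample_ids)
    return OmicsMatrix(values, MODALITY_ADJ, matrix.groups)


def filter_probes(annotation: pd.DataFrame, require_island: bool = False,
                  tss_window: int | None = None,
                  min_probes_per_gene: int | None = None) -> pd.DataFrame:
    """Subset a mapped probe annotation.

    Keeps probes with an assigned gene; optionally restricts to CpG-island
    probes, to probes within ``tss_window`` bp of the TSS, and to genes
    carrying at least ``min_probes_per_gene`` retained probes.
    """
    out = annotation[annotation["gene_id"].notna()].copy()
    if require_island:
        out = out[out["cpg_island"].astype(bool)]
    if tss_window is not None:
        out = out[out["tss_distance"].abs() < tss_window]
    if min_probes_per_gene is not None:
        counts = out.groupby("gene_id")["probe_id"].transform("count")
        out = out[counts >= min_probes_per_gene]
    return out.reset_index(drop=True)


def _ttest_pvalues(values: np.ndarray, copd_mask: np.ndarray,
                   equal_var: bool = True):
    a = values[:, copd_mask]
    b = values[:, ~copd_mask]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind(a, b, axis=1, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    p[degenerate] = 1.0
    t[~np.isfinite(t)] = 0.0
    return t, p, degenerate


def differential(matrix: OmicsMatrix, groups: pd.Series | None = None,
                 equal_var: bool = True) -> pd.DataFrame:
    """Two-sample t-test of every feature between COPD and CTRL.

    Returns a frame with columns feature_id, mean_ctrl, mean_copd, t, p,
    direction.  Direction follows the COPD - CTRL mean difference:
    hyper/hypo for methylation, up/down for expression, and ``none`` when
    the pooled variance is zero (p is then 1).
    """
    groups = matrix.groups if groups is None else pd.Series(groups).reindex(matrix.sample_ids)
    if groups is None:
        raise ValueError("group labels required")
    copd = (groups == GROUP_COPD).to_numpy()
    ctrl = (groups == GROUP_CTRL).to_numpy()
    if copd.sum() < 2 or ctrl.sum() < 2:
        raise ValueError("need >= 2 samples per group")
    vals = matrix.values.to_numpy(dtype=float)
    t, p, degenerate = _ttest_pvalues(vals, copd, equal_var=equal_var)
    mean_copd = vals[:, copd].mean(axis=1)
    mean_ctrl = vals[:, ctrl].mean(axis=1)
    diff = mean_copd - mean_ctrl
    if matrix.modality == MODALITY_METH:
        up, down = "hyper", "hypo"
    else:
        up, down = "up", "down"
    direction = np.where(diff > 0, up, down)
    direction = np.where(degenerate | (diff == 0), "none", direction)
    return pd.DataFrame({
        "feature_id": matrix.feature_ids,
        "mean_ctrl": mean_ctrl,
        "mean_copd": mean_copd,
        "t": t,
        "p": p,
        "direction": direction,
    }).reset_index(drop=True)


def permutation_fdr_differential(matrix: OmicsMatrix, groups: pd.Series | None = None,
                                 p_threshold: float = 0.01, n_perm: int = 100,
                                 seed: int = 0, equal_var: bool = True) -> FDRReport:
    """Estimate the FDR of the differential test by label permutation.

    Group labels are permuted (sizes preserved) ``n_perm`` times; the FDR
    at the threshold is mean(permuted significant count) / observed count.
    """
    groups = matrix.groups if groups is None else pd.Series(groups).reindex(matrix.sample_ids)
    obs = differential(matrix, groups, equal_var=equal_var)
    n_observed = int((obs["p"] < p_threshold).sum())
    rng = np.random.default_rng(seed)
    vals = matrix.values.to_numpy(dtype=float)
    copd = (groups == GROUP_COPD).to_numpy()
    counts = []
    for _ in range(n_perm):
        perm_mask = rng.permutation(copd)
        _, p, _ = _ttest_pvalues(vals, perm_mask, equal_var=equal_var)
        counts.append(int((p < p_threshold).sum()))
    return FDRReport(threshold=p_threshold, n_observed=n_observed,
                     permuted_counts=counts)
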