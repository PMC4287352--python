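"""Key-regulator aggregation and degree-distribution diagnostics.

Model-I trios are grouped by cis gene and their trans genes unioned over
all of that gene's probes, giving each regulator its set of unique
downstream targets.  A *key regulator* is a gene whose downstream count
strictly exceeds the mean plus ``k_sd`` sample standard deviations of the
counts over all regulating genes (genes with at least one downstream
target; switchable).  The mirror analysis for Model-II trios groups by
the source expression gene and unions the methylation-target genes.
A least-squares log-log fit of the degree histogram quantifies how
scale-free the downstream-count distribution is.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import RegulatorSummary


def summarize_regulators(trios: pd.DataFrame, model: str = "I") -> RegulatorSummary:
    """Aggregate classified trios into per-gene downstream sets.

    For model "I" the grouping key is the cis gene and the downstream set
    is the union of trans genes over all its probes; for model "II" the
    key is the source (trans) expression gene and the downstream set is
    the union of methylation-target (cis) genes.
    """
    if model not in ("I", "II"):
        raise ValueError("model must be 'I' or 'II'")
    cols = ["gene_id", "n_downstream", "is_key_2sd", "is_key_3sd"]
    if trios.empty:
        return RegulatorSummary(pd.DataFrame(columns=cols), {})
    sub = trios[trios["model"] == model]
    if sub.empty:
        return RegulatorSummary(pd.DataFrame(columns=cols), {})
    if model == "I":
        key, target = "cis_gene", "trans_gene"
    else:
        key, target = "trans_gene", "cis_gene"
    downstream = {g: frozenset(grp[target]) for g, grp in sub.groupby(key)}
    table = pd.DataFrame({
        "gene_id": list(downstream),
        "n_downstream": [len(v) for v in downstream.values()],
    }).sort_values("n_downstream", ascending=False).reset_index(drop=True)
    for k_sd, col in ((2.0, "is_key_2sd"), (3.0, "is_key_3sd")):
        keys = key_regulators_from_counts(table.set_index("gene_id")["n_downstream"],
                                          k_sd=k_sd)
        table[col] = table["gene_id"].isin(keys)
    return RegulatorSummary(table[cols], downstream)


def key_regulators_from_counts(counts: pd.Series, k_sd: float = 2.0) -> set:
    """Genes whose count strictly exceeds mean + k_sd * sample SD.

    ``counts`` is indexed by gene_id.  With fewer than two genes, or all
    counts equal, the key set is empty.
    """
    if len(counts) < 2:
        return set()
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1))
    threshold = mean + k_sd * sd
    return set(counts.index[counts > threshold])


def key_regulators(summary: RegulatorSummary, k_sd: float = 2.0,
                   include_zero_counts: bool = False,
                   universe: list | None = None) -> set:
    """Key regulators at the mean + k_sd * SD threshold.

    By default the mean/SD population is the genes with at least one
    downstream target.  With ``include_zero_counts`` the population is
    extended to every gene in ``universe`` (zero-count genes pull the
    threshold down).
    """
    if summary.table.empty:
        return set()
    counts = summary.table.set_index("gene_id")["n_downstream"]
    if include_zero_counts:
        if universe is None:
            raise ValueError("include_zero_counts requires a universe of genes")
        counts = counts.reindex(universe, fill_value=0)
    return key_regulators_from_counts(counts, k_sd=k_sd)


def scale_free_fit(summary: RegulatorSummary):
    """Least-squares fit of log10(#genes with count d) on log10(d).

    Uses the raw (unbinned) degree histogram over observed counts d >= 1.
    Returns (slope, r_squared); with fewer than five distinct counts the
    fit is undefined and (nan, nan) is returned.
    """
    if summary.table.empty:
        return float("nan"), float("nan")
    counts = summary.table["n_downstream"].to_numpy()
    counts = counts[counts >= 1]
    values, freqs = np.unique(counts, return_counts=True)
    if len(values) < 5:
        return float("nan"), float("nan")
    x = np.log10(values.astype(float))
    y = np.log10(freqs.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return float(slope), r2
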