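"""Core data containers shared across the pipeline.

The carriers are deliberately thin wrappers over pandas objects: a
feature-by-sample matrix with a modality tag and per-sample group labels
(:class:`OmicsMatrix`), plus small dataclasses for reports.  Annotation
tables (probes, genes, covariates, phenotypes) travel as plain DataFrames
with documented column contracts; see :mod:`methdriver.io` for the on-disk
formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MODALITY_METH = "methylation-beta"
MODALITY_EXPR = "expression"
MODALITY_ADJ = "adjusted"  # covariate-adjusted values; unbounded

GROUP_CTRL = "CTRL"
GROUP_COPD = "COPD"

#: The five COPD severity traits.  DLCO, FEV1 percent predicted and the
#: FEV1/FVC ratio decrease as severity increases; the BODE index and
#: emphysema percentage increase.
TRAITS = ["DLCO", "BODE", "FEV1pp", "FEV1_FVC", "emphysema_pct"]
TRAIT_SIGNS = {
    "DLCO": -1,
    "BODE": +1,
    "FEV1pp": -1,
    "FEV1_FVC": -1,
    "emphysema_pct": +1,
}

#: Column contract for probe annotation tables.
PROBE_COLUMNS = ["probe_id", "chrom", "pos", "cpg_island", "gene_id", "tss_distance", "tie"]
#: Column contract for gene annotation tables.
GENE_COLUMNS = ["gene_id", "chrom", "tss", "strand"]


class FormatError(ValueError):
    """Raised when an input file or table violates its contract."""


@dataclass
class OmicsMatrix:
    """Feature-by-sample real matrix with modality and group labels.

    Parameters
    ----------
    values
        DataFrame, rows = features, columns = samples.  Row and column
        indices must be unique.
    modality
        One of ``methylation-beta`` (values constrained to [0, 1]),
        ``expression`` or ``adjusted``.
    groups
        Optional per-sample label in {CTRL, COPD}, indexed by sample id.
    """

    values: pd.DataFrame
    modality: str
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate feature id: {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        vals = self.values.to_numpy()
        if vals.size and not np.issubdtype(vals.dtype, np.number):
            raise FormatError("matrix values must be numeric")
        if self.modality == MODALITY_METH and vals.size:
            bad = ~np.isnan(vals) & ((vals < 0) | (vals > 1))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise FormatError(
                    f"beta value outside [0,1] at feature {idx[i]!r}, sample {cols[j]!r}"
                )
        if self.groups is not None:
            self.groups = pd.Series(self.groups).reindex(cols)
            if self.groups.isna().any():
                missing = self.groups.index[self.groups.isna()][0]
                raise FormatError(f"sample {missing!r} has no group label")

    # -- convenience -----------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "OmicsMatrix":
        g = self.groups.loc[sample_ids] if self.groups is not None else None
        return OmicsMatrix(self.values.loc[:, sample_ids], self.modality, g)

    def subset_features(self, feature_ids) -> "OmicsMatrix":
        return OmicsMatrix(self.values.loc[feature_ids], self.modality, self.groups)

    def copy(self) -> "OmicsMatrix":
        g = None if self.groups is None else self.groups.copy()
        return OmicsMatrix(self.values.copy(), self.modality, g)


@dataclass
class FDRReport:
    """Permutation-based FDR estimate at a fixed threshold.

    FDR = mean(permuted counts) / observed count, clipped to [0, 1].
    An observed count of zero leaves the FDR undefined (``None``), never
    infinite.
    """

    threshold: float
    n_observed: int
    permuted_counts: list[int] = field(default_factory=list)

    @property
    def mean_permuted(self) -> float:
        if not self.permuted_counts:
            return float("nan")
        return float(np.mean(self.permuted_counts))

    @property
    def fdr(self) -> float | None:
        if self.n_observed == 0:
            return None
        return min(1.0, self.mean_permuted / self.n_observed)

    @property
    def undefined(self) -> bool:
        return self.n_observed == 0


@dataclass
class MatchReport:
    """Result of the iterative methylation <-> expression sample alignment.

    ``pairs`` has one row per matched pair with columns
    (meth_sample, expr_sample, score, z); ``dropped`` one row per discarded
    sample with columns (sample, axis, reason).
    """

    pairs: pd.DataFrame
    dropped: pd.DataFrame
    iterations: int

    @property
    def mapping(self) -> dict:
        return dict(zip(self.pairs["meth_sample"], self.pairs["expr_sample"]))


@dataclass
class RegulatorSummary:
    """Per-gene downstream target sets aggregated from causal trios.

    ``table`` columns: gene_id, n_downstream, is_key_2sd, is_key_3sd.
    ``downstream`` maps gene_id -> frozenset of downstream gene ids.
    """

    table: pd.DataFrame
    downstream: dict

    def downstream_of(self, gene_id: str) -> frozenset:
        return self.downstream[gene_id]


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset
    description: str = ""

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    """Upper-tail hypergeometric overlap between two gene sets."""

    query: str
    reference: str
    universe_size: int
    query_size: int
    reference_size: int
    overlap: int
    expected: float
    p: float
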