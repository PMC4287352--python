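"""Readers and writers for every file the pipeline touches.

Dialects
--------
* Matrices: tab-delimited text, first column feature id, header row of
  sample ids.  Comment lines start with ``#``; the writer records the tool
  version, the modality and the per-sample group labels there so a matrix
  round-trips losslessly.
* Probe annotation: BED-like, 0-based half-open on disk and converted to
  1-based positions internally (a width-1 interval [99,100) becomes
  position 100).  Columns: chrom, start, end, probe_id, cpg_island
  [, gene_id, tss_distance, tie].
* Gene annotation: gene_id, chrom, tss (1-based), strand.
* Covariates / phenotypes: tab-delimited with a sample_id first column;
  missing phenotype values are written as ``NA``.
* Gene sets: GMT (name, description, member genes, one set per line).
* Configs: YAML.

Readers are strict: duplicate ids, non-numeric cells, out-of-range beta
values and ragged rows are rejected with the offending location, never
silently padded.
"""

from __future__ import annotations

import io as _io
from importlib.metadata import PackageNotFoundError, version as _pkg_version

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    FormatError,
    GeneSet,
    MODALITY_METH,
    OmicsMatrix,
    TRAITS,
)

try:
    TOOL_VERSION = _pkg_version("methdriver")
except PackageNotFoundError:  # pragma: no cover - running from a source tree
    TOOL_VERSION = "unknown"

_NA = "NA"


def _header_lines(extra: dict | None = None) -> list[str]:
    lines = [f"# methdriver {TOOL_VERSION}"]
    if extra:
        for k, v in extra.items():
            lines.append(f"# {k}={v}")
    return lines


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def write_matrix(matrix: OmicsMatrix, path, params: dict | None = None) -> None:
    """Write an OmicsMatrix as TSV with a metadata header comment."""
    extra = {"modality": matrix.modality}
    if params:
        extra.update(params)
    if matrix.groups is not None:
        extra["groups"] = ",".join(f"{s}:{g}" for s, g in matrix.groups.items())
    with open(path, "w") as fh:
        for line in _header_lines(extra):
            fh.write(line + "\n")
        matrix.values.to_csv(fh, sep="\t", index_label="feature_id", float_format="%.10g")


def read_matrix(path, modality: str) -> OmicsMatrix:
    """Read a feature-by-sample TSV matrix.

    Group labels are recovered from the header comment when present.
    Rejects duplicate ids, ragged rows and non-numeric cells with the
    offending row/column named.
    """
    groups = None
    with open(path) as fh:
        text = fh.read()
    body = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if stripped.startswith("groups="):
                pairs = [p for p in stripped[len("groups="):].split(",") if p]
                groups = pd.Series(dict(p.split(":", 1) for p in pairs))
        else:
            body.append(line)
    df = pd.read_csv(_io.StringIO("\n".join(body)), sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate feature id: {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"duplicate sample id: {dup!r}")
    # ragged rows surface as missing cells after pandas parsing
    if df.isna().any().any():
        j = df.columns[df.isna().any()][0]
        i = df.index[df[j].isna()][0]
        raise FormatError(f"missing value (ragged row?) at feature {i!r}, sample {j!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        j = df.columns[bad.any()][0]
        i = df.index[bad[j]][0]
        raise FormatError(f"non-numeric cell at feature {i!r}, sample {j!r}: {df.loc[i, j]!r}")
    return OmicsMatrix(numeric, modality, groups)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def write_probe_bed(probes: pd.DataFrame, path) -> None:
    """Write probe annotation as BED-like TSV (0-based half-open intervals)."""
    with open(path, "w") as fh:
        for line in _header_lines({"coords": "BED 0-based half-open; internal = start+1"}):
            fh.write(line + "\n")
        for _, r in probes.iterrows():
            start = int(r["pos"]) - 1
            fields = [str(r["chrom"]), str(start), str(start + 1), str(r["probe_id"]),
                      "1" if bool(r["cpg_island"]) else "0"]
            if "gene_id" in probes.columns and pd.notna(r.get("gene_id")):
                fields += [str(r["gene_id"]), str(int(r["tss_distance"])),
                           "1" if bool(r.get("tie", False)) else "0"]
            fh.write("\t".join(fields) + "\n")


def read_probe_bed(path) -> pd.DataFrame:
    """Read BED-like probe annotation, applying the coordinate convention.

    Returns a DataFrame with columns probe_id, chrom, pos (1-based),
    cpg_island and, when present on disk, gene_id / tss_distance / tie.
    An empty file yields an empty annotation, not an error.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (5, 8):
                raise FormatError(f"{path}: malformed line {lineno}: expected 5 or 8 fields, "
                                  f"got {len(fields)}")
            try:
                chrom, start, end, name, island = fields[:5]
                start_i, end_i = int(start), int(end)
                if island not in ("0", "1"):
                    raise ValueError(f"island flag must be 0/1, got {island!r}")
                row = {"probe_id": name, "chrom": chrom, "pos": start_i + 1,
                       "cpg_island": island == "1", "gene_id": None,
                       "tss_distance": np.nan, "tie": False}
                if end_i != start_i + 1:
                    raise ValueError("probe intervals must have width 1")
                if len(fields) == 8:
                    row["gene_id"] = fields[5]
                    row["tss_distance"] = int(fields[6])
                    row["tie"] = fields[7] == "1"
                rows.append(row)
            except ValueError as exc:
                raise FormatError(f"{path}: malformed line {lineno}: {exc}") from exc
    cols = ["probe_id", "chrom", "pos", "cpg_island", "gene_id", "tss_distance", "tie"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols)


def write_gene_table(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for line in _header_lines({"coords": "tss is 1-based"}):
            fh.write(line + "\n")
        genes[["gene_id", "chrom", "tss", "strand"]].to_csv(fh, sep="\t", index=False)


def read_gene_table(path) -> pd.DataFrame:
    """Read the gene annotation table (gene_id, chrom, tss, strand)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty:
        return pd.DataFrame(columns=["gene_id", "chrom", "tss", "strand"])
    required = {"gene_id", "chrom", "tss", "strand"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: gene table needs columns {sorted(required)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"duplicate gene_id: {dup!r}")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise FormatError(f"{path}: invalid strand {df.loc[bad, 'strand'].iloc[0]!r}")
    return df


# ---------------------------------------------------------------------------
# covariates / phenotypes
# ---------------------------------------------------------------------------

def write_sample_table(table: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for line in _header_lines():
            fh.write(line + "\n")
        table.to_csv(fh, sep="\t", index_label="sample_id", na_rep=_NA)


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.duplicated().any():
        raise FormatError("duplicate sample_id in covariate table")
    return df


def read_phenotypes(path) -> pd.DataFrame:
    """Read the per-sample severity trait table; 'NA' marks missing values."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, na_values=[_NA])
    if df.index.duplicated().any():
        raise FormatError("duplicate sample_id in phenotype table")
    missing = [t for t in TRAITS if t not in df.columns]
    if missing:
        raise FormatError(f"phenotype table missing traits: {missing}")
    return df


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            genes = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.name}\t{gs.description}\t{genes}\n".rstrip() + "\n")


def read_gmt(path) -> list[GeneSet]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}: malformed GMT line {lineno}")
            out.append(GeneSet(fields[0], frozenset(fields[2:]), fields[1]))
    return out


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

def write_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_config(path) -> dict:
    with open(path) as fh:
        loaded = yaml.safe_load(fh)
    return loaded or {}
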