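"""End-to-end orchestration of the analysis stages.

``run_all`` executes simulate/ingest -> match -> preprocess -> associate
-> causality -> regulators -> enrich with one configuration object, a
single seed fanned out into per-stage substreams, and INFO logging of the
stage-count funnel (pairs found, trios classified, FDRs).  Every output
file carries the configuration hash in its header comment.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, causality, enrichment, io, matching, preprocess, regulators
from .datatypes import GROUP_COPD, MODALITY_EXPR, MODALITY_METH, OmicsMatrix
from .simulate import SimConfig, simulate

log = logging.getLogger("methdriver")

FILES = {
    "meth": "meth.tsv",
    "expr": "expr.tsv",
    "probes": "probes.bed",
    "genes": "genes.tsv",
    "covariates": "covariates.tsv",
    "phenotypes": "phenotypes.tsv",
    "truth_trios": "truth_trios.tsv",
    "probes_mapped": "probes_mapped.bed",
    "match_report": "match_report.tsv",
    "diff_expr": "differential_expression.tsv",
    "diff_meth": "differential_methylation.tsv",
    "cis_pairs": "cis_pairs.tsv",
    "trans_pairs": "trans_pairs.tsv",
    "trios": "causal_trios.tsv",
    "fdr": "fdr_reports.tsv",
    "regulator_summary": "regulator_summary.tsv",
    "regulator_sets": "regulator_downstream.gmt",
    "signatures": "trait_signatures.gmt",
    "meth_trait_screen": "regulator_trait_screen.tsv",
    "overlap_screen": "downstream_signature_screen.tsv",
    "degree_fit": "degree_distribution.tsv",
}


@dataclass
class PipelineConfig:
    """All stage thresholds, permutation counts and the master seed."""

    sim: SimConfig = field(default_factory=SimConfig)
    p_diff: float = 0.01
    n_perm_diff: int = 100
    p_cis: float = 0.01
    p_trans: float = 1e-5
    p_assoc: float = 1e-4
    p_indep: float = 0.01
    n_perm_pairs: int = 5
    key_sd: float = 2.0
    trait_p_expr: float = 0.01
    trait_p_meth: float = 0.05
    trait_p_overlap: float = 0.05
    n_perm_traits: int = 5
    match_p_cis: float = 0.01
    match_z_min: float = 3.0
    match_max_iter: int = 25
    require_island: bool = False
    seed: int = 1

    def validate(self) -> None:
        for name in ("p_diff", "p_cis", "p_assoc", "p_indep", "trait_p_expr",
                     "trait_p_meth", "trait_p_overlap", "match_p_cis"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0.0 <= self.p_trans <= 1.0:
            raise ValueError("p_trans must be in [0, 1]")
        for name in ("n_perm_diff", "n_perm_pairs", "n_perm_traits",
                     "match_max_iter"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["downstream_counts"] = (
            list(d["sim"]["downstream_counts"])
            if d["sim"]["downstream_counts"] is not None else None)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            for tup in ("background_count_range", "covariate_effects"):
                if tup in sim and sim[tup] is not None:
                    sim[tup] = tuple(sim[tup])
            sim = SimConfig(**sim)
        return cls(sim=sim, **d)

    @property
    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def stage_seeds(self) -> dict:
        names = ["diff", "pairs", "causality", "traits"]
        state = np.random.SeedSequence(self.seed).generate_state(len(names))
        return {n: int(s & 0x7FFFFFFF) for n, s in zip(names, state)}


def _write_fdr_table(reports: dict, path, params: dict) -> None:
    rows = []
    for name, rep in reports.items():
        rows.append({"analysis": name, "threshold": rep.threshold,
                     "n_observed": rep.n_observed,
                     "mean_permuted": rep.mean_permuted,
                     "fdr": "NA" if rep.fdr is None else f"{rep.fdr:.6g}",
                     "permuted_counts": ",".join(str(c) for c in rep.permuted_counts)})
    with open(path, "w") as fh:
        for k, v in params.items():
            fh.write(f"# {k}={v}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def run_all(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the full pipeline on a simulated cohort; return the result bundle.

    The bundle maps stage names to their in-memory results; when
    ``outdir`` is given every artifact is also written there with the
    configuration hash in its header.
    """
    config.validate()
    seeds = config.stage_seeds()
    chash = config.config_hash
    params = {"config_hash": chash, "seed": config.seed}
    out: dict = {"config_hash": chash}

    # ---- simulate -------------------------------------------------------
    meth, expr, probes, genes, covariates, phenotypes, truth = simulate(config.sim)
    out["truth"] = truth
    log.info("simulate: %d probes x %d samples meth, %d genes expr",
             meth.n_features, meth.n_samples, expr.n_features)

    # ---- probe mapping (needed by the matcher) -------------------------
    mapped = preprocess.map_probes(probes, genes)
    mapped = preprocess.filter_probes(mapped, require_island=config.require_island)
    out["annotation"] = mapped

    # ---- match ----------------------------------------------------------
    report = matching.match_samples(meth, expr, mapped, p_cis=config.match_p_cis,
                                    max_iter=config.match_max_iter,
                                    z_min=config.match_z_min)
    out["match_report"] = report
    mapping = report.mapping
    log.info("match: %d pairs in %d iterations, %d dropped",
             len(mapping), report.iterations, len(report.dropped))
    meth_m = meth.subset_samples(list(mapping.keys()))
    expr_m = expr.subset_samples(list(mapping.values()))
    # align expression columns to methylation partner order under meth ids
    expr_m = OmicsMatrix(
        pd.DataFrame(expr_m.values.to_numpy(), index=expr_m.feature_ids,
                     columns=list(mapping.keys())),
        expr_m.modality,
        pd.Series({u: expr.groups[v] for u, v in mapping.items()}))

    # ---- preprocess -----------------------------------------------------
    diff_expr = preprocess.differential(expr_m)
    diff_meth = preprocess.differential(meth_m)
    fdr_diff_expr = preprocess.permutation_fdr_differential(
        expr_m, p_threshold=config.p_diff, n_perm=config.n_perm_diff,
        seed=seeds["diff"])
    fdr_diff_meth = preprocess.permutation_fdr_differential(
        meth_m, p_threshold=config.p_diff, n_perm=config.n_perm_diff,
        seed=seeds["diff"] + 1)
    out.update(diff_expr=diff_expr, diff_meth=diff_meth,
               fdr_diff_expr=fdr_diff_expr, fdr_diff_meth=fdr_diff_meth)
    log.info("differential: %d expr / %d meth features at p<%g (FDR %s / %s)",
             fdr_diff_expr.n_observed, fdr_diff_meth.n_observed, config.p_diff,
             fdr_diff_expr.fdr, fdr_diff_meth.fdr)

    adj_meth = preprocess.adjust_covariates(meth_m, covariates)
    adj_expr = preprocess.adjust_covariates(expr_m, covariates)

    # ---- associate ------------------------------------------------------
    cis = association.find_cis_pairs(adj_meth, adj_expr, mapped, p_max=config.p_cis)
    if cis.empty or config.p_trans == 0.0:
        cand = pd.DataFrame(columns=["probe_id", "cis_gene", "gene_id", "rho",
                                     "p", "relation"])
    else:
        cand = association.find_trans_pairs(adj_meth, adj_expr, mapped, cis,
                                            p_max=config.p_trans)
    out.update(cis_pairs=cis, trans_pairs=cand)
    log.info("associate: %d cis pairs (p<%g), %d candidate trios (p<%g)",
             len(cis), config.p_cis, len(cand), config.p_trans)

    # ---- causality ------------------------------------------------------
    th = causality.CausalityThresholds(p_assoc=config.p_assoc,
                                       p_indep=config.p_indep,
                                       p_cis=config.p_cis)
    trios, fdr_models = causality.run_causality(
        cand, adj_meth, adj_expr, mapped, thresholds=th,
        scan_p_cis=config.p_cis, scan_p_trans=config.p_trans,
        n_perm=config.n_perm_pairs, seed=seeds["causality"])
    out.update(trios=trios, fdr_model_i=fdr_models["I"], fdr_model_ii=fdr_models["II"])
    n1 = int((trios["model"] == "I").sum()) if not trios.empty else 0
    n2 = int((trios["model"] == "II").sum()) if not trios.empty else 0
    log.info("causality: %d Model I (FDR %s), %d Model II (FDR %s)",
             n1, fdr_models["I"].fdr, n2, fdr_models["II"].fdr)

    # ---- regulators -----------------------------------------------------
    summary_i = regulators.summarize_regulators(trios, model="I")
    summary_ii = regulators.summarize_regulators(trios, model="II")
    keys = regulators.key_regulators(summary_i, k_sd=config.key_sd)
    slope, r2 = regulators.scale_free_fit(summary_i)
    out.update(regulator_summary=summary_i, regulator_summary_ii=summary_ii,
               key_regulators=keys, scale_free=(slope, r2))
    log.info("regulators: %d regulating genes, %d key at mean+%gSD; "
             "log-log slope %.2f (R2 %.2f)", len(summary_i.table), len(keys),
             config.key_sd, slope, r2)

    # ---- enrich ---------------------------------------------------------
    copd_samples = [s for s in expr_m.sample_ids
                    if expr_m.groups is not None and expr_m.groups[s] == GROUP_COPD]
    expr_copd = adj_expr.subset_samples(copd_samples)
    meth_copd = adj_meth.subset_samples(copd_samples)
    signatures, sig_fdr, flagged = enrichment.trait_signatures(
        expr_copd, phenotypes.loc[phenotypes.index.intersection(copd_samples)],
        p_max=config.trait_p_expr, n_perm=config.n_perm_traits,
        seed=seeds["traits"])
    meth_screen, all5_meth = enrichment.regulator_trait_screen(
        meth_copd, sorted(keys), mapped,
        phenotypes.loc[phenotypes.index.intersection(copd_samples)],
        p_max=config.trait_p_meth)
    universe = expr_m.n_features
    key_summary = regulators.RegulatorSummary(
        summary_i.table[summary_i.table["gene_id"].isin(keys)],
        {g: summary_i.downstream[g] for g in keys})
    pmat, survivors = enrichment.downstream_signature_screen(
        key_summary, signatures, universe, p_max=config.trait_p_overlap)
    out.update(trait_signatures=signatures, trait_signature_fdr=sig_fdr,
               flagged_traits=flagged, meth_trait_screen=meth_screen,
               meth_trait_all5=all5_meth, overlap_screen=pmat,
               overlap_survivors=survivors)
    log.info("enrich: signature sizes %s; %d regulators methylation-"
             "significant for all traits; %d all-trait overlap survivors",
             {t: len(s) for t, s in signatures.items()}, len(all5_meth),
             len(survivors))

    if outdir is not None:
        _write_bundle(Path(outdir), out, meth, expr, probes, genes, covariates,
                      phenotypes, mapped, params, config)
    return out


def _tsv(df: pd.DataFrame, path: Path, params: dict, index=False) -> None:
    with open(path, "w") as fh:
        for k, v in params.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def _write_bundle(outdir: Path, out, meth, expr, probes, genes, covariates,
                  phenotypes, mapped, params, config) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_config(config.to_dict(), outdir / "config.yaml")
    io.write_matrix(meth, outdir / FILES["meth"], params)
    io.write_matrix(expr, outdir / FILES["expr"], params)
    io.write_probe_bed(probes, outdir / FILES["probes"])
    io.write_probe_bed(mapped, outdir / FILES["probes_mapped"])
    io.write_gene_table(genes, outdir / FILES["genes"])
    io.write_sample_table(covariates, outdir / FILES["covariates"])
    io.write_sample_table(phenotypes, outdir / FILES["phenotypes"])
    _tsv(out["truth"].trios, outdir / FILES["truth_trios"], params)
    _tsv(out["match_report"].pairs, outdir / FILES["match_report"], params)
    _tsv(out["diff_expr"], outdir / FILES["diff_expr"], params)
    _tsv(out["diff_meth"], outdir / FILES["diff_meth"], params)
    _tsv(out["cis_pairs"], outdir / FILES["cis_pairs"], params)
    _tsv(out["trans_pairs"], outdir / FILES["trans_pairs"], params)
    _tsv(out["trios"], outdir / FILES["trios"], params)
    _write_fdr_table(
        {"differential_expression": out["fdr_diff_expr"],
         "differential_methylation": out["fdr_diff_meth"],
         "causality_model_I": out["fdr_model_i"],
         "causality_model_II": out["fdr_model_ii"],
         **{f"signature_{t}": r for t, r in out["trait_signature_fdr"].items()}},
        outdir / FILES["fdr"], params)
    _tsv(out["regulator_summary"].table, outdir / FILES["regulator_summary"], params)
    from .datatypes import GeneSet
    io.write_gmt([GeneSet(g, s, "downstream targets")
                  for g, s in sorted(out["regulator_summary"].downstream.items())],
                 outdir / FILES["regulator_sets"])
    io.write_gmt(list(out["trait_signatures"].values()), outdir / FILES["signatures"])
    _tsv(out["meth_trait_screen"], outdir / FILES["meth_trait_screen"], params)
    _tsv(out["overlap_screen"], outdir / FILES["overlap_screen"], params, index=True)
    slope, r2 = out["scale_free"]
    _tsv(pd.DataFrame([{"slope": slope, "r_squared": r2}]),
         outdir / FILES["degree_fit"], params)
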