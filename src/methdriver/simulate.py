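"""Synthetic paired methylation / expression cohorts with planted causal structure.

The generator emulates the features of a case/control lung cohort that the
downstream analysis relies on:

* promoter-probe beta values produced on the logit scale and mapped into
  [0, 1], with a CpG-island hypermethylation shift in the disease group;
* cis methylation -> expression links of both signs (a minority positive,
  mirroring the observed mix of up- and down-regulated hypermethylated
  genes);
* hub regulators whose downstream target counts follow a heavy-tailed
  (power-law-like) distribution: a few explicit hubs with large counts on
  top of a background population of low-degree regulators;
* a minority of reversed (Model II) chains in which a gene's expression
  drives another gene's promoter methylation, which in turn drives that
  gene's own cis expression;
* confounded trios (Model III) in which a latent factor drives both a
  methylation probe and a distal gene's expression with no mediation;
* additive covariate effects (age, sex, pack-years) on expression;
* five severity traits driven by the downstream genes of one designated
  hub, with the conventional signs (DLCO, FEV1pp, FEV1/FVC fall with
  severity; BODE and emphysema% rise), and optional missingness.

Every draw flows from a single :class:`numpy.random.Generator` seeded from
``SimConfig.seed``, so all outputs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    GROUP_COPD,
    GROUP_CTRL,
    MODALITY_EXPR,
    MODALITY_METH,
    OmicsMatrix,
    TRAITS,
    TRAIT_SIGNS,
)

# Fixed generative constants (documented in docs/methods.md).  Effect
# magnitudes are drawn uniformly within a band so every planted link is
# detectable at the default cohort size while slopes still vary.
_CIS_EFFECT_RANGE = (1.2, 1.5)
_TRANS_EFFECT_RANGE = (1.15, 1.35)
_MODEL2_EFFECT_RANGE = (1.5, 2.0)
_MODEL2_METH_NOISE = 0.6     # x noise_sd, residual sd of a driven methylation latent
_PROBE_NOISE = 0.2           # x noise_sd, probe-level jitter on the logit scale
_CONFOUND_EFFECT = 1.2
_GENE_SPACING = 100_000      # bp between TSSs on the synthetic chromosome
_PROBE_WINDOW = 5_000        # probes placed within +-5 kb of the TSS

_TRAIT_CENTER = {"DLCO": 70.0, "BODE": 3.0, "FEV1pp": 60.0, "FEV1_FVC": 0.55,
                 "emphysema_pct": 25.0}
_TRAIT_SCALE = {"DLCO": 15.0, "BODE": 2.0, "FEV1pp": 20.0, "FEV1_FVC": 0.12,
                "emphysema_pct": 15.0}


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return np.log(p / (1.0 - p))


@dataclass
class SimConfig:
    """Generative parameters for one synthetic cohort.

    The defaults are the study conditions used throughout the test suite:
    52 control and 100 disease samples, 500 genes with two promoter probes
    each, five hub regulators with 40-80 downstream genes apiece on top of
    a low-degree background, a 10% admixture of reversed (Model II)
    chains, and unit-variance noise.
    """

    n_ctrl: int = 52
    n_copd: int = 100
    n_genes: int = 500
    probes_per_gene: int = 2
    n_key_regulators: int = 5
    downstream_counts: list[int] | None = None   # default: evenly spaced 40..80
    n_background_regulators: int = 150
    background_count_range: tuple[int, int] = (1, 8)
    background_exponent: float = 2.5
    frac_model2: float = 0.10
    n_confounded: int = 20
    frac_cis: float = 0.7
    cis_effect_sd: float = 1.0
    trans_effect_sd: float = 1.0
    noise_sd: float = 1.0
    meth_latent_sd: float = 1.0
    frac_positive_cis: float = 0.45
    hypermeth_shift: float = 0.6
    island_fraction: float = 0.6
    covariate_effects: tuple[float, float, float] = (0.3, 0.3, 0.3)
    trait_noise_sd: float = 1.0
    trait_missing_frac: float = 0.15
    seed: int = 1

    def resolved_downstream_counts(self) -> list[int]:
        if self.downstream_counts is not None:
            return list(self.downstream_counts)
        if self.n_key_regulators == 0:
            return []
        if self.n_key_regulators == 1:
            return [60]
        lo, hi = 40, 80
        return [int(round(lo + i * (hi - lo) / (self.n_key_regulators - 1)))
                for i in range(self.n_key_regulators)]

    def validate(self) -> None:
        for name in ("n_ctrl", "n_copd", "n_genes", "n_key_regulators",
                     "n_background_regulators", "n_confounded"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.probes_per_gene < 1:
            raise ValueError("probes_per_gene must be >= 1")
        for name in ("frac_model2", "frac_cis", "frac_positive_cis",
                     "island_fraction", "trait_missing_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("cis_effect_sd", "trans_effect_sd", "noise_sd",
                     "meth_latent_sd", "trait_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        counts = self.resolved_downstream_counts()
        if len(counts) != self.n_key_regulators:
            raise ValueError("downstream_counts length must equal n_key_regulators")
        if any(c < 0 for c in counts):
            raise ValueError("downstream_counts must be >= 0")
        if sum(counts) > self.n_genes - self.n_key_regulators:
            raise ValueError(
                "downstream_counts sum exceeds n_genes - n_key_regulators")


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort.

    ``trios`` has one row per planted (probe, cis gene, trans gene) trio
    with a ``model`` label in {I, II, III}; the labels partition the list.
    """

    trios: pd.DataFrame
    key_regulators: list[str]
    background_regulators: list[str]
    model2_sources: list[str]
    trait_drivers: dict
    cis_links: pd.DataFrame            # gene_id, slope
    sample_pairing: dict               # meth sample -> expr sample (identity)
    downstream: dict = field(default_factory=dict)   # model-I regulator -> set

    def __post_init__(self):
        if not self.trios.empty:
            models = set(self.trios["model"])
            if not models.issubset({"I", "II", "III"}):
                raise ValueError(f"unknown trio model labels: {models}")
        if not self.downstream:
            m1 = self.trios[self.trios["model"] == "I"]
            self.downstream = {
                g: set(sub["trans_gene"]) for g, sub in m1.groupby("cis_gene")
            }


def simulate(config: SimConfig):
    """Generate one synthetic cohort.

    Returns
    -------
    (meth, expr, probes, genes, covariates, phenotypes, truth)
        ``meth`` and ``expr`` are :class:`OmicsMatrix` (probes x samples,
        genes x samples); ``probes`` / ``genes`` are annotation frames;
        ``covariates`` and ``phenotypes`` are per-sample tables;
        ``truth`` is the :class:`GroundTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_s = config.n_ctrl + config.n_copd
    n_g = config.n_genes

    sample_ids = ([f"CTRL_{i+1:03d}" for i in range(config.n_ctrl)]
                  + [f"COPD_{i+1:03d}" for i in range(config.n_copd)])
    groups = pd.Series([GROUP_CTRL] * config.n_ctrl + [GROUP_COPD] * config.n_copd,
                       index=sample_ids, name="group")
    is_copd = (groups == GROUP_COPD).to_numpy().astype(float)

    gene_ids = [f"gene_{i+1:04d}" for i in range(n_g)]
    tss = _GENE_SPACING * (np.arange(n_g) + 1)
    strand = rng.choice(["+", "-"], size=n_g)
    island = rng.random(n_g) < config.island_fraction
    genes = pd.DataFrame({"gene_id": gene_ids, "chrom": "chr1", "tss": tss,
                          "strand": strand})

    # ---- covariates ----------------------------------------------------
    age = rng.normal(65.0, 8.0, size=n_s)
    sex = rng.choice(["F", "M"], size=n_s)
    pack_years = np.abs(rng.normal(35.0, 15.0, size=n_s))
    covariates = pd.DataFrame({"age": age, "sex": sex, "pack_years": pack_years},
                              index=pd.Index(sample_ids, name="sample_id"))
    Z = np.vstack([
        (age - age.mean()) / age.std(),
        (sex == "M").astype(float) - (sex == "M").mean(),
        (pack_years - pack_years.mean()) / pack_years.std(),
    ])  # (3, n_s)

    # ---- role assignment ----------------------------------------------
    gene_idx = np.arange(n_g)
    hub_counts = config.resolved_downstream_counts()
    hubs = rng.choice(gene_idx, size=config.n_key_regulators, replace=False)
    non_hub = np.setdiff1d(gene_idx, hubs)
    total_hub_targets = sum(hub_counts)
    hub_target_pool = rng.choice(non_hub, size=total_hub_targets, replace=False)
    hub_targets: dict[int, np.ndarray] = {}
    off = 0
    for h, c in zip(hubs, hub_counts):
        hub_targets[h] = hub_target_pool[off:off + c]
        off += c

    bg_pool = np.setdiff1d(non_hub, hub_target_pool)
    n_bg = min(config.n_background_regulators, len(bg_pool))
    bg_regs = rng.choice(bg_pool, size=n_bg, replace=False) if n_bg else np.array([], int)
    lo_d, hi_d = config.background_count_range
    degrees = np.arange(lo_d, hi_d + 1)
    pdeg = degrees.astype(float) ** (-config.background_exponent)
    pdeg /= pdeg.sum()
    bg_counts = rng.choice(degrees, size=n_bg, p=pdeg) if n_bg else np.array([], int)
    # regulators are never targets of another chain (chained regulators
    # would compound variance and dilute every planted association), and
    # each gene takes at most one background parent: targets are drawn
    # globally without replacement while the pool lasts
    bg_targets: dict[int, np.ndarray] = {}
    bg_target_pool = np.setdiff1d(gene_idx, np.concatenate([hubs, bg_regs]))
    demand = int(bg_counts.sum())
    if demand <= len(bg_target_pool):
        drawn = rng.choice(bg_target_pool, size=demand, replace=False)
    else:
        drawn = np.concatenate([
            rng.permutation(bg_target_pool),
            rng.choice(bg_target_pool, size=demand - len(bg_target_pool)),
        ])
    off2 = 0
    for r, c in zip(bg_regs, bg_counts):
        bg_targets[r] = drawn[off2:off2 + c]
        off2 += c

    n_chains = total_hub_targets + int(bg_counts.sum())
    n_m2 = int(round(config.frac_model2 * n_chains))
    used = set(hubs) | set(hub_target_pool) | set(bg_regs)
    for t in bg_targets.values():
        used |= set(t)
    src_pool = np.array(sorted(set(gene_idx) - used), int)
    m2_sources = np.array([], int)
    m2_targets: dict[int, np.ndarray] = {}
    if n_m2 > 0:
        n_src = max(1, min(len(src_pool), n_m2 // 12 + 1))
        if n_src == 0:
            raise ValueError("no genes left to serve as Model-II sources; "
                             "reduce planted structure or raise n_genes")
        m2_sources = rng.choice(src_pool, size=n_src, replace=False)
        tgt_pool = np.setdiff1d(gene_idx,
                                np.concatenate([hubs, bg_regs, m2_sources]))
        chosen = rng.choice(tgt_pool, size=min(n_m2, len(tgt_pool)), replace=False)
        splits = np.array_split(chosen, n_src)
        m2_targets = {s: t for s, t in zip(m2_sources, splits)}
    m2_target_all = (np.concatenate(list(m2_targets.values()))
                     if m2_targets else np.array([], int))

    conf_A = np.array([], int)
    conf_B = np.array([], int)
    if config.n_confounded > 0:
        pool = np.setdiff1d(gene_idx, np.concatenate([hubs, m2_target_all]))
        k = min(config.n_confounded, len(pool) // 2)
        picked = rng.choice(pool, size=2 * k, replace=False)
        conf_A, conf_B = picked[:k], picked[k:]

    # ---- cis links ------------------------------------------------------
    must_cis = set(hubs) | set(bg_regs) | set(m2_target_all) | set(conf_A)
    has_cis = rng.random(n_g) < config.frac_cis
    has_cis[list(must_cis)] = True
    sign = np.where(rng.random(n_g) < config.frac_positive_cis, 1.0, -1.0)
    b = sign * rng.uniform(*_CIS_EFFECT_RANGE, size=n_g) * config.cis_effect_sd
    b[~has_cis] = 0.0

    # ---- methylation latent --------------------------------------------
    mu = rng.normal(0.0, 1.0, size=n_g)
    eta = rng.normal(0.0, config.meth_latent_sd, size=(n_g, n_s))
    L = mu[:, None] + config.hypermeth_shift * island[:, None] * is_copd[None, :] + eta

    X_conf = rng.normal(0.0, 1.0, size=(len(conf_A), n_s))
    for k, a in enumerate(conf_A):
        L[a] += _CONFOUND_EFFECT * X_conf[k]

    # ---- expression -----------------------------------------------------
    c_cov = rng.normal(0.0, 1.0, size=(n_g, 3)) * np.asarray(config.covariate_effects)
    e_noise = rng.normal(0.0, config.noise_sd, size=(n_g, n_s))
    alpha = rng.normal(0.0, 1.0, size=n_g)

    def cis_expression(rows: np.ndarray) -> np.ndarray:
        return (alpha[rows, None] + b[rows, None] * L[rows]
                + c_cov[rows] @ Z + e_noise[rows])

    # Model-II chains: source expression drives the target's methylation
    # latent, then the target's own cis expression follows from it.  The
    # sources' expression is purely cis-driven, so it can be computed
    # before the final expression pass and comes out identical there.
    m2_kappa: dict[tuple[int, int], float] = {}
    if m2_targets:
        E_src = cis_expression(m2_sources)
        src_std = (E_src - E_src.mean(axis=1, keepdims=True))
        sd = src_std.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        src_std /= sd
        for si, s in enumerate(m2_sources):
            for v in m2_targets[s]:
                kappa = (rng.choice([-1.0, 1.0])
                         * rng.uniform(*_MODEL2_EFFECT_RANGE) * config.trans_effect_sd)
                m2_kappa[(s, v)] = kappa
                resid = rng.normal(0.0, _MODEL2_METH_NOISE * config.noise_sd, size=n_s)
                L[v] = (mu[v] + config.hypermeth_shift * island[v] * is_copd
                        + kappa * src_std[si] + resid)

    E = cis_expression(gene_idx)

    trans_gamma: dict[tuple[int, int], float] = {}
    for reg, targets in list(hub_targets.items()) + list(bg_targets.items()):
        for t in targets:
            gamma = (rng.choice([-1.0, 1.0])
                     * rng.uniform(*_TRANS_EFFECT_RANGE) * config.trans_effect_sd)
            trans_gamma[(reg, t)] = gamma
            E[t] = E[t] + gamma * E[reg]
    for k, bgene in enumerate(conf_B):
        E[bgene] = E[bgene] + _CONFOUND_EFFECT * X_conf[k]

    expr = OmicsMatrix(pd.DataFrame(E, index=gene_ids, columns=sample_ids),
                       MODALITY_EXPR, groups.copy())

    # ---- probes ---------------------------------------------------------
    n_p = config.probes_per_gene
    probe_rows = []
    beta_rows = np.empty((n_g * n_p, n_s))
    offsets = np.linspace(-_PROBE_WINDOW, _PROBE_WINDOW, n_p + 2)[1:-1]
    for gi in range(n_g):
        for pj in range(n_p):
            pid = f"probe_{gi+1:04d}_{pj+1}"
            pos = int(tss[gi] + round(offsets[pj]))
            probe_rows.append({"probe_id": pid, "chrom": "chr1", "pos": pos,
                               "cpg_island": bool(island[gi]),
                               "gene_id": None, "tss_distance": np.nan, "tie": False})
            jitter = rng.normal(0.0, _PROBE_NOISE * config.noise_sd, size=n_s)
            beta_rows[gi * n_p + pj] = _logistic(L[gi] + jitter)
    probes = pd.DataFrame(probe_rows)
    meth = OmicsMatrix(
        pd.DataFrame(beta_rows, index=[r["probe_id"] for r in probe_rows],
                     columns=sample_ids),
        MODALITY_METH, groups.copy())

    # ---- traits ---------------------------------------------------------
    driver = int(hubs[0]) if len(hubs) else None
    phen = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"),
                        columns=TRAITS, dtype=float)
    if driver is not None and len(hub_targets.get(driver, [])) > 0:
        tgt = hub_targets[driver]
        w = np.array([np.sign(trans_gamma[(driver, t)]) for t in tgt])
        w = w * rng.uniform(0.5, 1.0, size=len(tgt))
        raw = w @ E[tgt]
        z = (raw - raw.mean()) / raw.std()
    else:
        z = np.zeros(n_s)
    for trait in TRAITS:
        val = TRAIT_SIGNS[trait] * z + rng.normal(0.0, config.trait_noise_sd, size=n_s)
        phen[trait] = _TRAIT_CENTER[trait] + _TRAIT_SCALE[trait] * val
        if config.trait_missing_frac > 0:
            drop = rng.random(n_s) < config.trait_missing_frac
            phen.loc[drop, trait] = np.nan

    # ---- ground truth ---------------------------------------------------
    trio_rows = []
    probe_of = lambda gi, pj: f"probe_{gi+1:04d}_{pj+1}"  # noqa: E731
    for (reg, t) in trans_gamma:
        for pj in range(n_p):
            trio_rows.append({"probe_id": probe_of(reg, pj),
                              "cis_gene": gene_ids[reg],
                              "trans_gene": gene_ids[t], "model": "I"})
    for (s, v) in m2_kappa:
        for pj in range(n_p):
            trio_rows.append({"probe_id": probe_of(v, pj),
                              "cis_gene": gene_ids[v],
                              "trans_gene": gene_ids[s], "model": "II"})
    for a, bgene in zip(conf_A, conf_B):
        for pj in range(n_p):
            trio_rows.append({"probe_id": probe_of(a, pj),
                              "cis_gene": gene_ids[a],
                              "trans_gene": gene_ids[bgene], "model": "III"})
    trios = pd.DataFrame(trio_rows,
                         columns=["probe_id", "cis_gene", "trans_gene", "model"])
    cis_links = pd.DataFrame({"gene_id": gene_ids, "slope": b})
    cis_links = cis_links[cis_links["slope"] != 0.0].reset_index(drop=True)
    truth = GroundTruth(
        trios=trios,
        key_regulators=[gene_ids[h] for h in hubs],
        background_regulators=[gene_ids[r] for r in bg_regs],
        model2_sources=[gene_ids[s] for s in m2_sources],
        trait_drivers={t: (gene_ids[driver] if driver is not None else None)
                       for t in TRAITS},
        cis_links=cis_links,
        sample_pairing={s: s for s in sample_ids},
    )
    return meth, expr, probes, genes, covariates, phen, truth


def shuffle_samples(expr: OmicsMatrix, n_swaps: int, seed: int = 0):
    """Permute ``n_swaps`` sample labels of an expression matrix.

    The chosen labels are deranged with a cyclic shift, so exactly
    ``n_swaps`` labels end up attached to another sample's data.  Returns
    the relabelled matrix and the true pairing map
    (original sample -> label its data now carries).

    ``n_swaps`` must be 0 or >= 2 (a single sample cannot be deranged) and
    at most the number of samples.
    """
    n = expr.n_samples
    if n_swaps > n:
        raise ValueError(f"n_swaps ({n_swaps}) exceeds number of samples ({n})")
    if n_swaps == 1:
        raise ValueError("n_swaps=1 cannot produce a derangement; use 0 or >= 2")
    pairing = {s: s for s in expr.sample_ids}
    if n_swaps == 0:
        return expr.copy(), pairing
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=n_swaps, replace=False)
    rolled = np.roll(chosen, 1)
    perm = np.arange(n)
    perm[chosen] = rolled            # column at position chosen[i] takes data of rolled[i]
    values = expr.values.iloc[:, perm]
    values.columns = expr.sample_ids  # labels keep their order; data moved
    cols = list(expr.sample_ids)
    for i, j in zip(chosen, rolled):
        pairing[cols[j]] = cols[i]   # data of sample j now sits under label i
    groups = expr.groups.copy() if expr.groups is not None else None
    return OmicsMatrix(values, expr.modality, groups), pairing
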