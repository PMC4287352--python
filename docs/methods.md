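# Methods

`methdriver` implements an integrative analysis of paired DNA-methylation
and gene-expression profiles from a case/control cohort.  Its goal is to
identify *key regulator* genes: genes whose promoter methylation
cis-regulates their own expression and, through it, trans-regulates the
expression of many downstream genes — and then to single out the
regulators whose downstream programs track disease-severity phenotypes.

## The causal model

For a promoter methylation level M of gene *g*, the expression C of *g*
(the *cis* gene) and the expression T of a distal gene (the *trans*
gene), three generating structures are distinguished:

* **Model I** — M → C → T: methylation drives cis expression, which
  drives the trans gene.
* **Model II** — T → M → C: the trans gene's expression drives the cis
  gene's promoter methylation, which drives the cis gene's expression.
* **Model III** — a latent factor X drives M and T independently; no
  mediation through C.

The decision procedure chains marginal association tests with a
residual-based conditional-independence test.  All associations are
Spearman rank correlations (two-sided p from the t approximation
t = ρ√((n−2)/(1−ρ²)) on n−2 df); only the mediation regression is
ordinary least squares on the raw values.

A trio is called **Model I** when

1. p(M, C) < `p_cis` (default 0.01) — the cis anchor,
2. p(C, T) < `p_assoc` (default 10⁻⁴) — the mediated chain, and
3. Spearman p of (M, residuals of T regressed on C) > `p_indep`
   (default 0.01) — M carries no information about T once the mediator
   is removed.

**Model II** mirrors the chain with roles reversed: p(T, M) < `p_assoc`
and Spearman p of (T, residuals of C regressed on M) > `p_indep`.
Zero-variance residuals (perfect mediation) count as fully independent
(p = 1).  A trio may satisfy neither test (`none`).  When it satisfies
both — which happens when the cis link is so tight that C is a nearly
noiseless proxy of M and the two directions become statistically
indistinguishable — the direction with the larger conditional-
independence p (stronger mediation evidence) wins and the trio is
flagged `ambiguous`.  This tie rule is a design choice of this package.

Statistical caveat: the test identifies *statistical* causal structure.
A Model II call also arises when T merely co-varies with whatever drives
M (confounding upstream of M); distinguishing these requires
intervention, not observational data.

## The analysis funnel

1. **Sample matching.**  Methylation and expression samples are aligned
   by an iterative self-consistent procedure: under the current pairing,
   cis (probe, gene) pairs at Spearman p < 0.01 are collected; every
   (methylation sample, expression sample) couple is scored by the
   Spearman correlation — across those pairs — of the two profiles after
   each feature is rank-transformed across its own samples and oriented
   by the sign of its cis correlation (promoter methylation correlates
   with expression in either direction, so unsigned profiles carry no
   signal).  A couple is accepted when it is the mutual best of its row
   and column and its score exceeds the row mean by ≥ 3 row standard
   deviations; the pairing is updated and the loop repeats until stable
   (at most 25 iterations).  Exact score ties (e.g. duplicated columns)
   are unresolvable and those samples are dropped, never arbitrarily
   assigned.  The procedure is deterministic and invariant to sample
   order.
2. **Probe→gene mapping.**  Each probe maps to the gene with the nearest
   transcription start site when the distance is strictly below 10 kb;
   distances are strand-signed (positive = downstream of the TSS).
   Equidistant ties go to the lexicographically smaller gene id and are
   flagged.
3. **Covariate adjustment.**  Each feature is regressed on the covariate
   design (age, dummy-coded sex, pack-years); the analysis value is the
   feature mean plus the residuals, so means are preserved exactly and
   the operation is idempotent.  Collinear design columns are dropped
   with a warning.
4. **Differential analysis.**  Two-sample Student t-test (pooled
   variance; Welch behind `equal_var=False`) per feature between the
   disease and control groups, two-sided.  The false discovery rate at a
   p threshold is estimated by permuting group labels (sizes preserved)
   100 times: FDR = mean permuted significant count / observed count,
   clipped to [0, 1]; zero observed leaves the FDR undefined rather than
   infinite.
5. **Association.**  Cis pairs: one Spearman test per (probe, assigned
   gene), retained at p < 0.01.  Trans pairs: only cis-anchored probes
   are scanned against all other genes (a gene is never its own trans
   partner), retained at p < 10⁻⁵ by default.  The trans threshold is
   deliberately configurable; the causality stage re-tightens the C–T
   association to 10⁻⁴, so final calls are robust to it.  Pair FDRs come
   from 5 permutations of the sample columns of the whole expression
   matrix (methylation untouched), re-running detection from scratch each
   time.
6. **Causality.**  Every candidate trio is classified as above; per-model
   FDRs again use 5 whole-matrix expression permutations with candidates
   re-derived on the permuted data.
7. **Regulators.**  Model-I trios are grouped by cis gene, trans genes
   unioned over all of the gene's probes.  A key regulator has a
   downstream count strictly greater than mean + 2·SD (sample SD, n−1)
   of the counts over all genes with ≥ 1 downstream target; the
   mean+3·SD variant is also reported.  Zero-count genes are excluded
   from the threshold population by default (they would drag the
   threshold toward zero and the degree distribution is defined over
   regulating genes); `include_zero_counts` switches this.  The
   downstream-count distribution is summarised by a least-squares line on
   the raw (unbinned) log₁₀ degree histogram; a near-linear fit with
   negative slope is the scale-free signature (few hubs, many low-degree
   regulators).  The mirror analysis groups Model-II trios by source
   expression gene.
8. **Severity screens.**  Five lung-function traits are screened
   (DLCO, BODE index, FEV1 percent predicted, FEV1/FVC ratio, emphysema
   percentage; the first, third and fourth fall with severity, the
   second and fifth rise).  (a) Trait expression signatures: genes whose
   expression correlates with a trait at p < 0.01 over samples with a
   non-missing value (pairwise deletion, minimum 10), FDR from 5
   expression permutations.  (b) Regulator methylation screen: mean
   promoter beta of each key regulator against each trait at p < 0.05,
   reporting regulators significant for all five.  (c) Downstream
   overlap: each regulator's downstream set against each signature by
   the upper-tail hypergeometric test (identical to one-sided Fisher's
   exact; the equivalence is asserted in tests), reporting regulators
   significant for all five.  The overlap universe defaults to the genes
   in the expression matrix and is configurable.  Generic gene-set
   collection enrichment reuses the same test, skipping sets larger than
   1500 genes as non-specific.

## The synthetic cohort

No real cohort ships with the package; a generator with planted ground
truth stands in so that every stage can be scored against known
structure.  Defaults define the study conditions used by the test suite:
52 control + 100 disease samples, 500 genes with 2 promoter probes each,
5 hub regulators with 40–80 downstream genes, 150 low-degree background
regulators (counts 1–8, discrete power law with exponent 2.5), a 10%
admixture of reversed (Model II) chains, 20 confounded (Model III)
trios, and seed 1.

Generative form, per sample *s* and gene *g*:

* Methylation latent L₉ₛ = μ₉ + shift·island₉·disease(s) + η, with
  η ~ N(0, 1) and shift = 0.6 on the logit scale (CpG-island probes are
  hypermethylated in the disease group); probe beta values are
  inverse-logit(L + probe jitter), hence always in [0, 1].
* Cis expression C₉ = α₉ + b₉·L₉ + covariate terms + N(0, noise_sd),
  with |b| ~ U(1.2, 1.5)·`cis_effect_sd` and sign(b) positive with
  probability 0.45 (promoter methylation activates a minority of genes,
  mirroring the mixed direction seen in real cohorts); 70% of genes
  carry a cis link.
* Model-I targets add γ·C_regulator with |γ| ~ U(1.15, 1.35)·
  `trans_effect_sd`.  Regulators are never targets of another chain,
  and each gene takes at most one background parent: chained or heavily
  shared targets would compound variance and dilute every planted
  association below detectability at n ≈ 150.  The two effect bands were
  chosen from the variance budget (corr_cis = b/√(b²+1+V_trans) must
  exceed 0.3 for ≥ 90% of links while corr(M, T) must clear p < 10⁻⁵),
  not fitted to data.
* Model-II chains override a target's methylation latent with
  κ·standardised source expression (|κ| ~ U(1.5, 2.0)) plus a reduced
  residual (0.6·noise_sd); the target's cis expression then follows from
  its methylation as usual.
* Confounded trios add a shared latent (weight 1.2) to one gene's
  methylation and another gene's expression.
* Covariates (age, sex, pack-years) act additively on expression with
  per-gene N(0, 0.3) coefficients; methylation carries no covariate
  effect, so the conditional-independence property of planted Model-I
  trios holds exactly on covariate-adjusted data (the pipeline order).
  On raw data, covariates shared by C and T leak a small M–residual
  association at large n — one reason adjustment precedes association.
* Traits are a signed standardised weighted sum of one designated hub's
  downstream expressions plus N(0, 1) noise, mapped to plausible
  clinical units; 15% of values are missing at random, mirroring
  incomplete clinical measurement.

What the generator does **not** emulate: array probe-level noise models,
batch effects, realistic genomic coordinates (one synthetic chromosome,
genes every 100 kb, probes within ±5 kb of the TSS, 60% of promoters
island-flagged), linkage between covariates and disease status, or the
demographic structure of a real cohort.  Passing tests therefore
demonstrate correctness of the procedures and their calibration under a
faithful generative model — not performance on real arrays.

## Numerical choices and edge cases

* Spearman: average-rank ties; |ρ| = 1 ⇒ p = 0; zero variance ⇒
  (ρ = 0, p = 1); fewer than 5 complete pairs ⇒ flagged, p = 1.
  The t approximation is validated against a 100,000-draw permutation
  oracle (agreement within a factor of 2 for p > 0.001 at n = 30).
* Permutations preserve group sizes (labels permuted, not values) and
  are seeded; a single master seed fans out to per-stage substreams, so
  identical configurations produce byte-identical outputs.
* Matrices on disk are TSV with a header comment carrying the tool
  version, modality, group labels and configuration hash; BED intervals
  are 0-based half-open on disk, 1-based closed internally.
* Readers are strict: duplicate ids, ragged rows, non-numeric cells and
  out-of-range beta values are rejected with the offending location.
* Problem sizes: the default cohort (1,000 probes × 152 samples,
  500 genes) runs the full pipeline in a few seconds on one core; the
  conditional-independence large-sample property is checked at n = 2,000
  on a reduced gene panel.

## Known limitations

* When the cis correlation approaches 1, Models I and II are inherently
  confounded; the tie rule resolves these by mediation strength and
  flags them, but the direction call is then weakly supported.
* The permutation FDR with 5 permutations is a coarse estimator; its
  variance is visible for small observed counts (an observed count of 0
  leaves it undefined by design).
* The matcher needs a genuine cis signal; on data with none it aborts
  with a diagnostic rather than returning an arbitrary pairing.
* The generic gene-set enrichment assumes the user supplies collections
  already mapped to the analysis gene universe.
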