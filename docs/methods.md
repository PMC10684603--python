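# Methods

## The problem

Acute graft-versus-host disease (aGVHD) after allogeneic hematopoietic cell
transplantation (HCT) is staged clinically in three target organs — skin,
liver and gastrointestinal (GI) tract — each on an ordinal 0–4 scale, and
the triple is summarized into an overall severity grade. Several rule-based
grading systems coexist (MAGIC, the 1994 Keystone Consensus, the IBMTR
severity index, the Minnesota system) and disagree on parts of the
125-phenotype space (5³ stage combinations; (0,0,0) denotes absence of
disease). This package implements those rule systems alongside data-driven
alternatives — a principal-component severity index and two clustering
gradings — plus the survival machinery needed to compare them on a cohort.

## PC1 severity grading

Patients are points p = (skin, liver, gi) ∈ {0..4}³. PCA is applied to the
raw (mean-centered but unstandardized) stage triples; the three organs
share one ordinal scale, so no per-organ rescaling is warranted. The
severity index of a patient is the affine projection onto the leading
eigenvector c₁ of the sample covariance:

    s' = (p − p₀) · c₁ + s₀

with p₀ the training mean and s₀ = 0. Eigenvector signs are arbitrary; the
sign is fixed so the largest-magnitude loading is positive, which on
realistic cohorts makes the index increase with GI severity.

**Nonnegative loadings.** A severity index must be monotone in every organ
stage, i.e. all loadings nonnegative. When skin and GI involvement are
weakly negatively associated, the leading eigenvector picks up a small
negative skin component even though it is overwhelmingly a GI/liver
severity axis. `fit_pc1` therefore clamps negative loadings of magnitude
≤ `loading_tolerance` (default 0.25, ≈ 6% of variance weight) to zero,
renormalizes, and warns; a negative loading beyond the tolerance means the
leading component is a contrast between organs rather than a severity
axis, and the fit fails with a diagnostic. On the default synthetic
conditions the clamped loadings come out near (0, 0.27, 0.96) — skin
essentially ignored, GI dominant — mirroring the near-zero skin weight
such indices exhibit on real aGVHD cohorts.

**Staging.** The continuous index is discretized with the affine map

    stage = round(k · (s' − s'_min)) + 1,   k = (n_stages − 1) / (s'_max − s'_min)

where the index range is computed over the 124 aGVHD phenotypes (never the
observed cohort, so staging is cohort-independent once loadings are
fixed). This pins the least severe phenotype to stage 1 and (4,4,4) to
n_stages for any fitted loadings; when the index span happens to equal
(n_stages − 1)/2 it reduces to the classical "double and round" form.
Rounding is half-away-from-zero to avoid platform-dependent banker's
rounding at .5 ties. n_stages is 12 (default) or 6 (the coarse variant).
(0,0,0) maps to stage 0, flagged as absence of disease. Stages 1–12
consolidate into four grades by blocks of three (1–3 → I, …, 10–12 → IV).

**Internal validation.** `bootstrap_validate` refits the PCA on repeated
subsamples (default 500 resamples of 2/3 of the cohort, drawn without
replacement) and reports mean/min/max per eigenvalue. Degenerate
resamples with a constant organ are redrawn and counted.

## Cluster gradings

Ward (minimum increase of sum of squares) agglomerative clustering and
K-means both run on patients' raw integer stage triples — duplicated
phenotypes carry their patient mass, and the geometry matches the PCA
module. The tree/partition is cut at k = 4 by default for comparability
with conventional grading (threshold cutting is available for the
hierarchical tree; a fixed distance threshold is cohort-scale-dependent,
so the count-based cut is the default). K-means takes the best of
`n_init = 50` k-means++ runs by SSD and is deterministic given its seed;
`select_k` reports SSD (elbow = maximal second difference) and the
silhouette coefficient over a k range.

Clusters carry no intrinsic severity, so they are ranked by outcome:
descending Kaplan-Meier overall survival at 12 months (the package's
evaluation horizon), ties broken by ascending mean stage sum. Rank 1 =
grade I. A cluster with no information at the horizon falls back to mean
observed follow-up, logged.

Phenotypes unseen in training are handled by policy: `nearest` assigns to
the nearest centroid (K-means) or to the cluster whose Ward objective
increases least, n_c/(n_c+1)·d² (hierarchical); `omit` excludes the
patient from analyses, mirroring external validation practice. Distance
ties break toward the less severe grade.

## Survival machinery

* **OS**: Kaplan-Meier with Greenwood 95% bands on the log(−log) scale;
  unweighted K-sample log-rank test.
* **Competing risks**: nonrelapse mortality (NRM) and relapse are
  competing events (0 = censored, 1 = NRM, 2 = relapse). Cumulative
  incidence uses the Aalen-Johansen estimator. Gray's K-sample test
  (ρ = 0) is implemented in score form on the subdistribution: subjects
  failing from the competing cause remain in the risk set with
  inverse-probability-of-censoring weights G(t⁻)/G(Tᵢ⁻) (the Fine-Gray
  risk-set construction, with a pooled censoring Kaplan-Meier), and the
  usual log-rank O−E/variance accumulation runs on the weighted risk
  sets against a χ²(K−1) reference. With no censoring this is exactly the
  log-rank test on subdistribution times. Calibration is verified by a
  500-replicate null simulation in the test suite, and the statistic was
  checked against an independent reference implementation during
  development (agreement to ~1% on a 300-patient fixture).
* **Cox regression** maximizes the partial likelihood with the Efron tie
  correction (Breslow available; the two coincide on tie-free data).
  Counting-process (start-stop) rows support time-dependent covariates
  such as a grade entering at aGVHD onset — the cause-specific Cox
  substitute for "time-dependent Fine-Gray", which is methodologically
  contested and deliberately not offered.
* **Fine-Gray regression** (baseline covariates only) expands the data
  into weighted counting-process intervals — competing-event subjects stay
  at risk past their failure time with weight G(t⁻)/G(Tᵢ⁻), split at the
  event-of-interest times — and fits a weighted time-varying Cox model.
  Standard errors are model-based (not robust); coefficient estimates
  matched an independent reference implementation to 5 decimals during
  development. With no competing events present the expansion is trivial
  and the fit reduces to cause-specific Cox.
* **Grading AIC**: AIC = −2 log L + 2 p′ with L the Efron partial
  likelihood of a Cox model on dummy-encoded grades and p′ the *number of
  grade categories*, taken literally; the conventional categories-minus-one
  parameter count is available behind `p_convention="parameters"` and
  shifts every system by the same constant within fixed-G comparisons.
  Smaller is better.
* **Harrell's concordance**: concordant/(concordant+discordant) over
  censoring-usable pairs, score ties counted ½.
* **Time-dependent AUROC**: cumulative-case/dynamic-control AUC at a
  horizon with Kaplan-Meier IPCW; 95% CI from 200 seeded bootstrap
  resamples. For NRM the cause-specific event is used (relapse treated as
  censoring). Two-sided p-values throughout; no multiple-testing
  correction; confidence level fixed at 95%.

## Agreement and repertoire analyses

Cohen's kappa is unweighted ((p_o − p_e)/(1 − p_e)) over the union of both
category sets; two identical constant labelings have κ = 1, two different
constant labelings κ = 0 with a warning (p_e = 1). The kappa matrix is
computed pairwise-complete: patients ungradable in either system of a pair
(clustering omit policy) are dropped for that pair only. Repertoire tables
count distinct phenotypes and patient proportions per grade; within-grade
proportions sum to 1 and per-phenotype counts reconstruct the cohort's
phenotype tally exactly. The redistribution analysis partitions the
patients at a conventional grade (e.g. MAGIC III) into those a data-driven
system downgrades (grade ≤ threshold) and the remainder, then compares
subgroup OS (KM + log-rank) and NRM (CIF + Gray).

## Synthetic cohorts

Real aGVHD cohorts are access-restricted, so a seeded generator stands in
with the dependence and outcome structure the analyses assume.

* **Stages** come from a Gaussian copula thresholded to per-organ
  marginals. Default marginals (stage 0..4):
  skin (0.32, 0.38, 0.22, 0.06, 0.02), liver (0.62, 0.16, 0.11, 0.07,
  0.04), GI (0.22, 0.20, 0.18, 0.18, 0.22) — skin involvement common but
  mostly mild, liver mostly absent, GI spanning the range. Under these
  conditions the leading principal component explains ≈ 0.5 of the stage
  variance and is GI-dominated, the structure the data-driven grading
  targets. Pairwise Spearman targets default to liver-GI +0.20,
  skin-GI −0.10, skin-liver 0.0; the latent correlation for each pair is
  calibrated by bisection against the population midrank correlation of
  the thresholded pair (computed from bivariate-normal cell
  probabilities), so empirical Spearman matches the target at large n.
  Infeasible marginal/correlation combinations fail with the nearest
  feasible value named.
* **Conditioning.** `agvhd_only` (default on, matching cohorts of
  diagnosed patients) resamples away (0,0,0) draws. Excluding that cell
  perturbs the law: marginals shift slightly and rank correlations move
  (e.g. liver-GI 0.20 → ≈ 0.14, skin-GI −0.10 → ≈ −0.21 at the defaults).
  Calibration targets the *unconditional* law, and the recovery tests
  check that law; the conditional shift is a property of the study
  conditions, not an error. `include_full_repertoire` deterministically
  seats one patient on each of the 124 aGVHD phenotypes before random
  filling — a coverage device for exhaustive calibration and repertoire
  analyses.
* **Outcomes** are competing exponentials: per-day hazards
  h(s) = h₀ · exp(β·s) with s a canonical severity index using fixed
  reference loadings (0.08, 0.27, 0.96)-normalized — simulation truth
  only, never the fitted model. Defaults: h₀(NRM) = 7·10⁻⁵/day with
  β(NRM) = 0.6 per index unit (12-month NRM rising from ≈ 2% at s = 0 to
  ≈ 35% at the maximal phenotype), h₀(relapse) = 3·10⁻⁴/day with
  β(relapse) = 0 (severity-neutral relapse). Censoring is administrative
  at 1825 days plus exponential dropout at 10⁻⁴/day. `os_event` is 1 for
  NRM deaths; relapse patients die with probability
  `relapse_death_prob = 0.5`, recorded at the relapse time — the
  single-time schema cannot carry a separate post-relapse death time, a
  deliberate simplification.
* **What the generator does not emulate:** center and era effects, real
  covariate joint distributions, time-varying organ staging, post-relapse
  survival trajectories. Passing tests demonstrate correctness of the
  estimators and the internal consistency of the gradings under these
  stylized conditions, not clinical performance on real cohorts.

## Numerical choices and problem sizes

Training-shaped simulations use n = 2319 and test-shaped n = 700 (with a
735-patient no-aGVHD reference generator); staging-calibration checks use
n = 5000 with full phenotype coverage. Type-I-error calibration of
log-rank and Gray's tests uses 500 null replicates of n = 200; slope
recovery uses the median of 50 replicates at n = 5000; Fine-Gray
recovery draws directly from a subdistribution model with known HR 2
(median over 8 replicates of n = 800); the redistribution direction is
checked over 50 seeded replicates of n = 700. PCA equivalence to a
brute-force 3×3 eigensolver is asserted at 10⁻⁸; Efron/Breslow identity
on tie-free data at 10⁻⁸ in log-likelihood. Cox convergence is declared
on a gradient-norm check and failure raises rather than returning a bad
fit.

## Known limitations

* Fine-Gray standard errors are model-based; robust (sandwich) errors are
  not provided.
* Gray's test uses a pooled (not group-specific) censoring distribution
  for the risk-set weights; the statistic differs slightly from the
  classical formulation but is correctly calibrated under the null.
* The PC1 loading clamp discards a small negative skin weight rather than
  fitting a sign-constrained component.
* The time-dependent AUROC for NRM is cause-specific rather than
  subdistribution-based.
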