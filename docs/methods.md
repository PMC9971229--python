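# Methods

## Instrument and data model

The NMSS scores each of 30 non-motor symptoms as severity (0 = none … 3 =
severe) × frequency (1 = rarely … 4 = very frequent), so an item can only
take values in {0, 1, 2, 3, 4, 6, 8, 9, 12}; the validator rejects anything
else (e.g. a 5 is necessarily a data-entry error). Items map onto nine
domains with sizes (2, 4, 6, 3, 3, 3, 3, 2, 4); domain scores are
within-domain sums and the total ranges 0–360. Missing cells are carried as
an explicit mask: the acceptability report (computable fraction of total
scores, per-item floor/ceiling shares) is computed on the full file, while
every network stage uses listwise-complete rows only, matching the
completer-cohort design of longitudinal scale studies.

## Network estimation

The estimand is the Gaussian-copula graphical model over the items. The
pipeline is the standard EBICglasso recipe:

- **Nonparanormal transform.** Each column is mapped through its empirical
  CDF (ranks/n, average midranks for ties), Winsorized at
  δ = 1/(4 n^¼ √(π log n)) and 1 − δ, then through Φ⁻¹ and rescaled to unit
  sample variance. Tied scores (ubiquitous under floor effects) receive
  identical transformed values; this is the tie-handling contract. The
  transform is applied to all columns uniformly (`npn=False` switches it
  off globally).
- **Penalty path.** 100 log-spaced λ values from λ_max (largest absolute
  off-diagonal correlation) down to 0.01 λ_max. Each graphical-lasso
  solve maximizes log det Θ − tr(SΘ) − λ‖Θ‖₁ over the off-diagonal
  entries (diagonal unpenalized), via scikit-learn's coordinate-descent
  solver; grid points whose estimate is not finite positive definite are
  dropped with a warning. Solver tolerance (1e-4) and iteration cap (500)
  are exposed in `EstimatorSettings` because bootstrap- and
  permutation-heavy analyses re-estimate the network thousands of times;
  a relaxed tolerance of 1e-3 changes selected weights by well under 1e-3.
- **EBIC selection** with γ = 0.5: EBIC = −2ℓ + E log n + 4 E γ log p,
  where ℓ = n(log det Θ − tr(SΘ))/2 is the Gaussian profile log-likelihood
  (constants omitted; selection is invariant to them) and E counts non-zero
  off-diagonal entries. γ = 0.5 is deliberately edge-conservative.
- **Weights.** The selected precision matrix is standardized to partial
  correlations ω_ij = −θ_ij/√(θ_ii θ_jj). No post-selection refit: reported
  weights are the penalized estimates, as in standard EBICglasso use.

Degenerate inputs fail loudly: constant columns, n < 10, and correlation
matrices with condition number > 1e12 raise informative errors; n ≤ p only
warns.

## Centrality, layout

Strength s_i = Σ_j |ω_ij| is the only headline centrality (the appropriate
choice for partial-correlation networks of this kind); "normalized" means
z-standardized across nodes. Node ranks break ties stably by node order.
The Fruchterman–Reingold layout (networkx `spring_layout`, attraction
weight |ω_ij|, fixed seed, no unit-box rescale) is cosmetic output embedded
in the GraphML/JSON bundles; no plot rendering is part of the pipeline.

## Stability

- **Case-dropping bootstrap**: for each drop fraction h in
  {0.05, …, 0.75}, B subsamples of ⌈(1−h)n⌉ rows without replacement are
  re-estimated with identical settings and their strength vector is
  Pearson-correlated with the original. Fractions leaving fewer than
  p + 10 rows are skipped. The CS coefficient is the largest h whose
  correlation is ≥ 0.7 in ≥ 95% of subsamples (0 if none); values above
  0.25 are acceptable, above 0.5 good. B defaults to 1000; desk-scale runs
  and tests use B = 50–200 with a coarser grid, which only coarsens the CS
  resolution.
- **Nonparametric bootstrap**: B resamples with replacement give per-edge
  2.5/97.5% quantile CIs (shrinkage can put a zero estimate exactly at a
  CI boundary; tolerated) and difference tests: two node strengths (or two
  edges) differ when the bootstrap CI of their difference excludes zero.
- **Replicate seeding**: every replicate draws from
  `SeedSequence([master_seed, fraction_index, replicate_index])`, so results
  are independent of execution order and of which grid subsets are run.

## Network comparison test

Observed statistics come from networks re-estimated on each dataset with
identical settings: M = max |ω_ij^A − ω_ij^B| (structure invariance),
S = |Σ|ω^A| − Σ|ω^B|| (global strength invariance), and per-edge
differences. The null distribution permutes the data and re-estimates both
networks each time; p-values use the add-one convention
p = (1 + #{perm ≥ obs})/(1 + n_perm), so the smallest attainable p is
1/(1 + n_perm). Per-edge p-values are reported raw and Holm-corrected; the
default tests all p(p−1)/2 pairs (`edges="union"` restricts to pairs
non-zero in either observed network).

The permutation scheme is a mandatory explicit argument. The canonical NCT
assumes independent groups; for the longitudinal two-visit design the
`paired` scheme instead swaps each subject's two observations with
probability ½, preserving subject-level dependence. Both are implemented;
nothing defaults silently.

## Synthetic generator

The generator exists so the pipeline can be exercised without the
restricted clinical cohort; it emulates structure, not item-by-item
marginals of any particular dataset.

- **Latent model.** Subject latents are multivariate normal with a sparse
  precision matrix; its standardized negative off-diagonal is the true
  partial-correlation network that estimation should recover. Choosing a
  Gaussian copula makes the nonparanormal pipeline's assumption exactly
  true, so recovery failures indicate estimation problems, not model
  mismatch — conversely, passing tests say nothing about copula violations
  in real data.
- **Default truth (30 items).** Fully connected within-domain blocks
  (partial correlations 0.15–0.30) plus 150 random weak cross-domain edges
  (0.03–0.09, 20% negative), always including a cardiovascular/perceptual
  fainting–delusions edge; ≈190 of 435 possible edges are non-zero. The
  precision matrix is shrunk geometrically toward the identity only if its
  smallest eigenvalue falls below 0.05 (the default construction needs no
  shrinkage).
- **Discretization.** Severity is the count of per-item latent cuts passed;
  frequency is a coarser monotone binning of the same latent above the
  severity-0 cut; the score is their product, hence monotone in the latent
  and concentrated on the achievable product set. Severity and frequency
  being driven by one latent keeps them positively dependent, as in real
  symptom ratings — a modelling choice, not an empirical claim. Floor cuts
  are drawn from [0.1, 1.1] latent SD, giving 50–90% zeros per item
  (marked floor effects on every item).
- **Longitudinal design.** The follow-up latent is ρ·z₁ + √(1−ρ²)·ε + drift
  with ε drawn from the same graphical model (ρ = 0.6 retest correlation),
  and per-item drift uniform on [0.05, 0.22] latent SD with four items held
  at zero. Drift acts on the latent mean only, so marginal scores worsen
  while the conditional-dependence network is preserved — the regime the
  longitudinal comparison is designed to detect as "no network change".
  With n = 499 these settings produce Wilcoxon effect sizes r ≈ 0.05–0.25,
  the low-effect-size regime typical of two-year symptom progression.
- `implied_rank_correlation` computes, by bivariate-normal rectangle
  probabilities and midranks, the population Spearman correlation of two
  discretized items — the exact value sample rank correlations converge to,
  used to validate copula fidelity.

## Psychometrics

Cronbach's alpha uses the variance form k/(k−1)(1 − Σσ²_i/σ²_total); item
homogeneity is the mean off-diagonal inter-item Pearson correlation
(constant columns excluded with a warning); corrected item–total is the
correlation of an item with the sum of the remaining 29. The paired
Wilcoxon signed-rank test uses the normal approximation with tie
correction and zero-difference exclusion. The effect size is
**r = |Z|/√N with N the number of submitted pairs**: published descriptive-table
values (e.g. 6.040/√499 = 0.270) are consistent with this form even where
an accompanying text formula reads "r = Z/N", which does not reproduce
them; the √N form is the standard definition and is what this package
implements. Shapiro–Wilk screening is a descriptive utility only; it never
branches the network pipeline.

## Problem sizes in tests and the acceptance script

Stochastic guarantees are checked at the scale that makes them sharp but
still desk-runnable, as the package's own study-size choices: edge-sign
recovery on the full 30-item generator at n = 2000 over 50 replicates
(default estimator settings); permutation-test calibration on a 6-item
sub-scale network (200 null replicates, n = 300 per group, 100
permutations each) with a short 5-point penalty path; CS monotonicity on
the 8-item sub-scale at n ∈ {300, 1000, 3000} with B = 100. The acceptance
script runs the full synthetic study at the cohort scale n = 499 with
B = 50 and 100 permutations under an 8-point path.

## Known limitations

- The generator draws severity and frequency from one latent; real ratings
  have independent rater noise on each factor.
- No handling of missing data beyond listwise deletion for estimation.
- Ordinal data are handled only through the nonparanormal transform;
  polychoric-correlation input and mixed graphical models are out of scope.
- The paired NCT permutes visit labels; it does not model attrition or
  practice effects.
- CS values are quantized to the drop grid; a coarse grid coarsens CS.
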