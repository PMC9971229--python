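# nmssnet

Network analysis of non-motor symptoms in Parkinson's disease, built around
the Non-Motor Symptoms Scale (NMSS): 30 items, each scored as severity (0–3)
× frequency (1–4), grouped into 9 domains, total score 0–360.

The package is for researchers who want to treat a symptom inventory as a
complex interacting system rather than a list of separate severities. It
estimates a regularized partial-correlation network over the items, asks
which symptoms are most central, how stable that answer is under resampling,
and whether the network changes between two visits. Because the clinical
cohorts such analyses are run on are typically access-restricted, the
package ships a synthetic-data generator that emulates NMSS-structured data
(ordinal products, strong floor effects, domain-block dependence, paired
visits with mild worsening), so the whole pipeline is testable end to end.

## The model

Item scores are modelled as monotone discretizations of a latent Gaussian
vector **z** ~ N(0, Σ) (a Gaussian copula). The estimand is the Gaussian
graphical model: the partial correlation between items *i* and *j* given
all others,

> ω_ij = −θ_ij / √(θ_ii θ_jj),  Θ = Σ⁻¹,

which is zero exactly when the two items are conditionally independent.
Estimation follows the standard EBICglasso recipe:

1. **Nonparanormal transform** of each column: shrunken empirical CDF
   (ranks/n, Winsorized at δ = 1/(4n^¼ √(π log n))) followed by Φ⁻¹ and
   rescaling to unit variance.
2. **Graphical lasso** over a descending grid of 100 penalties λ from
   λ_max = max|r_ij| down to 0.01·λ_max, maximizing
   log det Θ − tr(SΘ) − λ‖Θ‖₁,off.
3. **EBIC selection** with γ = 0.5:
   EBIC(λ) = −2ℓ + E log n + 4Eγ log p, with E the edge count.

Downstream: **strength centrality** s_i = Σ_j |ω_ij| (reported
z-standardized), a **case-dropping bootstrap** summarized by the CS
coefficient (largest case-drop proportion retaining correlation ≥ 0.7 with
the original strength in ≥ 95% of subsamples), nonparametric bootstrap
edge CIs and difference tests, and a **network comparison test** between
two visits: permutation p-values for the maximum edge difference M, the
global strength difference S, and every individual edge.

## Worked example

```python
from nmssnet import (default_config, simulate, estimate_network, strength,
                     case_dropping_bootstrap, cs_coefficient,
                     network_comparison_test, EstimatorSettings)

baseline, followup = simulate(default_config(seed=1, n_subjects=499))
net, path = estimate_network(baseline)
print(net.n_edges, "of", net.n_possible_edges, "edges")
print(strength(net).to_frame().sort_values("rank").head(3))

fast = EstimatorSettings(n_lambda=8, lambda_min_ratio=0.1, solver_tol=1e-3)
cs = cs_coefficient(case_dropping_bootstrap(baseline, fast, B=100, seed=1))
print("CS(cor=0.7) =", cs.value)

nct = network_comparison_test(baseline, followup, fast,
                              n_perm=200, scheme="paired", seed=1)
print(f"M={nct.m_observed:.3f} (p={nct.p_m:.3f})  "
      f"S={nct.s_observed:.3f} (p={nct.p_s:.3f})")
```

Output (seed 1):

```
35 of 435 edges
                    strength         z  rank
flat_mood           0.898324  2.399814     1
lack_of_motivation  0.847808  2.229372     2
feeling_nervous     0.811543  2.107011     3
CS(cor=0.7) = 0.75
M=0.106 (p=0.318)  S=0.085 (p=0.776)
```

`35 of 435` is the number of non-zero partial correlations the EBIC
(γ = 0.5) keeps at n = 499 — deliberately conservative, so only
well-supported conditional associations survive. The three most central
(highest-strength) items are mood-domain symptoms, a CS of 0.75 means the
strength ordering survives dropping three quarters of the sample, and the
non-significant M and S say the baseline and follow-up networks are
statistically indistinguishable even though the drift worsens the marginal
scores.

The same stages are available from a shell:

```bash
nmssnet simulate --n 499 --seed 1 --baseline-out b.csv --followup-out f.csv
nmssnet run-all --baseline b.csv --followup f.csv --scheme paired \
        --seed 1 -B 200 --n-perm 500 --out-dir results/
```

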