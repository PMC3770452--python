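# Methods

## Model

Genotype counts in the two groups are modelled as independent
multinomials: **X** | θ ~ Multinomial(n, **γ**), **Y** | θ ~
Multinomial(m, **Π**), with θ = (γ, Π) on the product of two 2-simplices
(ambient dimension 4). The hypotheses handled, with their null-set
dimensions:

| hypothesis | null set | dim | df |
|---|---|---|---|
| genotypic homogeneity (H0G) | γ = Π | 2 | 2 |
| allelic homogeneity (H0A) | γ_AA + ½γ_AB = Π_AA + ½Π_AB | 3 | 1 |
| HWE (one group) | (p², 2p(1−p), (1−p)²), p ∈ [0,1] | 1 (in d = 2) | 1 |

H0G ⊂ H0A: equal genotype frequency vectors force equal allele
frequencies. The HWE hypotheses are treated on the affected group's own
simplex (d = 2); the other group's parameters are irrelevant to them.

## Frequentist tests

**Genotypic chi-square.** Q^G = Σ_i (X_i − nθ̂_i)²/(nθ̂_i) + (Y_i −
mθ̂_i)²/(mθ̂_i) with the pooled MLE θ̂_i = (x_i + y_i)/(n + m); 2 df.

**Doubled-sample allelic chi-square (biased comparator).** The 2×2
Pearson chi-square of the derived allele table (x_A = 2x_AA + x_AB,
etc.), which pretends the 2n + 2m alleles are independent draws. That
independence holds exactly when both groups are in HWE, and only then is
the null distribution χ²₁. It is included because it remains in wide
use; every result object carries a warning saying so.

**Corrected allelic test.** Q^A* compares the genotype table (all six
cells) with expected counts at the MLE constrained to H0A; 1 df
(dim 4 − dim 3). Asymptotically this test is equivalent to the
Cochran–Armitage trend test, which is also provided (scores 0, 1, 2; the
two-sided statistic is invariant to score orientation).

**Constrained MLE by profiling.** On H0A both groups share an allele-A
frequency λ. For fixed λ the two groups decouple, and within a group the
log-likelihood in u = γ_AB/2 is a sum of logs of affine functions —
strictly concave — whose stationarity condition is the quadratic
N u² − B u + C = 0 with N = Σc, B = c_AA(1−λ) + c_AB + c_BB λ,
C = c_AB λ(1−λ). The admissible root (in [0, min(λ, 1−λ)]) is therefore
closed-form. The outer one-dimensional profile over λ is maximised by a
65-point grid followed by 48 golden-section iterations (bracket width
≈ 2/64 · 0.618⁴⁸ ≈ 10⁻¹⁴), vectorised across tables. This replaces a
generic 3-coordinate constrained optimiser: it needs no starting point,
no restarts, cannot converge to an infeasible point, and evaluates
~100,000 bootstrap refits in about two seconds. Boundary maximisers
(some cell estimate 0) are legitimate outputs and flagged, not errors.
A degenerate group with all-zero weights has a flat likelihood; the
mid-curve point is returned.

**Monte-Carlo exact p-values.** Replicate tables are drawn at the plug-in
null fit — Multinomial(n, γ̂*) × Multinomial(m, Π̂*) for the corrected
test (constrained MLE re-fit on every replicate), the pooled MLE for the
genotypic test, Binomials in the doubled-allele model for the usual test
(its own model, for internal consistency). p̂ = #{replicate statistic ≥
observed}/R; ties count as exceedances (conservative), with a 10⁻⁹
slack so exact ties survive floating-point noise. A 95%
normal-approximation binomial CI accompanies every MC p-value, and every
stochastic result records its seed and replicate count. No supremum over
the null manifold is attempted: the plug-in bootstrap is the stated
procedure, and the test is exact in the Monte-Carlo sense (the CI
quantifies the only approximation). Defaults: 10,000 replicates for
routine use, 100,000 in the acceptance script.

**Chi-square cell conventions.** Expected 0 with observed 0 contributes
0; expected 0 with observed > 0 yields +∞ (p = 0, flagged). Everywhere a
log-likelihood is formed, 0·log 0 := 0.

**HWE goodness of fit.** Standard 1-df chi-square against expected
counts (N p̂², 2N p̂q̂, N q̂²), p̂ = (2·AA + AB)/2N, no continuity
correction; monomorphic groups (p̂ ∈ {0, 1}) are an explicit error.

## FBST

Independent Dirichlet priors (default all-ones, i.e. uniform) are
conjugate: the posterior is Dirichlet(x + a) × Dirichlet(y + b). All
density comparisons use the fixed unnormalised scale
Σ_i (α_i − 1) log(freq_i); normalising constants cancel inside the
tangential-set indicator, and the e-value is invariant to any additive
shift of the log density.

*Optimisation step.* On H0G the pooled exponents e_i = α_case,i +
α_control,i − 2 give the closed-form maximiser p_i ∝ e_i. On H0A the
same profile algorithm as the constrained MLE is run with exponents
α − 1 as weights; the H0G arg-sup (which lies in the H0A null set) is
always injected as a candidate, so sup_{H0A} ≥ sup_{H0G} holds exactly
regardless of optimiser tolerance. On the HWE curve the exponents of
log p and log(1−p) are a = 2w_AA + w_AB, b = 2w_BB + w_AB, giving the
closed-form maximiser p = a/(a + b) (verified against a 10⁻⁵-step grid
in the tests). If any relevant exponent is strictly negative (possible
with sub-uniform priors and zero counts) the density is unbounded on the
null set; the supremum is +∞, the tangential set empty and the e-value
1 — a numerical "fallback optimisation" would silently return a finite
wrong answer, so it is not attempted.

*Integration step.* θ is sampled from the posterior (numpy's Dirichlet
generator, i.e. normalised Gamma draws, one RNG stream per run);
ev = 1 − #{draws with density > sup}/n_draws, with Monte-Carlo standard
error √(ev(1−ev)/n_draws) ≤ 0.0016 at the default 100,000 draws.

*Coherence.* Because H0G ⊂ H0A, the null suprema are ordered and the
tangential sets nested, so ev(H0G) ≤ ev(H0A) for every dataset and
prior. `evalues_nested` evaluates both hypotheses on one shared draw
set, making the inequality hold draw-by-draw (exactly, not just in
expectation); the coherence auditor relies on this.

*Cutoff calibration.* The asymptotic e-value/p-value link for a sharp
hypothesis of codimension k in ambient dimension d gives the rejection
threshold cutoff(α) = 1 − F_d(F⁻¹_k(1 − α)) (F_j = chi-square CDF);
reject when ev ≤ cutoff. At α = 0.05: 0.4279 for H0A (d = 4, k = 1) and
0.1998 for H0G (d = 4, k = 2). Power studies reject on ev ≤ cutoff
(boundary counts as rejection).

*Bayes factors.* Under uniform priors, P(data|H0G)/P(data|Θ) is a ratio
of Dirichlet moment integrals (multinomial coefficients cancel), computed
in log space. For H0A the null set is a 3-manifold with no canonical
uniform measure; this package takes Lebesgue-uniform in the chart
(γ_AB, Π_AA, Π_AB) on the feasible region (rejection-sampled Monte-Carlo
average of the likelihood kernel). Other defensible conventions give
different numbers — Bayes-factor values are therefore reported with this
convention stated, and are not used for any calibration or acceptance
claim. The worked real-data example gives ≈ 4.68 for H0G and ≈ 1.28 for
H0A under these conventions; the point that matters is the lack of
monotonicity of Bayes factors over nested sharp hypotheses, which is
what motivates the e-value.

## Simulation design

**Power scenarios.** Fix γ_AA, γ_AB, Π_AA and an offset ε, and set
Π_AB = 2(γ_AA + ½γ_AB − Π_AA − ε), so the case/control allele-A
frequencies differ by exactly ε; ε = 0 is the allelic null. Scenarios
whose implied frequencies leave [0, 1] are rejected with the violated
bound named. Default grid ε ∈ {0, 0.02, …, 0.20} ∩ feasibility (the
design's published grid is not stated; curves are reproduced as shapes,
not point values). The headline design simulates 100 datasets of
n = m = 100 per grid point; calibration assertions use ≥ 2,000 datasets,
since 100 cannot distinguish a 5% size from 8%.

**Regimes.** Three generator families: (1) γ = Π (genotypic
homogeneity, hence allelic too); (2) equal allele frequencies with
genuinely different genotype vectors (each group mixes its heterozygote
share independently — both groups off HWE in different ways); (3) allele
frequencies differing by at least a requested margin. Regime 2 satisfies
the allelic constraint to machine precision by construction.

**Seed policy.** A master seed spawns per-scenario and per-dataset
substreams (`SeedSequence((seed, scenario, dataset))`), so any single
dataset is re-derivable from the master seed and its index. When no seed
is given, fresh entropy is drawn and recorded.

**What the generators do and do not emulate.** Tables are ideal
product-multinomial draws: no genotyping error, no population
stratification, no covariates, no linkage between loci. A green
simulation test therefore establishes calibration and coherence of the
*tests* under the stated sampling model, not robustness to the
epidemiological artefacts that motivate care with real data.

## Known limitations

- Strictly biallelic, single-locus, two-group; no covariates, stratified
  analyses, or VCF/PLINK ingestion.
- The corrected test's bootstrap is plug-in (parametric bootstrap at the
  constrained MLE), not a worst-case supremum over the null; its
  Monte-Carlo CI quantifies simulation error only.
- Asymptotic p-values rely on chi-square approximations that degrade for
  very sparse tables; the Monte-Carlo engines are the remedy and are
  exact up to quantified simulation error.
- Bayes-factor values for H0A depend on an arbitrary dominating-measure
  convention (above); treat them qualitatively.
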