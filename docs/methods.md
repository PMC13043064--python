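# Methods

## The model and what the package computes

The object of study is the single-variant interaction regression

    Y = μ + αE + βG + γGE (+ covariates) + ε,

fitted per variant by ordinary least squares. For a binary exposure and a
haploid variant with all four (E, G) cells populated the model is saturated,
so the coefficients are identically the cell-mean contrasts of
P_{a,b} = Ê[Y | E=a, G=b]; the package exposes both routes and tests their
agreement to 1e−10. p-values use the t reference with residual degrees of
freedom; HC1 heteroskedasticity-consistent standard errors are an option
(`robust=True`) because transformed outcomes are typically heteroskedastic
across exposure strata.

### Induced interactions under outcome re-expression

Assume the outcome is additive and homoskedastic on its original scale
(γ = 0, symmetric noise with density f) and is re-expressed through a
monotone map φ. The induced coefficients on the φ scale are the
noise-averaged contrasts

    β_φ = ∫ [φ(P01+e) − φ(P00+e)] f(e) de,
    γ_φ = ∫ [φ(P11+e) − φ(P10+e) − (φ(P01+e) − φ(P00+e))] f(e) de.

For maps with globally signed second derivative this yields the product rule
sgn(γ_φ) = sgn(φ″)·sgn(α_φ)·sgn(β_φ); the package evaluates the integrals by
Gauss–Hermite quadrature (exactly for point-mass noise) and checks the rule
against the oracle exhaustively. Quadrature notes: default order 80; nodes
whose arguments leave the map's domain are dropped when their total
normalized weight is below 1e−12 (the Gaussian tail carries no mass there) —
larger out-of-domain mass is a hard error; orders above 300 are rejected
because the Hermite node computation itself degrades. The saturating tanh
needs order ≈ 200 at noise sd 2; everything else in the registry is
converged below 1e−8 by order ≈ 60. The oracle reports "indeterminate"
when |γ_φ| < 1e−12 × the scale of φ over the cell range, to avoid asserting
the sign of a numerical zero.

The registry stores only sgn(φ″) (+1, 0, −1, or "mixed" for the logistic and
tanh, which are convex on one half of their domain and concave on the
other). Mixed-curvature maps are excluded from the analytic rule; their
induced signs are variant-specific and come only from the numeric oracle.

Positivity shifts: log, sqrt and the increasing square are defined on
positive support, so real-valued outcomes are shifted first. A shift is
affine and changes neither monotonicity nor sgn(φ″). `ShiftPolicy`
supports `none`, `fixed`, and `to_positive` (shift so min(y) equals a
margin); the applied offset is always returned so a per-replicate shift is
reproducible from the report alone.

### Correlated G and E

When G and E are correlated, the induced interaction acquires a
non-orthogonality term in addition to the transformation term
α·β·E[φ″(·)]. The package estimates the decomposition empirically
(`dominance_check`): it simulates correlated Bernoulli (G, E) pairs at a
requested correlation (feasibility checked against the Fréchet bounds),
fits the transformed regression per replicate, and reports the mean induced
γ_φ, the transformation term, their difference as the operational
correlation term, and the fraction of replicates obeying the product rule.
The second derivative is averaged over the noise *around the latent
phenotype location* (Gauss–Hermite on φ″ when the registry provides it,
central differences with h = sd·1e−3 otherwise); evaluating at the data's
location rather than at zero is what makes the correlation term vanish to
first order at ρ = 0 for location-dependent curvature such as exp or log.
No closed form for the correlation term is attempted; the operational
definition is the tested contract.

### Endogenous treatment

The threshold model assigns E = 1{Y > t} to a polygenic phenotype
Y = Σ β_i G_i + ε (independent haploid Bernoulli variants, Gaussian noise)
and shifts the observed outcome by a treatment effect. Conditional on E the
outcome is truncated normal, so with P_a = (t − E[Y | G_j=a])/s_j the
expected regression coefficients are the inverse-Mills-ratio contrasts
given in the README; λ(x) = ϕ(x)/Φ(x) is computed in log space and is
accurate to the asymptotic regime λ(x) ≈ −x − 1/x by x = −40. The
polygenic background of the other variants is absorbed into the noise as a
Gaussian, giving the variant-conditional scale
s_j² = σ_ε² + Σ_{i≠j} β_i² p_i (1−p_i); with no background and unit noise
this reduces to the plain unit-variance expressions. The Gaussian
absorption is accurate when individual effects are small relative to s_j —
the simulator's demonstration settings use |β_j| ≤ 0.3 s_j, under which
fitted coefficients at n = 2×10⁵ match the analytic values within Monte
Carlo error. Treatment-below-threshold is implemented by the reflection
Y → −Y, t → −t on the same code path. The expected coefficients require
both variant-conditional means below the threshold (direction "above");
violating inputs raise rather than extrapolate. The treatment effect's
magnitude and sign cancel from both expectations.

## The synthetic panel generator

`simulate_panel` emulates a phenotype measured on its natural clinical
scale, tested SNP-by-SNP for interaction with a binary exposure:

- n = 10,000 samples, balanced 5,000 per exposure arm (by design, not by
  sampling);
- 200 independent diploid SNPs in Hardy–Weinberg proportions with
  MAF ~ U(0.05, 0.5) — the lower bound keeps every (E, G) cell populated at
  these sample sizes;
- additive effects β ~ N(0, 1), interaction effects on 100 randomly chosen
  SNPs with magnitudes |N(0, σ²_GxE)| and signs forced half aligned with /
  half opposed to the corresponding main effects;
- outcome Y = 2E + Xβ + (X∘E)γ + ε.

Scale convention: the drawn effects are jointly rescaled so that the
realized Var(Xβ) among the unexposed equals the target heritability (0.5 by
default) with noise variance 1 − h², i.e. the phenotype is measured in
unexposed-stratum sd units and the exposure main effect (default 2) is
2 unexposed-sds. Per-SNP effects are then ≈ N(0, h²/Σ_j var(x_j)),
the usual per-SNP normalization in polygenic simulation. This convention is
what gives the outcome transformations a meaningful lever arm: on an
arbitrary unnormalized scale the same maps are locally linear over the data
and induce nothing detectable. Genotype dosages are left uncentered, as
the generating equation states.

The replicate driver applies, per replicate: the log after a
`to_positive` shift with margin 0.1 (≈ 0.1 sd — a margin comparable to the
data spread visibly flattens the log's curvature, a full-sd margin halves
the induced effect); the square with *no* shift (`"square_raw"`), which is
how a practitioner squares a real-valued outcome — non-monotone wherever
the data straddle zero, and materially different from the monotone
shifted square, which acts only through its slope ratio at these spreads;
and the rank-based INT with the Blom-type constant 0.5 and averaged ranks
for ties (the variant is otherwise a free choice; ranks, not distances,
are what INT preserves). Interaction significance is assessed at the
nominal 5% level with classical SEs on every scale.

The sign-consistency rate follows the detected-set definition: among
variants passing the a priori p-value filters (interaction threshold,
optional nominal main-effect threshold), the proportion showing the more
prevalent sign relationship with their main effects — hence ≥ 0.5 whenever
defined; the majority relationship (aligned/opposed) is reported alongside
because the theory predicts *which* relationship dominates, and the rate
alone discards that direction. Exact zero estimates are excluded and
counted separately. The accompanying two-sided binomial test against 1/2
is a labelled aid, not part of the definition, and every report carries the
caveat that no universal rate threshold identifies scaling or endogeneity
as the driver.

Seed policy: one integer seed; replicate r of grid cell s uses
`SeedSequence([seed, s, r])` folded to 31 bits, so any single replicate is
independently reproducible.

### What the generator does and does not emulate

It reproduces the statistical structure the diagnostics respond to —
additive polygenic signal, balanced binary exposure, randomly directed
interactions, exposure-stratum heteroskedasticity induced by interactions,
HWE genotypes. It has no linkage disequilibrium, population stratification,
relatedness, missingness, or measurement error; passing tests therefore
demonstrate the scaling/endogeneity mechanisms and the diagnostic's
behavior under them, not robustness of real-data G×E scans to those
orthogonal complications.

## Study conditions used by the shipped experiments

The headline experiments run 20 replicates at σ²_GxE = 2: with 100 of 200
SNPs interacting, that is the point where expected interaction-explained
variance among the exposed equals the additive-explained variance, the
boundary of the regime where interactions explain at least as much as the
additive effects. Under these conditions the mean sign-consistency rate
among 5%-significant interactions is ≈ 0.75–0.79 after the log and ≈
0.75–0.79 after the raw square (replicate sd ≈ 0.09–0.12), against ≈ 0.54
on the original scale; at smaller interaction variance (σ²_GxE = 0.5) the
transformed-scale rates approach 1. The INT changes the rate by ≈ +0.05
relative to the original scale under these strong-interaction conditions:
pooled-quantile mapping of the exposure-mixture distribution (the exposed
stratum has roughly twice the unexposed variance here) compresses the
upper tail and induces a small opposed-sign component. Neutrality of the
INT is therefore approximate, at ~0.05 resolution, not exact.

The endogenous-treatment demonstration uses 20 variants with
|β| ∈ [0.1, 0.3], MAF ∈ [0.2, 0.5], threshold 1.5 (treated fraction ≈ 13%)
and n = 2×10⁵ — sizes at which the Gaussian-background approximation error
is well inside Monte Carlo error while a laptop-scale run stays under a
minute.

## Numerical and degenerate-input choices

- Rank-deficient designs (monomorphic variant, constant exposure) raise
  errors naming the offending column; `fit_all` aggregates per-variant
  failures with indices.
- Domain violations in transforms are hard errors, never silent NaN.
- Empty diagnostic selections yield an NA rate with an explanatory note,
  not an error; empty variant sets yield empty tables.
- Covariates are standardized (non-binary ones) before optional
  covariate×E interaction columns are formed; genotypes are never
  standardized, since the diagnostic is about signs.
- Achievable G-E correlations for binary pairs are checked against the
  Fréchet bounds and per-dosage exposure probabilities are required to lie
  in [0, 1]; infeasible requests raise.

## Known limitations

- The analytic sign rule is exact only under the null-interaction,
  homoskedastic premise; the package quantifies (rather than proves)
  behavior outside it by simulation.
- The correlation-term decomposition is operational (difference of
  estimates), not a closed form, and inherits Monte Carlo error.
- The endogenous expectations use the Gaussian-background approximation;
  for oligogenic traits with large per-variant effects the approximation
  degrades and only the simulator is reliable.
- The diagnostic is a screen: a high sign-consistency rate flags possible
  scaling/endogeneity artifacts but cannot apportion them, and a genuine
  biological mechanism producing uniformly directed interactions would be
  indistinguishable from it.
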