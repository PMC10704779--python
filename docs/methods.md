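# Methods

## Models and estimators

### Age-reading precision

Each fish's age is read R times (default 3) per structure. The average
percent error (Beamish–Fournier) and average coefficient of variation
(Chang) are computed per fish and averaged *unweighted* over fish, so a
fish read five times counts no more than one read three times. The CV
uses the sample SD (divisor R − 1), the convention of the precision
literature; a population-SD variant is available (`ddof=0`). For R = 2
the two indices are locked together, ACV = √2·APE — a useful algebraic
unit test. Consensus ages default to the per-fish median (deterministic;
software has no microscope to re-read under); the modal rule returns the
majority read and flags full disagreement for re-evaluation.

The between-structure comparison regresses vertebral consensus age on
otolith consensus age over fish present in both sets. The free-slope OLS
fit is the default; a slope-fixed-at-1 mode estimates only the mean
offset, for protocols that treat the structures as counting the same
annuli. Published versions of this comparison sometimes print an
implicit slope of exactly 1; whether that reflects a constrained fit or
rounding is generally undecidable from a printed equation, so both modes
exist and neither is privileged.

### Length–weight relationship

OLS of log₁₀W on log₁₀L; a = 10^intercept. All logs in the package are
base 10. The isometry test is t = (b − 3)/SE(b) at df = n − 2. Sex
contrasts follow the conventional ANCOVA order: the slope difference is
the t on the sex × log₁₀L interaction in the two-slopes model; the
intercept difference is the t on the sex indicator in the common-slope
model. Juveniles are an age class, not a sex, and are excluded.

### Von Bertalanffy growth

L(t) = L∞(1 − e^(−K(t−t₀))) fitted by unconstrained nonlinear least
squares (Levenberg–Marquardt, analytic Jacobian, ftol = xtol = 1e−12).
Starting values are data-driven: L∞⁰ = 1.1·max(L); K⁰ from the slope of
log(1 − L/L∞⁰) against age; t₀⁰ = 0. Standard errors come from
s²(JᵀJ)⁻¹ at the optimum with s² = RSS/(n − 3); t = estimate/SE and
two-sided P from Student's t at df = n − 3 (this df convention was
validated against an independently published five-partition growth
table, whose printed t and P values it reproduces). No box constraints
by default — when a partition is unidentifiable the fit is allowed to
wander to absurd L∞ with huge SEs, because *reporting* that failure is
the honest outcome; bounds are available as an option. A Jacobian
condition number above 1e14 marks the fit singular and suppresses SEs
rather than laundering them through a pseudoinverse.

The five-series design fits: all fish; females; males; females +
juveniles; males + juveniles (juveniles enter both mixed partitions).
Sex-only partitions of a slow-growing, late-maturing cohort span a
narrow old-age window near the asymptote, which leaves (L∞, K) nearly
unidentifiable — the recovery tests verify both the success of the
anchored fits and this failure mode.

Growth performance: Φ′ = log₁₀K + 2·log₁₀L∞, constant along slope −2
lines of the (log₁₀L∞, log₁₀K) auximetric plane.

### Interspecific allometry and PGLS

Across species, OLS of log₁₀K on log₁₀L∞. The phylogenetic version is
GLS with covariance σ²C(λ), where C is the Brownian-motion matrix of
shared root-to-MRCA branch lengths and Pagel's λ multiplies its
off-diagonal entries. λ is estimated by maximum likelihood (not REML) on
[0, 1] by bounded scalar optimization of the profile log-likelihood
(β and σ² concentrated out), with both endpoints checked explicitly.
λ = 0 reproduces OLS exactly; on a star phylogeny every λ does. The
PGLS R² is computed on C(λ)^(−1/2)-whitened data against the whitened
intercept-only model — stated here because PGLS R² definitions vary.
The implementation is cross-checked against a brute-force matrix GLS
and against R's `nlme::gls` + `ape::corPagel` (ML) on a frozen fixture;
note `corPagel` optimizes λ unconstrained by default and can return
λ > 1, whereas this package keeps λ in [0, 1], the standard domain.
Species names match tree taxa case-insensitively with spaces and
underscores interchangeable; unmatched names fail loudly.

Group contrasts on K, L∞ or Φ′ (optionally log₁₀-transformed) use
Welch's t by default — the variance assumption behind a pooled test is
rarely defensible for unbalanced species sets — with the pooled variant
as an option.

### Composition and energy

Analyte trends are straight-line OLS on untransformed axes (analyte in
mg/g, length in cm). Slopes from two fits are compared with
t = (b₂ − b₁)/√(SE₁² + SE₂²), df = n₁ + n₂ − 4 (two slopes and two
intercepts estimated; sources rarely state their df convention, this one
is recorded). Analytes measured on the same samples are correlated, so a
paired mode (slope t-test on the within-sample difference) is provided;
the independent form is the default because it needs only the two fitted
lines.

Energy density E = (23.6·protein + 39.5·lipid + 17.2·glycogen)/1000
kJ/g, the standard combustion equivalents; ash burns to nothing and
contributes zero. Coefficients are injectable for alternative
calorimetric tables. Whether the mg/g values sit on a wet- or dry-mass
basis is treated as opaque — the formula is basis-agnostic and the
package never converts.

Pooling of small fish follows a 2 mm rule: sorted by length, a pool
opens at the smallest unpooled fish and absorbs consecutive fish within
2 mm of the pool's *first* member; the pool carries mean length and mean
analytes. The greedy-from-smallest rule is one deterministic reading of
"pool individuals within 2 mm" — the grouping algorithm is otherwise
underdetermined, and determinism is what makes pooled analyses
reproducible. A small (1e−9 cm) slack absorbs float representation of
0.1-cm-precision lengths.

## The synthetic-data generator

The generator inverts the analysis models, so zero-noise configurations
make every downstream estimator exact — the core identifiability test —
and seeded noisy configurations support recovery and error-rate checks.
Defaults describe a cohort of a slow-growing cave loach:

| parameter | default | rationale |
|---|---|---|
| n_fish | 102 | study cohort size |
| age range | 3.3–15.8 yr | observed age span |
| VBGF (L∞, K, t₀) | 23.4 cm, 0.060 yr⁻¹, 0.12 yr | published total-data fit |
| length noise | 0.5 cm additive Gaussian | ~0.1-cm caliper precision plus individual scatter; at this level the VBGF fit on the full cohort is tight while sex-only windows degrade |
| LWR (a, b) | 0.0046, 3.03 | published combined-sex power law |
| weight noise | lognormal, ln-SD 0.1 | ~10% multiplicative error, the standard residual model for power laws |
| maturity age | 4.8 yr | earliest observed maturity; younger fish are juveniles |
| sex ratio | 0.5 | observed near-parity (32F/33M) |
| reads per structure | 3 | standard protocol |
| reading SD (otolith, vertebra) | 0.4, 0.5 yr | chosen so ACV lands in the published few-percent range at mean age ~9 yr, with otoliths the more precise structure |
| species allometry | slope −1.64, intercept 1.09 | published six-species regression |

Ages are uniform on the range — the least-informative choice given only
an observed min/max. Reading errors are continuous by default with an
integer-rounding option: band counts are integers, but published ages
are often fractional (capture-month offsetting), and the generator
sidesteps that unstated conversion by producing continuous truth.

Composition defaults (intercept, slope, per-fish SD in mg/g):
protein (140, −2.0, 45), lipid (−13, 11.3, 35), glycogen (6, −0.05, 2),
ash (35, −0.5, 10). These encode the study's qualitative findings: a
steep, detectable lipid rise (slope 11.3) with protein/glycogen/ash
drifting gently but non-significantly at cohort scale, and an implied
energy slope of ≈ 0.40 kJ/g/cm. Negative draws are truncated at zero
and the truncation count is reported via warning, never silently.

What the generator does *not* emulate: seasonal sampling structure,
capture bias, measurement rounding to instrument precision, the
integer-to-fractional age conversion, multiplicative composition noise,
or any cave-hydrology covariates. Passing recovery tests therefore shows
the estimators are correct and well-calibrated under the stated
generating models — not that the models capture every feature of real
specimens. Pooled-sample composition R² tends to run higher here than in
real data because noise is modeled per fish and averages down under
pooling.

Yule trees come from dendropy's birth–death sampler; the process stops
at the n-th speciation, so one extra exponential waiting time is added
to all tip branches to keep terminal branches positive (and the BM
covariance positive definite). Brownian residuals on a tree are scaled
so the average marginal SD equals the configured residual SD (tip
variances differ on non-ultrametric trees).

## Numerical choices

- CSVs are read with `float_precision="round_trip"` so write→read is
  bit-identical for finite values (the round-trip property tests depend
  on it).
- Degenerate straight-line fits: a constant response gives slope 0 and
  R² = 0 (not NaN); zero x-variance raises.
- The isometry test refuses se_b = 0 (zero-residual data make the t
  ratio 0/0); exactness of the exponent itself is the testable claim
  there.
- Optimizer non-convergence and singular Jacobians are flags on the
  returned fit, never exceptions and never silent.
- Printed-table consistency checks propagate half-ulp rounding of every
  printed figure into their tolerances rather than using ad hoc slack.

## Problem sizes

Recovery checks in the test suite and the acceptance script use 100–200
replicates of 102-fish cohorts (or 30-sample composition sets), sizes at
which Monte-Carlo error on the reported means/medians is well under the
comparison tolerances; the full suite runs in well under a minute.

## Known limitations

- PGLS assumes the supplied tree is correct and complete; no tree
  inference, no measurement-error-in-covariate correction.
- The five-partition VBGF design duplicates juveniles across both mixed
  partitions by construction; the partitions are therefore not
  independent and no cross-partition test is offered.
- The independent-slopes composition contrast ignores within-sample
  correlation between analytes (the paired mode addresses it but needs
  matched records).
- Energy coefficients are constants; no species- or season-specific
  calorimetry.
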