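# cavegrowth

Life-history analysis toolkit for slow-growing, cave-dwelling loaches —
age-reading precision, length–weight allometry, von Bertalanffy growth
modelling, growth-performance comparison across species (with and without
phylogenetic correction), and body-composition/energy-density analysis —
together with synthetic-data generators that make every stage testable
against known truth.

## The scientific problem

Obligate cave fishes (troglobites) live in darkness with scarce food and
few predators. Classic life-history theory predicts they should grow
slowly, stay small, mature late and hoard energy as lipid. Testing this
on a wild cohort requires a chain of standard fisheries analyses:

1. **Ageing precision.** Ages are counted three times from two bony
   structures (lapillus otoliths, vertebrae). Between-reading agreement is
   summarised by the average percent error and the average coefficient of
   variation,

   APE = mean over fish of 100·(1/R)·Σᵢ|Xᵢⱼ − X̄ⱼ|/X̄ⱼ,  ACV = mean over fish of 100·sⱼ/X̄ⱼ,

   and the structures are compared by regressing vertebral on otolith
   consensus ages.

2. **Length–weight allometry.** W = aL^b, fitted by OLS on log₁₀ axes;
   b = 3 means isometric (shape-preserving) growth, tested by a one-sample
   t-test on the exponent; sex differences by ANCOVA-style contrasts.

3. **Growth.** The von Bertalanffy growth function (VBGF)

   L(t) = L∞(1 − e^(−K(t − t₀)))

   fitted by nonlinear least squares to five data series (all fish, each
   sex alone, each sex pooled with juveniles), with per-parameter SE, t and
   two-sided P at df = n − 3.

4. **Interspecific comparison.** The growth performance index
   Φ′ = log₁₀K + 2·log₁₀L∞ collapses the negatively correlated (K, L∞)
   pair into one number; across species, log₁₀K regresses on log₁₀L∞ by
   OLS and by phylogenetic GLS under Pagel's λ (ML-estimated on [0, 1]).

5. **Energy storage.** Proximate composition (protein, lipid, glycogen,
   ash in mg/g) converts to energy density
   E = (23.6·protein + 39.5·lipid + 17.2·glycogen)/1000 kJ/g, and each
   component is regressed on total length.

The package implements all five stages as a library (`cavegrowth`), a CLI
(`cavegrowth simulate|precision|fit-lwr|fit-growth|interspecific|energy|run`),
and a numbered analysis sequence under `analysis/`.

## Worked example

Running the analysis sequence on the default synthetic cohort (102 fish
generated from the VBGF with L∞ = 23.4 cm, K = 0.060 yr⁻¹, t₀ = 0.12 yr,
weights from W = 0.0046·L^3.03, maturity at 4.8 yr):

```bash
cd analysis
python 01_simulate_cohort.py
python 03_length_weight.py
```

prints

```
W = 0.004618 L^3.03   (R^2 = 0.992, n = 102)
isometry: t = 1.056, P = 0.293 -> consistent with isometric growth
sex effect: slope t = -0.045 (P = 0.964), intercept t = -1.075 (P = 0.285) -> one curve for both sexes
```

— the fitted power law recovers the generating coefficients, the exponent
does not differ from 3 (isometric growth), and the sexes share one curve.
`python 04_growth_curves.py` then gives the five-partition VBGF table:

```
partition           n           L_inf               K              t0
total             102   22.603± 2.475    0.063± 0.012    0.113± 0.392
female             50   17.786± 1.950    0.107± 0.030    1.516± 0.792
male               42   26.636± 7.922    0.049± 0.024   -0.270± 0.973
female&juvenile    60   21.177± 2.583    0.070± 0.016    0.228± 0.447
male&juvenile      52   26.312± 5.262    0.050± 0.016   -0.239± 0.498
growth performance (total fit): phi' = 1.51 (generating curve: phi' = 1.52)
```

Note how the sex-only partitions — mature fish spanning a narrow old-age
window with no juveniles to anchor the rising limb — are far less
precisely identified than the total and mixed fits. With real data this
degeneracy can be extreme (SEs larger than the estimates themselves).

`python 05_interspecific.py` reproduces the cross-species allometry from
the shipped six-loach literature table:

```
OLS: log10 K = -1.64 log10 L_inf + 1.09 (R^2 = 0.91, P = 0.003, n = 6)
```

and `python 06_composition_energy.py` shows the energy-storage pattern:
lipid rises steeply with length (slope ≈ 11.9 mg/g/cm, P < 0.001), energy
density follows it (≈ 0.42 kJ/g/cm), while protein, glycogen and ash stay
flat. Outputs land as CSV tables under `results/`.

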