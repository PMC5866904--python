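# Methods

## The measurement problem

Serum gadoxetate concentration after an IV bolus declines biphasically: a
fast distribution phase over the first ~10 minutes, then a slower terminal
phase governed by elimination. Total body clearance (hepatic + renal) is the
primary liver-function readout; volumes of distribution and half-lives
complete the picture. All parameters are estimated noncompartmentally —
directly from areas and slopes of the observed curve — so no structural
model is imposed on the data being analysed. The structural model appears
only on the generative side, where it is needed to simulate realistic
cohorts.

## Generative model (simulation only)

Each subject is a two-compartment IV-bolus system parameterised by micro
constants: total clearance CL (mL/min), central volume Vc (mL), peripheral
volume Vp (mL) and distributional clearance Q (mL/min); Vss = Vc + Vp. With
k10 = CL/Vc, k12 = Q/Vc, k21 = Q/Vp, the concentration is the biexponential

    C(t) = A·e^(−α·t) + B·e^(−β·t),   α > β > 0,   C(0) = dose/Vc,

via the standard micro↔macro conversion (implemented in both directions;
round-trips to 1e−9 relative, and the Q → 0 limit collapses to
mono-exponential decay with rate CL/Vc).

Cohort defaults are the study design:

| quantity | default | unit | note |
|---|---|---|---|
| group sizes | 16 / 14 / 20 | animals | control / 70% / 90% hepatectomy |
| sampling times | 1, 3, 5, 10, 20, 30, 60, 90 | min | early-dense IV schedule |
| dose | 100 | µmol/kg | 0.1 mmol Gd/kg |
| body weight | 285 ± 20 | g | adult male Sprague-Dawley; one cohort-wide pair (group differences of ~10% would not affect CL, which is dose-independent) |
| group CL means | 12.7 / 6.8 / 2.7 | mL/min | generative truth per group |
| group Vss means | 269.7 / 189.1 / 142.1 | mL | generative truth per group |
| between-subject CV | 0.32 / 0.34 / 0.56 | – | per group, back-calculated from the observed CL SD/mean ratios; log-normal on CL and Vss (independently), parameterised so the *expectation* equals the group mean |
| assay CV | 0.10 | – | proportional log-normal, unit mean; a realistic ICP-MS precision |
| LLOQ | 1e−4 | µmol/L | 0.1 nmol Gd/L; effectively never censors the 90-min window at this dose |
| Vc fraction of Vss | 0.4 | – | see below |
| Q | 8.0 | mL/min | see below |

Vc/Vss = 0.4 and Q = 8 mL/min are not identifiable from group summary
statistics; they were fixed once so that the *implied* terminal-phase
quantities land on the observed scale: Vz = CL/β evaluates to 469/258/161 mL
and t½β to 25.6/26.3/41 min across the three groups, close to the observed
487.7/254.9/160.6 mL and 27.3/27.0/52.6 min. The early-time behaviour is
also consistent: C(1 min)/dose ≈ 7.2 L⁻¹ for controls against an observed
Cmax/dose of 8.0 ± 2.6.

Randomness follows a strict contract: one root seed; each subject draws from
a child stream keyed by (group index, subject index) via
`numpy.random.SeedSequence(entropy=seed, spawn_key=...)`, so a subject's
data do not change when *other* groups' sizes change. Identical config +
seed reproduces the cohort bit-for-bit. Optional uniform ±5% jitter on
nominal times models real sampling-time scatter (off by default; the
estimator always uses the recorded actual times). BLQ values are retained
with flags; masking is the consumer's decision.

What the generator does **not** emulate: correlated CL–Vss variability,
assay heteroscedasticity beyond a constant CV, time-dependent regeneration
during the sampling window, urinary-excretion data, or enterohepatic
recirculation. Passing recovery tests therefore demonstrates estimator
correctness under a biexponential truth with multiplicative noise — not
robustness to model misspecification in real animals.

## NCA conventions

- **C0 anchor.** Sampling starts at 1 min but areas integrate from t = 0;
  C0 is the log-linear extrapolation through the first two quantifiable
  points (exact for mono-exponential data). If those points are
  non-decreasing, C0 falls back to the first observation, flagged.
- **Trapezoids.** Per segment: linear rule dt·(c1+c2)/2 when concentration
  is non-decreasing, log rule dt·(c1−c2)/ln(c1/c2) when strictly decreasing
  (exact on exponential segments). Equal-concentration segments use the
  linear rule with a flag. AUMC applies the same assignment to the
  first-moment curve y = C·t, with a linear fallback whenever the product
  endpoints are equal or non-positive (always the case at t = 0).
- **λz selection.** Among all suffix windows of ≥ 3 quantifiable points
  strictly after the peak, the window maximising adjusted R² wins; exact
  ties prefer more points; windows with non-negative slope are excluded.
  The scan uses a reverse Welford accumulation (O(n), numerically stable),
  so dense 10⁴-point validation grids cost milliseconds. A fixed window can
  be supplied instead. Ĉ_last is the regression prediction at t_last
  (observed C_last available as an option).
- **Tails.** AUC_inf = AUC_last + Ĉ_last/λz. For AUMC the default tail is
  the closed form Ĉ_last·(t_last/λz + 1/λz²), i.e. the exact tail of an
  exponential decline from Ĉ_last. An alternative estimates a first-moment
  rate constant λz* by regressing ln(C·t) on t and uses (C·t)̂_last/λz*.
  The alternative is *not* the default because on sparse schedules the
  first-moment curve peaks near 1/λz (~30–60 min here), leaving at most two
  later samples, and where the regression is estimable at all its slope is
  ≈ λz − d(ln t)/dt — close to zero — so the tail is unstable and can
  inflate MRT several-fold; the closed form is the standard and is exact in
  the same limit in which λz itself is meaningful. When the λz* option is
  selected but not estimable, the closed form is used and flagged.
- **Eligibility and failure.** ≥ 3 quantifiable samples and a declining
  terminal window are required; anything less raises a structured
  not-evaluable error (reason code), never a partial result. Batch analysis
  collects failures into a separate table.
- **Quality flags.** C0 fallback, flat-segment linear fallback, BLQ
  exclusions, AUC extrapolation > 20% (flagged, not rejected — the 90%
  hepatectomy group legitimately exceeds it), terminal R² < 0.8, λz* tail
  fallback.
- **Units.** Concentrations µmol/L, time min, dose µmol; CL in mL/min and
  volumes in mL, with the single L→mL factor applied in one place
  (`derive_parameters`). t½,eff uses the conventional 0.693·MRT literal.

## Statistics

Group summaries are mean ± sample SD (n−1). The omnibus test is classical
one-way ANOVA (zero within-group variance handled explicitly: F = 0/p = 1
for equal means, F = ∞/p = 0 otherwise). Post-hoc tests are two-sided
pooled-variance Student's t per pair with Bonferroni adjustment
p_adj = min(1, m·p_raw), m = 3 for the three-group design (Welch is a
deliberate non-default: "Student's t" is the stated procedure). The CL–group
trend uses Spearman rank correlation with midranks — mandatory, since the
ordinal group coding (0/1/2) is massively tied — and the t-approximation
p-value. Significance threshold 0.050 two-sided throughout.

## Numerical validation choices

Validation profiles are geometric time grids from 1e−4/α to 15–25
half-lives of the slow phase, 6,000–12,000 points: dense enough that the
trapezoidal areas agree with adaptive quadrature to 1e−6 (AUC) / 1e−5
(AUMC) relative, and long enough that the extrapolated tail is < 1e−6 of
the total, isolating integration error from tail-formula error. On exact
mono-exponential input every derived parameter then matches its closed form
(CL = λ·V, Vss = Vz = V, MRT = 1/λ) to 1e−6 relative. Recovery tests under
the full design compare per-group sample-mean CL against the generative
mean at 2-SEM tolerance; measured estimator bias on CL is ≲ 1.5% per group
(integration and back-extrapolation biases largely cancel), small relative
to the 8–13% SEMs. Replicate counts (200 for design-level properties,
10,000 for the type-I-error simulation) keep the whole suite in the tens of
seconds while leaving binomial noise well inside the asserted margins.

## Liver-weight layer

Relative lobe weight is 100·lobe/total; combined resected fractions sum the
chosen lobes; the regeneration rate is 100·remnant/reference using the
control-group mean total liver weight as the reference — an approximation
forced by the absence of per-animal pre-operative liver weights, and the
reason reported regeneration is a cross-sectional, not longitudinal,
quantity. Reporting rounds to one decimal; arithmetic is unrounded (the
module reports the computed 66.0% for the 70%-group remnant even where
prose conventions would round to "about 65%"). A 5% dissection-loss
tolerance is enforced between the lobe sum and the measured total for
control records.

## Known limitations

- The generator and the estimator share the biexponential family; the test
  suite therefore cannot detect misspecification biases that would arise
  with, e.g., nonlinear (saturable) uptake — which the real agent may show
  at high dose.
- λz on the 8-point schedule carries a small α-phase contamination
  (≈ +1–2% for well-separated phases), visible in the slightly
  conservative Vz means.
- Concentrations are treated as serum throughout; no whole-blood
  correction is attempted.
- The statistical layer implements the study's procedures; it does not add
  normality diagnostics, log-scale testing or multiplicity control beyond
  Bonferroni.
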