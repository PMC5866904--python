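# gdnca

Noncompartmental pharmacokinetics of gadoxetate (Gd-EOB-DTPA) as a
quantitative liver-function readout in the rat partial-hepatectomy model.

Gadoxetate is a hepatobiliary MR contrast agent taken up by hepatic organic
anion transporters; how fast it disappears from serum after an IV bolus
reflects functional liver mass. In the graded hepatectomy model, defined
lobe combinations are resected (≈70% of liver mass: left lateral + median
lobes; ≈90%: additionally the right lobe) and serial blood samples are drawn
at 1, 3, 5, 10, 20, 30, 60 and 90 min after 0.1 mmol Gd/kg. This package is
for pharmacokinetic and imaging researchers who want that entire analysis —
cohort simulation, per-subject noncompartmental analysis (NCA), liver-weight
arithmetic, and three-group statistics — as tested, scriptable code.

## What it computes

Per subject, from the concentration–time curve alone (no compartmental
fitting):

- **Areas.** AUC_last and the first-moment area AUMC_last by the
  linear-up / log-down trapezoidal rule, anchored at an IV-bolus C0
  back-extrapolated log-linearly through the first two samples.
- **Terminal slope.** λz from ordinary least squares of ln C vs t over the
  terminal window with the best adjusted R² (all suffix windows of ≥ 3
  points after t_max are scanned; a fixed window can be forced).
- **Extrapolation.** AUC_inf = AUC_last + Ĉ_last/λz with Ĉ_last the
  regression-predicted last concentration; AUMC_inf adds the closed-form
  exponential tail Ĉ_last·(t_last/λz + 1/λz²) (a first-moment-regression
  λz* variant is available); AUC_extrapolated% = 100·(1 − AUC_last/AUC_inf).
- **Derived parameters.** CL = dose/AUC_inf, MRT = AUMC_inf/AUC_inf,
  Vss = CL·MRT, Vz = CL/λz, t½β = ln 2/λz, t½,eff = 0.693·MRT, plus Cmax,
  Tmax and dose-normalised quantities. Samples below the limit of
  quantification are flagged and excluded; quality flags record fallbacks,
  extrapolation > 20% and poor terminal fits.

Across subjects: group means ± SD, one-way ANOVA, pairwise pooled-variance
Student's t tests with Bonferroni correction, and a Spearman rank
correlation between CL and the ordered extent of hepatectomy.

Because no raw concentration data accompany the original experiment, the
package includes a first-class generator: a two-compartment IV-bolus model
(CL, Vc, Vp, Q; biexponential disposition C(t) = A·e^(−αt) + B·e^(−βt))
with group-dependent clearance and Vss, log-normal between-subject
variability, proportional assay noise and LLOQ censoring. Its defaults are
the study design itself (n = 16/14/20; CL means 12.7/6.8/2.7 mL/min; Vss
means 269.7/189.1/142.1 mL).

## Worked example

```python
from gdnca import CohortConfig, simulate_cohort, run_nca_cohort, compare_groups

config = CohortConfig(seed=42)
profiles = simulate_cohort(config)
parameters, failures = run_nca_cohort(profiles)
print(parameters.groupby("group")[["cl", "v_ss", "t_half_beta"]].mean().round(1))
report = compare_groups(parameters)
rho, p = report.spearman_cl
print(f"ANOVA p (CL): {report.anova['cl'][1]:.2e}")
print(f"Spearman rho (CL vs group): {rho:.3f}")
```

prints

```
           cl   v_ss  t_half_beta
group
control  13.0  242.6         24.1
hep70     5.8  187.6         33.1
hep90     2.6  133.9         44.4
ANOVA p (CL): 3.42e-13
Spearman rho (CL vs group): -0.889
```

Clearance falls roughly in proportion to remaining functional liver
(13.0 → 5.8 → 2.6 mL/min across control / 70% / 90% hepatectomy), the
steady-state distribution volume shrinks with the resected tissue, the
terminal half-life stretches as elimination slows, and the strongly negative
Spearman ρ says CL orders the three groups almost perfectly — the property
that makes gadoxetate clearance a liver-function test.

The same workflow is available from a shell:

```bash
gdnca all --seed 42 --out-dir out/   # simulate → nca → compare
```

which writes `cohort.csv`, `dosing.csv`, `parameters.csv`, `failures.csv`,
`report.json`/`report.txt` and a `manifest.json` (seed, config hash, input
hashes) making the run exactly reproducible.

Liver-weight arithmetic is a separate, deliberately simple layer:

```python
from gdnca import LiverWeightRecord, relative_lobe_weights
from gdnca.liver_weight import REFERENCE_LOBE_WEIGHTS_G, REFERENCE_TOTAL_WEIGHT_G

record = LiverWeightRecord(REFERENCE_LOBE_WEIGHTS_G, REFERENCE_TOTAL_WEIGHT_G)
print(relative_lobe_weights(record, rounded=True))
# {'left_lateral': 30.9, 'median': 33.1, 'right': 17.3, 'caudate': 6.4, 'paracaval': 11.0}
```

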