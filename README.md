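# nanopk

Formulation optimization and nose-to-brain pharmacokinetics for nanocrystal
drug-delivery studies, as a tested, reusable Python pipeline.

Nanocrystal formulations of poorly soluble CNS drugs are developed by
screening many process factors, optimizing the critical ones on a response
surface, and then showing in vivo that the intranasal formulation actually
delivers more drug to the brain than systemic redistribution alone would.
`nanopk` implements that whole computational chain:

* **`nanopk.doe`** — 12-run Plackett–Burman screening designs and inscribed
  central composite designs (CCD), with the coded↔natural transforms
  (factorial points at ±1, axial at ±α, α = 2^(k/4) for rotatability) and
  snapping of rounded printed levels back to canonical codes.
* **`nanopk.rsm`** — a statsmodels-style `ResponseSurfaceModel` fitting the
  quadratic polynomial

  y = β₀ + Σᵢ βᵢxᵢ + Σᵢ<ⱼ βᵢⱼxᵢxⱼ + Σᵢ βᵢᵢxᵢ² + ε

  on coded factors by OLS. Its `RSMResults` carries partial (Type III) sums
  of squares, the lack-of-fit / pure-error partition of the residual from
  replicated center points, R², adjusted R² and PRESS-based predicted R²,
  hierarchy-preserving backward elimination, and Derringer–Suich
  desirability optimization over the coded factorial cube.
* **`nanopk.nca`** — non-compartmental analysis (Cmax, Tmax, AUC₀→tlast,
  AUMC, MRT by the linear trapezoid rule), including pooling of sparse
  destructive brain sampling (one animal per time point) into a mean
  profile.
* **`nanopk.targeting`** — direct nose-to-brain transport indices

  %DTE = 100·[(AUC_brain/AUC_plasma)_i.n.] / [(AUC_brain/AUC_plasma)_i.v.],
  %DTP = 100·(B_i.n. − Bx)/B_i.n.,  Bx = (B_i.v./P_i.v.)·P_i.n.,

  with calibration of the i.v. reference ratio from a formulation whose
  %DTE is already published.
* **`nanopk.quality`** — % yield, dosing-precision %RSD, stability %-bias.
* **`nanopk.compare`** — one-way ANOVA with Tukey HSD (Tukey–Kramer for
  unequal n) and the exact Wilcoxon rank-sum test (tie-aware enumeration).
* **`nanopk.synthetic`** — generators for quadratic-surface responses and
  one-compartment extravascular PK studies with lognormal between-subject
  variability, for end-to-end testing without any raw data.
* **`nanopk.datasets`** — the printed summary tables of a published
  rufinamide nanocrystal study (20-run CCD with particle sizes, four-arm
  brain/plasma AUC summary, stability series) used as worked-example
  inputs and regression anchors.

## Worked example

Fit and reduce the particle-size model on the bundled 20-run CCD, then
locate the minimizing settings:

```python
from nanopk import datasets, ResponseSurfaceModel

design = datasets.ccd_design()
table = datasets.ccd_particle_size()
res = ResponseSurfaceModel.from_dataframe(
    design, table, "particle_size").fit().reduce(0.05)
print(res.summary())
opt = res.optimize("minimize")
```

which prints

```
Response-surface fit: particle_size (20 runs, 4 terms)
particle_size = 486.73 + 171.08*hpmc_conc - 23.57*ultrasonication_time - 30.86*ultrasonication_time^2

                        sum_of_squares  df  mean_square     F         p
source
model                        4.213e+05   3    1.404e+05 62.04 4.962e-09
hpmc_conc                    3.997e+05   1    3.997e+05 176.6 4.629e-10
ultrasonication_time              7585   1         7585 3.351   0.08585
ultrasonication_time^2       1.397e+04   1    1.397e+04 6.174   0.02442
residual                     3.621e+04  16         2263
lack_of_fit                  3.217e+04  11         2925 3.617   0.08345
pure_error                        4043   5        808.6
total                        4.575e+05  19

R-squared             0.9208
Adjusted R-squared    0.9060
Predicted R-squared   0.8434
PRESS               7.163e+04
```

Backward elimination keeps the linear ultrasonication term (p = 0.086)
because its quadratic is significant — the hierarchy rule. The model is
significant (F = 62.04) with insignificant lack of fit (p = 0.083), i.e.
the quadratic surface explains the design-point means down to replicate
noise. The optimum sits at the cube corner coded (−1, +1): 0.485 % w/v
stabilizer, 12.97 min ultrasonication, temperature (no model term) at the
10 °C region center, predicting a 261.2 nm particle size.

Targeting indices from the bundled four-arm AUC summary:

```python
from nanopk import FormulationPK, calibrate_iv_ratio, dtp

iv = calibrate_iv_ratio(FormulationPK("nc-susp", 340.7, 258.2), 373.16)
print(dtp(FormulationPK("nc-gel", 471.3, 192.3), iv))
# TargetingIndices(dte_percent=693.06..., dtp_percent=85.57..., bx=68.00...)
```

A %DTE of ~693 % means the nasal gel's brain:plasma exposure ratio is
almost seven times the intravenous one, and %DTP ≈ 86 % of its brain
exposure is attributable to direct nose-to-brain transport.

The same pipeline is scriptable from the shell:

```sh
nanopk design ccd factors.yaml --out design.csv
nanopk fit design.csv response.csv --outdir out/
nanopk optimize design.csv response.csv --goal minimize
nanopk simulate --seed 1 --outdir study/
nanopk nca study/concentrations.csv
nanopk dte formulations.csv --calibrate-from Rufi-NC-Susp
```

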