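# Methods

This note documents the statistical models and procedures `nanopk`
implements, the conventions and defaults it fixes where several are in
circulation, and what its synthetic generators do and do not emulate.

## Experimental designs and coding

A factor is stored as a coding transform `natural = center + step·coded`.
The **inscribed CCD** maps the user's natural bounds onto the axial points:
`center = (low+high)/2`, `step = (high−low)/(2α)`, so coded ±α hits the
bounds exactly and the 2^k factorial corners (coded ±1) are interior.  The
axial distance defaults to the rotatable choice α = 2^(k/4) (1.6818 for
k = 3).  Runs are emitted in conventional standard order — Yates-ordered
factorial block, axial pairs in factor order (low before high), center
replicates last — so published standard-order tables align row-for-row.
The linear coded columns are exactly orthogonal with Σx² = 2^k + 2α²
(13.657 for k = 3), which the test suite verifies by direct summation.

The **Plackett–Burman** 12-run design is built by cyclic rotation of the
standard N=12 generator row `+ + − + + + − − − + −` plus an all-minus run.
Columns beyond the requested factor count are retained as dummy columns.
Published PBD layouts vary by generator and column assignment; this is the
standard construction, not a claim to match any particular software's
(usually unpublished) layout.

**Snap-to-canonical coding.** Published design tables print natural levels
rounded to 2–3 significant figures.  Re-deriving codes from such values
gives e.g. 0.9754 instead of +1, and OLS on those perturbed codes does not
reproduce coefficients computed on the canonical design.  `to_coded`
therefore snaps a re-derived code to {0, ±1, ±α} when it falls within a
relative tolerance of the canonical level.  The default tolerance is **3 %**:
the bundled study's printed level "12.9 min" codes to 0.9754 on a step of
2.973 min/unit, i.e. 2.46 % from +1, so a 2 % tolerance would fail to
recover the canonical design while 3 % recovers it exactly.  3 % is still
far below half the spacing between any two canonical levels, so no level
can snap ambiguously.

## Response-surface model

The model is the full second-order polynomial in coded factors
(intercept, k linear, C(k,2) interaction and k quadratic terms),
fitted by ordinary least squares (statsmodels OLS under the hood; the
model matrix, ANOVA and diagnostics are built here).  Conventions, chosen
to match mainstream designed-experiment software:

* **Per-term partial (Type III) SS**: SS_j = β̂_j² / [(XᵀX)⁻¹]_jj, tested
  against the residual mean square.  On the bundled study this is the only
  choice that reproduces the published quadratic-term SS (13973.18)
  together with the orthogonal-term values.
* **Model SS** = corrected total SS − residual SS (so model + residual =
  total holds identically, verified to 1e−6 relative in tests).
* **Pure error** from replicate groups (runs with identical coded rows):
  Σ within-group squared deviations, df = Σ(group size − 1).  **Lack of
  fit** is the remainder of the residual, tested against pure error.  With
  no replicate group of size ≥ 2 the lack-of-fit rows are reported as
  undefined (NaN), never as zero.
* **R² family**: adjusted R² = 1 − (SSres/(n−p))/(SStot/(n−1)); PRESS via
  the leverage identity Σ(e_i/(1−h_ii))², equal to n explicit leave-one-out
  refits (asserted against that brute-force oracle in the tests);
  predicted R² = 1 − PRESS/SStot.
* p-values from the F distribution; the `summary()` renderer shows them in
  scientific notation rather than the "<0.0001" style of commercial
  reports.

**Model reduction** is backward elimination: refit after dropping the
non-intercept term with the largest partial-F p-value above `alpha_keep`
(default 0.05), under the hierarchy rule that a linear term is never
dropped while its quadratic or any interaction containing its factor
remains.  Ties are broken by canonical term order (linear < interaction <
quadratic, then factor index), making the elimination path deterministic.

**Desirability optimization** uses the Derringer–Suich transform of the
model prediction — a one-sided ramp for minimize/maximize anchored at the
predicted extremes over the search region (exponent 1 by default; the
original software's exponents are typically unstated, and 1 is the neutral
choice), a two-sided tent for target — maximized by dense grid search
(21 points per active factor) refined with bounded L-BFGS-B polish.  The
grid+polish optimum matches analytic interior vertices to 1e−6 in tests.
The search region defaults to the coded factorial cube [−1, 1]^k rather
than the axial sphere: factor settings outside the factorial box are
extrapolations in the inscribed design sense, and on the bundled study the
cube corner is exactly the reported optimum while the axial region would
push the stabilizer to its extreme.  Factors with no term in the fitted
model are reported at the region center and flagged as unconstrained.  A
flat desirability surface returns the region center with a degeneracy flag.

## Non-compartmental analysis

Linear trapezoid on C(t) and t·C(t) from the first time to the last
quantifiable point; Cmax/Tmax with the earliest-time tie-break;
MRT = AUMC_last/AUC_last.  Choices fixed here:

* **Linear, not lin-up/log-down, trapezoids** for both AUC and AUMC — the
  reproducible default when the originating software's rule is unknown;
  log-down integration would change AUC by a few percent on sparse decline
  phases.
* **No extrapolation to infinity, no λz**: sparse destructive designs
  cannot support terminal-slope estimation, so all metrics are "to tlast"
  and MRT is MRT_last.
* **BLQ rules**: below-quantification points before the first quantifiable
  point and embedded ones count as 0; trailing BLQ points are excluded
  (they shorten tlast).  A missing pre-dose sample is assumed 0 at t = 0.
* **Destructive pooling**: brain profiles are the per-time mean over the
  animals sacrificed at that time; NCA on the pooled mean is a point
  estimate without a standard deviation (per-time n and SD are carried as
  metadata, but no Bailer-type sparse variance is computed).  With a shared
  full schedule, pooled AUC equals the mean of per-subject AUCs by
  linearity of the trapezoid — a test asserts this.
* Arm summaries report mean ± sample SD per parameter, with Tmax shown as
  a `lo-hi` range when subjects differ.

## Targeting indices

%DTE = 100·(B_i.n./P_i.n.)/R_iv and %DTP = 100·(B_i.n. − R_iv·P_i.n.)/B_i.n.,
where R_iv = B_i.v./P_i.v. is the intravenous brain:plasma AUC ratio.  Only
the ratio is identifiable from these formulas, so the reference enters as a
ratio (a constructor from the AUC pair exists).  When the i.v. study is
published only through derived indices, `calibrate_iv_ratio` inverts the
%DTE formula on a formulation with known %DTE; on the bundled study the
ratio calibrated from the nanocrystal-suspension arm (0.35361) reproduces
the other three arms' published indices to printed rounding.  The identity
%DTP = 100 − 10000/%DTE holds exactly for every computed pair and is
enforced as a property test.  Brain AUC is per gram tissue and plasma per
mL; their quotient is used as such, with no tissue-density correction —
matching how these indices are conventionally reported.

## Quality metrics

% yield is recovered-pellet mass over charged mass ×100.  (Some reports
print the complementary loss fraction under the same name while quoting
recovery-scale values; the `as_printed` flag exposes that form, but the
recovery convention is the default because the pellet is the product and
reported yields of ~90 % are only consistent with it.)  %RSD uses the
sample (n−1) standard deviation.  Stability %-bias is measured against the
day-0 value of each series (the nominal specification would be an
alternative baseline; day-0 is what stability tables print), passing when
|bias| < threshold (default 5 %) at every point.

## Group comparisons

One-way fixed-effects ANOVA with the standard between/within partition
(all-equal data reports F = 0, p = 1 rather than NaN).  Tukey HSD uses the
studentized-range distribution with the Tukey–Kramer standard error for
unequal group sizes; for two groups q = √2·|t| exactly.  The Wilcoxon
rank-sum test enumerates the exact null distribution of the rank sum over
all C(n+m, n) assignments with mid-ranks for ties (combined n ≤ 20;
C(20,10) ≈ 1.8×10⁵ assignments), with p = 2·min(P(W ≤ w), P(W ≥ w)) capped
at 1; larger samples use the tie-corrected normal approximation with
continuity correction.  All tests are two-sided at α = 0.05 by default.

## Synthetic study generators

`simulate_rsm` draws y = Xβ + N(0, σ²) on a design's coded levels —
exactly the model the RSM ANOVA assumes, so it exercises estimation, the
lack-of-fit partition and coefficient-recovery properties, but not
model-form misspecification or variance heterogeneity.

`simulate_pk_study` draws per-animal one-compartment extravascular curves
C(t) = C0·ka/(ka−ke)·(e^(−ke·t) − e^(−ka·t)) with median-preserving
lognormal between-subject variability on (C0, ka, ke) and proportional
residual error, then samples a dense plasma schedule (5, 15, 30, 45, 60,
120, 240, 360, 480, 600 min) per subject and a sparse destructive brain
schedule (30, 60, 120, 240, 480 min, n = 4 distinct animals per point)
with brain concentration = partition ratio × that animal's plasma curve.
Defaults emulate the study conditions the package targets: 1 mg/kg nasal
dosing in rats, n = 4 plasma subjects; ka = 0.04 min⁻¹ and ke = 0.008 min⁻¹
put Tmax ≈ 50 min inside the observed 30–60 min window; C0 = 1.34 µg/mL
scales the noiseless Cmax to ≈ 0.9 µg/mL; partition ratio 1.4 matches the
observed brain:plasma Cmax quotient; between-subject CV 25 % reproduces
the reported AUC dispersion; residual CV 10 % is a typical bioanalytical
error.  The generator does **not** emulate a distinct direct
nose-to-brain uptake pathway (brain is a pure scaling of plasma, so the
implied %DTE is ~100 % up to sampling-grid truncation), enterohepatic or
multi-compartment disposition, BLQ censoring, or correlated PK parameters
— so passing recovery tests demonstrate correct estimation under the
stated model, not realism of any particular in vivo claim.

All generators are bit-reproducible given a seed (`numpy.random.default_rng`).

## Problem sizes and numerical tolerances

The bundled design analyses are 20-run OLS fits and complete in
milliseconds.  Simulation-based properties use 200 replicates for
coefficient recovery (asserting each |bias| < 2 Monte-Carlo SE), 100
simulated studies for the PK pipeline, and 2000 null replicates for the
ANOVA type-I-error check (rate 0.05 within ~3 binomial SE); these sizes
give standard errors comfortably below the asserted tolerances while the
whole suite runs in seconds.  ANOVA decomposition identities are asserted
to 1e−6 relative; closed-form NCA comparisons use 1 % (AUC) and 2 % (MRT)
on dense grids, reflecting trapezoid discretization rather than
implementation error.

## Known limitations

* The CCD builder enumerates the full factorial block (k ≤ 12 enforced);
  fractional-factorial composite designs, blocking, Box–Behnken and
  D-optimal designs are out of scope.
* Desirability optimization handles one response; multi-response weighting
  is not implemented.
* No λz/extrapolated AUC, no bioequivalence statistics, no sparse-sampling
  variance for pooled brain NCA.
* The exact Wilcoxon enumeration is O(C(n+m, n)) and capped at combined
  n = 20.
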