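# Methods

This note documents the models, numerical choices and limitations behind
`ch4meta`. It is the package's own account of its science; every number
mentioned here is computed by the test suite or the scripts, not asserted
from memory.

## Problem setting

Enteric methane (CH4) from cattle is a major agricultural greenhouse-gas
source, and direct measurement (respiration chambers, SF6 tracer) is too
expensive for routine inventory work. The standard alternative is empirical
prediction: regress measured CH4 output (MJ/day) on feed-intake and
diet-composition variables across a meta-analytic database of published
treatment means, then use the fitted equations — or evaluate existing ones
(e.g. the IPCC Tier 2 model, CH4 = 0.065 × GEI) — on new records.
`ch4meta` implements that entire desk workflow for beef, dairy and combined
cattle databases.

The experimental unit throughout is the *treatment mean*: the average
response of one dietary treatment within one source study, backed by a known
number of animals. Treatment means from the same study share design,
laboratory and animal-population effects, which is why every model carries
study-level random effects.

## Record harmonization

Published records are heterogeneous, so a fixed calculus completes what is
derivable (all energies MJ/day, chemistry g/kg DM, digestibilities g/kg):

- GE concentration from chemistry:
  `(23.6 CP + 39.8 EE + 17.3 NFC + 18.9 NDF) / 1000` MJ/kg DM;
  GE intake = DMI × concentration.
- Energy balance: `DEI = GEI − FE`, `MEI = DEI − CH4 − UE`, `q = MEI/GEI`.
  (The source literature prints the first identity with MEI on the
  right-hand side; that is dimensionally and physiologically impossible and
  is read as a typographical corruption of the standard digestible-energy
  balance.)
- Feeding level `FL = MEI / ME_m` with maintenance requirement
  `ME_m = 0.53 (BW/1.08)^0.67 / (0.35 q + 0.503)`; this is the only
  parenthesization of the printed expression in which 0.53 MJ/(kg/d) acts as
  a maintenance scale and FL is dimensionless. At MEI = 100 MJ/d, BW = 500
  kg, q = 0.55 it gives FL ≈ 2.148.
- Digestibility imputation regressions, applied in a fixed precedence order
  (OM←GE, GE←OM, GE←DM) cascading to a fixed point, never overwriting
  observed values.
- Intake adjustment of OM digestibility to the maintenance level:
  `OMDm = OMD + 1.83 (DMI/BW − DMI/BW at FL=1)` with DMI/BW in g/kg and the
  maintenance reference `13.8 + 2.195 × FL` evaluated at FL = 1 (15.995 g/kg).
- Unit conversions with the conventional constants 0.714 g/L, 39.54 kJ/L,
  55.65 kJ/g, 4.184 kJ/kcal. These are mutually inconsistent
  (0.714 × 55.65 = 39.73 ≠ 39.54); litre↔energy conversions therefore use
  39.54 directly and are never chained through grams, so every pairwise
  round trip is exact to machine precision even though the three-way
  triangle cannot close.

Harmonization is idempotent, flags every filled cell in a provenance sidecar
(`observed` / `derived` / `imputed`), and refuses records whose observed
energy fields violate an identity by more than 0.5% relative (rounding of
published means motivates the tolerance). Records lacking diet chemistry are
passed through flagged, not filled from feed tables.

## Equation registry

All 7 extant equations (Mills linear and monomolecular, IPCC 2006 Tier 2,
Ellis, Yan, Ramin & Huhtanen quadratic, Patra monomolecular) and all 37
developed equations (11 beef, 14 dairy, 12 combined) are stored with their
printed coefficients and evaluated by form:

- monomolecular `a − (a+b) e^{−cx}` (the running-text rendering of this form
  is corrupted in the source; the shape used is the one both printed
  monomolecular rows instantiate — Mills is exactly the Mitscherlich special
  case `b = 0`);
- Gompertz `b·exp{[1 − e^{−cx}] ln[(a+2b)/b]} − 2b`, which has value `−b` at
  x = 0 and asymptote `a`;
- exponential `|b| e^{cx}`: every printed exponential row carries a negative
  scale coefficient, which would force negative methane. The registry stores
  the printed value, exposes a `sign_anomaly` flag, evaluates `|b|`, and a
  `literal_sign=True` switch restores the printed sign for audit;
- power `b x^c`; linear/quadratic forms as printed.

Fiber intakes (NDFI, ADFI, kg/day) are computed as DMI × concentration/1000
when not supplied. Predictions are never clipped; extrapolation policy is
the caller's.

## Synthetic databases

The original 149-treatment database is not publicly deposited; the generator
produces surrogate databases whose structure matches what the analysis
assumes, calibrated to the published per-database summary table
(mean/min/max/SD for every variable).

- **Marginals** are truncated normals. The underlying location/scale are
  solved numerically so that the *truncated* distribution has the published
  mean and SD. This matters: using the printed moments as untruncated
  parameters would shift every skewed variable (combined DMI from 10.28 to
  ≈11.2 kg/day). One variable (ether-extract digestibility: mean 759, SD
  172 on [82, 942]) admits no exactly-matching truncated normal; the
  least-squares-closest fit is used and a warning emitted.
- **Composition closure**: NFC = OM − CP − EE − NDF, clipped to the
  calibration range. When the closure residual falls below the NFC minimum,
  CP/EE/NDF are shrunk toward their own calibration minima so that
  CP + EE + NDF + NFC ≤ OM holds exactly for every record. ADF is capped at
  NDF.
- **Correlation is induced structurally**, not by a copula (only pairwise
  correlations are published, not a joint distribution): OM digestibility is
  linked negatively to diet NDF (assumed r = −0.5 — fibrous diets digest
  worse); GE and DM digestibility follow the harmonization regressions plus
  their reported residual scatter (7.9 and 32.8 g/kg); and CH4 is generated
  *from* DMI through a true equation, which reproduces the strong published
  DMI–CH4 correlation.
- **Methane**: `CH4 = f(x) + s_i + b_i·DMI + e`, with `f` the database's own
  DMI-only linear equation by default (DM intake is the best single
  predictor in this literature), study intercept `s_i ~ N(0, 0.6²)` MJ/d,
  study slope `b_i ~ N(0, 0.08²)` (MJ/d)/(kg/d), residual `e ~ N(0, 0.8²)`
  MJ/d, floored at 0.1 MJ/day. The noise SDs are not published; these
  defaults were chosen so that CH4 stays positive over the whole DMI range —
  the floor is then essentially inactive (≈2 in 10,000 records) and the
  Gaussian error model is self-consistent. Real literature scatter around
  a single-predictor equation (RMSE ≈ 3 MJ/d) is larger because it includes
  measurement-method and breed heterogeneity the generator does not emulate;
  parameter-recovery results on these surrogates are therefore a best-case,
  not a field, statement. When the true equation uses MEI the mutual
  definition CH4 ↔ MEI (= DEI − CH4 − UE) is solved by fixed-point
  iteration.
- **Energy chain**: GEI from chemistry; DEI = GEI × GE digestibility;
  urinary energy assumed 4% of GEI (a conventional ruminant value; not
  published per record); MEI by balance; q, FL, OMDm and all CH4 unit
  variants derived with the harmonization constants, so generated tables are
  internally consistent and harmonization-stable.
- Animal counts per treatment are uniform on [4, 16] and used only as
  weights. A config plus seed fully determines the output.

## Linear mixed-effects development

The development model is
`Y_ij = B0 + B1 X_ij + B2 X_ij² + s_i + b_i X_ij + e_ij`
with study random intercept/slope (unstructured or independent covariance)
and residual variance σ²/w_ij, where w_ij is the animal count — standard
meta-analytic precision weighting (the alternative reading of
"adjusted for the number of animals", an offset, has no natural scale here).
Estimates are invariant to rescaling all weights.

Estimation is REML with σ² profiled out, optimized over relative variance
components (log-SD / tanh-correlation parameterization, L-BFGS-B from a
small deterministic start grid; batched per-study linear algebra when group
sizes are equal). statsmodels' `MixedLM` cannot weight residuals, so the
engine is in-package; at unit weights it reproduces statsmodels' REML fit to
high precision (cross-checked in the tests). Under the default `auto`
covariance policy the unstructured model is fitted first and the fit falls
back to independent components when the unstructured fit fails or its
intercept–slope covariance is not significant (REML likelihood ratio,
α = 0.10).

Supporting procedure:

- **Outlier screen**: Cook's distance on the fixed-effects (weighted)
  regression with an explicit D > 4/n rule replacing the source procedure's
  visual inspection; the cutoff is configurable and flagged records are
  reported, never silently dropped. Computed via the exact √w-transformed
  OLS; verified against the leave-one-out definition.
- **Collinearity**: VIF = 1/(1 − R²_k) from auxiliary regressions with
  intercept; candidate sets are trimmed below 10 before any mixed fit; exact
  collinearity reports ∞ (ties drop the later-listed candidate).
- **Backward elimination**: the fixed term with the largest Wald p above the
  stay level is dropped and the model refitted, with the study random slope
  riding on the first surviving candidate. The stay level defaults to 0.05,
  the common backward-elimination convention (the source procedure states a
  threshold only for its random-slope/quadratic screen, which is kept at
  0.10 and applied via `screen_random_and_quadratic`: Wald test for the
  quadratic term, REML LRT for the random slope). The trace records every
  fit and decision and is deterministic given the data.
- Fixed-effect p-values are Wald (normal) — degrees-of-freedom corrections
  are not attempted and this is flagged in the summary convention below.
- **R²** is reported as the squared correlation between observed response and
  fixed-effects predictions; mixed-model R² conventions differ and published
  values may use another one. RMSE is the residual SD at unit weight.

## Nonlinear mixed models

Monomolecular, Mitscherlich, Gompertz, exponential and power forms relate
CH4 to DM or ME intake, with independent Gaussian study-level deviations on
the curve parameters. The marginal likelihood uses a Laplace approximation:
per-study random deviations are found by damped Gauss–Newton on the
penalized residual, the Hessian uses the Gauss–Newton approximation, and the
outer problem (fixed parameters, log random SDs, log σ) is solved
derivative-free. The fallback chain is: all parameters random → `b` only →
fixed-effects nonlinear least squares. Initial values come from a
deterministic 10×10×10 log-spaced grid over data-driven bounds (asymptote
forms) or closed-form log/log-log regressions (exponential/power) — no
randomness. Model choice across forms is by minimum BIC among converged
fits, ties toward fewer parameters.

## Evaluation calculus

MSPE = Σ(O−P)²/n; RMSPE% = 100·√MSPE / mean(O). The decomposition into mean
bias (ECT), slope bias (ER) and random error (ED) and the concordance family
(CCC = r·Cb, Cb = 2/(v + 1/v + μ²)) use **population (divide-by-n) SDs**
throughout so that ECT + ER + ED = MSPE is an exact algebraic identity; the
convention is otherwise unstated in the literature this follows. The
location shift is μ = (Ō − P̄)/√(S_o·S_p), the only sign convention in which
negative μ means overprediction; the scale shift is Lin's v = S_o/S_p.
Records missing a predictor are dropped per equation (not imputed at
evaluation time) with the per-equation n reported. Correlation screens
report R² as r²; a published variant of that column is internally
inconsistent with its own r column and is not imitated.

## Problem sizes and reproducibility

Default analysis-scale runs use 30 studies × 5 treatments (150 records,
matching the scale of the 149-record literature database); calibration
checks use 10,000 records (2,000 studies); recovery simulations use 50
seeded replicates with elimination checked on 20. All randomness in a
pipeline run flows from one seed split deterministically per stage;
`scripts/acceptance.py --seed N --out f.json` regenerates the 10,000-record
calibration draw and reports the CH4/DMI/BW sample means.

## Known limitations

- The generator draws BW, roughage and the minor diet fractions
  independently of DMI; real records correlate them. Downstream, this makes
  noise-predictor rejection in backward elimination *easier* than on real
  data.
- Between-study heterogeneity is additive and Gaussian; no
  measurement-method (chamber vs SF6) or breed strata are simulated.
- The Laplace nonlinear engine reports no standard errors for the random
  structure and uses a diagonal random-effect covariance.
- Published coefficient tables are reproduced as printed, including a small
  number of internally inconsistent entries (negative exponential scales,
  R² discrepancies between table and text); these are surfaced, not
  reconciled.
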