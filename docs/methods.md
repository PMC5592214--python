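# Methods

## The flux model

The JST-S network couples five sub-systems: glycolysis (EMP), the pentose
phosphate pathway, pyruvate metabolism, the TCA cycle, and the periplasmic
ethanol oxidation chain (PQQ-ADH oxidising ethanol to acetaldehyde, `p15`,
and ALDH oxidising acetaldehyde to acetate, `p16`). The published analysis
treats it as a *determined* system: exactly as many independent linear
constraints (33) as flux variables (33), so the fluxes follow from the
measured exchange rates by a single linear solve, with no optimisation or
least-squares reconciliation involved.

The 33 rows are:

- **15 pool balances** (G6P, F6P, Ru5P, G3P, PEP, Pyr, AcCoA, acetaldehyde,
  Cit, Isoc, αKG, Suc, Fum, Mal, OAA): production − consumption = 0 under
  the pseudo-steady-state assumption.
- **5 fixed branch ratios** written into the published equation set
  (`p2 = p3`, `p4 = 0.5 p5`, `p8 = 6 p9`, `4 p12 = p13`, `p11 = p14`).
  These are empirical closure relations, not stoichiometry; they are
  implemented verbatim. The lumped `p11 = p14` route carries pyruvate
  directly to acetate without passing the acetaldehyde pool, and the 0.5/6/4
  factors have no stated mechanistic rationale — all are reproduced as
  given, without biological interpretation.
- **9 biomass drains** `p_k = c_pool · p33` withdrawing precursors (G6P,
  F6P, Ru5P, G3P, PEP, Pyr, AcCoA, OAA, αKG) in fixed proportion to the
  biomass flux. The coefficients are dimensionless multipliers taken from
  the literature rather than measured here.
- **4 exchange rows** binding `p1`, `p15`, `p14 + p16` and `p33` to the
  measured glucose uptake, ethanol uptake, total acetate formation and
  biomass formation rates (all mmol gDW⁻¹ h⁻¹).

Cofactors (NAD(P)H, ATP, FAD, CoA, CO₂, …) appear in the reaction
annotation strings only; the published equation set carries no cofactor
balance rows, so none are modelled. All fluxes are written
forward-positive; the algebra permits negative solutions, which are
reported as warnings rather than rejected, since the method itself imposes
no sign constraints.

### Coefficient reconciliation

The published equation listing contains three internal inconsistencies,
resolved here in favour of whichever reading closes the balances on the
published solved flux vectors:

1. **PEP drain index.** The PEP balance is listed with the drain `p29`, but
   `p29` is the *pyruvate* drain (it already appears in the pyruvate
   balance), and the published vectors satisfy the PEP balance only with
   `p28` (0.4384 − 0.3708 − 0.0618 − 0.0058 = 0). The model uses `p28`.
2. **Ru5P/F6P drain labels.** The drain-equation labels assign `p25` to F6P
   (0.001644) and `p26` to Ru5P (0.008948), but the F6P and Ru5P *balance*
   rows use `p26` and `p25` respectively, and the published values
   (`p25` = 0.0075 ≈ 0.008948 × 0.8401, `p26` = 0.0014 ≈ 0.001644 × 0.8401)
   match the balance-row usage. The balance-row assignment wins.
3. **Pyruvate and OAA drain coefficients.** The published coefficients
   0.03604 (Pyr) and 0.01959 (OAA) imply drains of 0.0303 and 0.0165 at
   `p33` = 0.8401, but the published drains are 0.0072 and 0.0016. The
   `reconciled` set replaces them with the values implied by the published
   fluxes themselves, 0.0072/0.8401 ≈ 0.008571 and 0.0016/0.8401 ≈ 0.001904.

Items 1–2 are part of the model topology (both coefficient sets use them);
item 3 is what distinguishes `reconciled` from `as_printed`. With the
reconciled set the solved fluxes match the published table within 5×10⁻⁴
(half a unit of its 4-decimal printing) for all 33 fluxes of both strains;
with `as_printed`, exactly the pyruvate and OAA drain equations fail
(residuals ≈ 0.023 and ≈ 0.015) and the solved lower network deviates
accordingly. Every solution records which set produced it. Note the
published table is itself only ~2×10⁻⁴ internally consistent (its worst
equation residual, at the `4 p12 = p13` row), so two published entries —
engineered `p8` = 0.3708 and original `p7` = 0.4859 — differ from the exact
solution in the fourth decimal by one unit; agreement is to the printed
precision, not bit-exact rounding.

## Rate estimation

The net-change rule: for species with molar mass `M` (g mol⁻¹), window
`(t₁, t₂)` (h) and biomass `X̄` (gDW L⁻¹),

    rate = ± (C(t₂) − C(t₁)) · 1000 / M / (t₂ − t₁) / X̄ ,

signed so uptake (glucose, ethanol) and formation (total acid) are both
positive in their nominal direction. Choices the published rule leaves
open:

- **Window**: default 48–60 h, the high-rate, near-stationary stretch of
  these fermentations; endpoints between samples are linearly interpolated.
- **Biomass averaging**: `X̄` is the trapezoidal time-average over the
  window — equal to the constant under stationarity and to the midpoint
  value under linear drift, which makes the zero-noise recovery of
  generator rates exact even with drifting biomass.
- **Total acid** (a titration measurement) is converted as acetic acid
  equivalents, `M` = 60.05 g mol⁻¹; glucose 180.16, ethanol 46.07.
- **Estimator**: the two-point difference is the rule and the default; an
  OLS slope over ≥3 samples is available for noisy data (flagged in the
  output, with a standard error).
- **Biomass rate**: the published biomass flux (0.8401 for both strains) is
  not re-derivable from the printed wet weights (1.6 / 1.54 g L⁻¹ at 48 h),
  so the case study takes ΔBM as given. When estimated from a course, the
  same net-change rule applied to biomass gives a specific growth rate
  (h⁻¹), which is not guaranteed to be on the published scale — the
  docstring says so and the explicit value is preferred. No wet-to-dry
  conversion factor is assumed; callers must supply gDW values.

`check_pseudo_steady_state` verifies the premise behind the rule: relative
biomass change over the window within a tolerance (default 10%).

## Synthetic data

The generator emulates exactly the regime the rate rule is valid in:
zero-order (linear) concentration dynamics at
`rate · M · X(t) / 1000` g L⁻¹ h⁻¹ with constant or linearly drifting
biomass, plus independent additive Gaussian noise per instrument. Default
noise SDs are instrument-scale choices, not fitted values: 0.05 g L⁻¹
(HPLC glucose), 0.2 g L⁻¹ (GC ethanol), 0.5 g L⁻¹ (titrated total acid),
noise-free biomass. Default sampling is five points over 48–60 h at
1 gDW L⁻¹ biomass, with initial concentrations (glucose 3, ethanol 20,
total acid 35 g L⁻¹) placed so the engineered-strain rates keep all
trajectories positive over the window. Concentrations that would go
negative are clipped at zero with a warning. All randomness flows through
an explicit seed; replicate seeds are spawned via `SeedSequence`.

What the generator does **not** emulate: lag/exponential/decline phase
kinetics, product inhibition, substrate exhaustion, autocorrelated or
heteroscedastic instrument error, and evaporation. Passing recovery tests
therefore shows the estimator is correct *under the rule's own
assumptions*; it does not validate the pseudo-steady-state assumption for
any real fermentation — that is what `check_pseudo_steady_state` is for on
real data.

With two samples and noise σ on one species, the two-point estimator's SD
has the closed form √2 · σ · 1000 / (M · Δt · X); the Monte-Carlo recovery
experiment (2000 replicates in the tests) reproduces it within 15%.

## Numerical choices

- Dense LU solve; singularity = numerical rank deficiency (SVD-based, at
  machine precision scaled by the matrix), reported with the implicated
  rows. Condition number always reported; warning above 10⁸ (the reference
  model's is ~1.4×10²).
- Re-substitution residual of every returned solution must be ≤ 10⁻⁹
  (warning threshold 10⁻⁶); published-vector consistency threshold 10⁻³
  (4-dp rounding noise across a handful of terms); published-table
  comparison tolerance 5×10⁻⁴ (half-ULP of 4-dp printing).
- Report rounding is 4 decimals, round-half-even, with full precision
  always emitted alongside.
- Model files serialise coefficients as decimal strings at 12 significant
  digits, which round-trips every coefficient in use losslessly.

## Problem sizes

The test suite and acceptance script run the 33×33 case-study solves (well
under a second each), 100 random systems up to 33×33 for the solver oracle,
and 2000-replicate Monte-Carlo recovery at two samples per replicate —
chosen as the smallest sizes at which the closed-form SD check is sharp at
its 15% tolerance.

## Known limitations

- The model is the published determined system, not a genome-scale
  reconstruction: no cofactor/redox or energy balancing, no reversibility,
  no flux variability or uncertainty propagation beyond the linear
  sensitivity scan. An overdetermined weighted-least-squares variant with
  measurement covariance is out of scope.
- The five branch-ratio rows are empirical constants; conclusions inherit
  them.
- The shared biomass flux (0.8401) for both strains is kept as published
  even though the printed wet weights differ; the package does not attempt
  to re-derive it.
- `as_printed` coefficients are retained only so the inconsistency is
  reproducible and reportable; results derived from them carry deviation
  warnings.
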