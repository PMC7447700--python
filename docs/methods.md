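# Methods

`ricephys` re-implements, as a tested library, the computational chain used
in two-cultivar hybrid-rice field physiology: leaf light-response and A/Ci
photosynthesis model fitting, closed-chamber canopy CO2-flux estimation,
Richards grain-filling kinetics, SPAD chlorophyll calibration, and the
cultivar trait-comparison statistics. Raw field measurements of such trials
are typically unpublished, so the package ships synthetic-data generators
that emulate every input with the statistical structure the estimators
assume; the generators are first-class, tested code.

## Leaf photosynthesis models

**Light response.** Net photosynthesis as a function of PPFD `I` is the
non-rectangular hyperbola

    Pn(I) = [αI + Pnmax − sqrt((αI + Pnmax)² − 4θαI·Pnmax)] / (2θ) − Rd

with apparent quantum yield α, light-saturated capacity Pnmax, convexity
θ ∈ [0, 1] and dark respiration Rd. We evaluate the minus-branch root in its
rationalized form `2αI·Pnmax / (αI + Pnmax + sqrt(disc))`, which is
algebraically identical but avoids catastrophic cancellation at small θ and
reduces continuously to the rectangular hyperbola `αI·Pnmax/(αI + Pnmax)` at
θ = 0 without a code branch. Discriminants pushed below zero by
floating-point noise are clamped to zero and flagged. (Field protocols often
label this curve a "rectangular hyperbola" even when the convexity form is
fitted; we implement the convexity form and expose the θ = 0 limit.)

**A/Ci (FvCB).** Net photosynthesis is the minimum of a Rubisco-limited and
an RuBP-regeneration-limited rate minus dark respiration:

    Pn = min(Wc, Wj) − Rd
    Wc = Vcmax · Ci / (Ci + Kc(1 + O/Ko))
    Wj = Jmax · Ci / (4Ci + 8Γ*)

These are deliberately the forms *without* the canonical (Ci − Γ*)
numerator: they are the forms used in the protocol this package follows,
and default kinetic constants are that protocol's set — Kc = 404 and
Γ* = 45 µmol mol⁻¹ (CO2-side, ppm), Ko = 278 and O = 210 mbar (O2-side),
so O/Ko is dimensionless. The canonical variants
`Wc = Vcmax(Ci − Γ*)/(Ci + K′)`, `Wj = Jmax(Ci − Γ*)/(4Ci + 8Γ*)` are
available behind `canonical=True` and are never the default; which form a
given historical dataset used cannot generally be recovered, so both are
provided. The carboxylation/regeneration crossover has the closed form
`Ci* = (Jmax·K′ − 8Γ*·Vcmax)/(4Vcmax − Jmax)`, `K′ = Kc(1 + O/Ko)`, used
for per-point limitation labelling; no crossover (denominator ≤ 0 or
Ci* ≤ 0) is a `None` return, not an error. Temperature response of the
constants, mesophyll conductance and TPU limitation are out of scope.

**Grain filling.** Single-grain dry weight after anthesis follows the
Richards curve in the parameterization

    W(t) = A · (1 + B·e^(−kt))^(−1/N)

with asymptote A (mg grain⁻¹), initial-condition parameter B, rate constant
k (day⁻¹) and shape N (N = 1 is logistic). Reports of "modified Richards"
fits rarely print the functional form; this parameterization is our
documented choice, and all quantitative claims about it are
parameter-recovery claims, never reproductions of unpublished fits. The
filling rate is the analytic derivative
`dW/dt = (AkB/N)·e^(−kt)·(1 + B·e^(−kt))^(−1/N−1)`.

## Curve fitting

All three nonlinear fits minimize the residual sum of squares with bounded
trust-region least squares (`scipy.optimize.least_squares`, method `trf`,
SSE-change tolerance 1e-10, at most 500 function evaluations per start).
Because spreadsheet-era fits published no starts or tolerances, determinism
is built in instead: starts form a fixed lattice of three values per free
parameter across the bound box (fractions 0.1/0.5/0.9; log-spaced for the
Richards `B`, whose box (0, 1e4] spans orders of magnitude), the best final
SSE wins, and ties break by lattice order — identical input always yields
bit-identical estimates.

Bounds: light response Pnmax ∈ (0, 100], α ∈ (0, 0.15], θ ∈ [0, 1],
Rd ∈ [0, 10]; A/Ci Vcmax ∈ (0, 500], Jmax ∈ (0, 1000], Rd ∈ [0, 10];
Richards A ∈ (0, 2·max(weight)], B ∈ (0, 1e4], k ∈ (0, 2], N ∈ (0, 10].
A parameter landing on a bound is flagged (`bound_hit:<name>`), not an
error. Standard errors use the Gauss–Newton approximation
`cov = s²(JᵀJ)⁻¹` at the optimum (`s² = SSE/(n − p)`) and are NaN when JᵀJ
is singular. Degenerate inputs (constant response) return a non-converged,
flagged result rather than raising. In A/Ci fits Rd is estimated by default
(`rd_mode="fit"`); when a separate dark-respiration measurement exists it
can be fixed (`rd_mode=<value>`), which is also the configuration used in
the Monte-Carlo calibration. If every point falls on one side of the
fitted crossover, the unconstrained capacity is flagged unidentifiable.

The SPAD→chlorophyll calibration is ordinary least squares per cultivar
(pooling across cultivars is never implicit); applying a calibration clamps
negative predictions to zero with a flag.

## Canopy chamber fluxes

Closed transparent chambers (default 1×1×1.5 m over 1 m² of ground) cycle
45 s closed / 495 s open while [CO2] is logged at 1 Hz; ten chambers share
one controller with phase offsets of period/10. Within each closure the
[CO2] slope is estimated by OLS after discarding the first `trim_head`
seconds (default 5 s — standard practice for post-closure mixing, not part
of the original protocol description, and configurable to 0). The flux is

    F = −slope · n_air / A_ground,   n_air = P·V/(R·T)

by the ideal-gas law (R = 8.314 J mol⁻¹ K⁻¹; defaults T = 303.15 K,
P = 101325 Pa, flagged as assumed when unlogged). The closed-source
instrument suite's exact conversion is not published; absolute fluxes
therefore depend on this documented choice. A linear drawdown model is
adopted — closures are short enough that saturation and leak corrections
are unnecessary — and slope standard error plus r² are exposed per closure
for user-side quality filtering, since any vendor-side filtering rules are
unknown. Sign convention: falling [CO2] during closure ⇒ positive flux
(daytime net canopy uptake). Water-vapour flux and chamber
temperature-control dynamics are out of scope.

Trailing-closure rule: a closure window is kept iff its full closed
interval is covered by the log (an 1800 s log with the default schedule
yields four closures, at 0, 540, 1080 and 1620 s).

## Trait statistics

Percent difference is `100·(test − reference)/reference` — the reference
cultivar is always the denominator — computed at full precision and rounded
half-up to 2 decimals only for display, matching field-trial table
conventions. Two-sample t-tests are two-sided, pooled-variance by default
(Welch available); published tables rarely state the variant, and pooled
matches replicated plot designs. The two-way cultivar × year ANOVA is the
classical balanced fixed-effects decomposition (closed-form sums of
squares, authored here both because it is part of the package's surface and
because the type-I-error simulation needs thousands of fast calls);
`statsmodels.anova_lm` serves as an independent oracle in the test suite.
Unbalanced designs are rejected — the emulated trials are balanced by
construction. Fisher's LSD at level α groups cell means greedily in
descending order: `LSD = t(1 − α/2, df_error)·sqrt(2·MS_error/n)`, maximal
runs within one LSD share a letter, and overlapping letters (e.g. "ab")
arise naturally. Significance stars: * for p < 0.05, ** for p < 0.01.

Agronomic indices are ratios: harvest index (grain / aboveground biomass,
values > 1 flagged), organ dry-matter partitioning (the last component is
closed so the four percentages sum to exactly 100), and productive tiller
percentage (> 100% flagged).

## Synthetic data: what it emulates and what it does not

Generators add i.i.d. Gaussian noise to the exact forward models on the
study's measurement grids: the 14-level PPFD ladder (2000…0), the 13-level
CO2 ladder (425…50 then 500…1800 ppm, with the chamber setpoints standing
in for Ci — in a real leaf Ci < Ca, but the fitter sees the same values the
generator used, so the distinction is irrelevant for round-trip claims),
1 Hz chamber logs with instantaneous open-period resets (no mixing
dynamics; the estimator never reads open periods), 5-day grain-weight
sampling, and balanced additive-effects trial tables. Default σ for leaf
Pn is 0.5 µmol m⁻² s⁻¹, the typical replicate SD of such measurements;
chamber [CO2] noise defaults to 0.2 µmol mol⁻¹.

What passing tests show: the estimators are exact adjoints of the
generators at zero noise, unbiased and well-calibrated under i.i.d.
Gaussian noise, and deterministic. What they do not show: robustness to
drift, autocorrelated instrument noise, stomatal patchiness, chamber
leaks, weather-driven variation or unbalanced field designs — none of
which the generators emulate.

## Numerical and interface choices

* Every generator is a pure function of (parameters, seed); identical seeds
  give identical data.
* CSV schemas are strict: header required, UTF-8, '.' decimal, unknown
  config keys rejected, mixed driver kinds in one curve file rejected,
  non-numeric cells reported with their line number. No dialect sniffing.
* JSON fit reports carry `schema_version`.
* Problem sizes used by the shipped acceptance script: 200 Monte-Carlo
  replicates per fitter at σ = 0.5, 500 noisy chamber closures, 1000 ANOVA
  simulations of a 2 × 3 × 3 design — sizes at which the Monte-Carlo
  standard error of each reported rate is comfortably below the claimed
  margins.

## Known limitations

* The A/Ci model fits the two-limitation FvCB form only; curves dominated
  by triose-phosphate export limitation at very high Ci will bias Jmax low.
* Fixed kinetic constants mean fitted Vcmax/Jmax are "apparent" values at
  the measurement temperature.
* The LSD grouping is the classical unadjusted procedure; it does not
  control the family-wise error rate.
* Percent-difference cells published after pre-rounding arithmetic cannot
  be reproduced from their printed means; only exactly-reproducing cells
  are used as reference values (`ricephys.reference`).
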