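# Methods

This note documents the models, parameter choices, numerical decisions
and limitations behind `acifit`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Models

### C3: FvCB on a chloroplastic-CO₂ basis

Net assimilation is the minimum of a Rubisco-limited and an
RuBP-regeneration-limited rate, less day respiration:

    A = min(Ac, Aj) − RL
    Ac = Vcmax (Cc − Γ*) / (Cc + Kc(1 + O/Ko))
    Aj = J (Cc − Γ*) / (4 Cc + 8 Γ*)

with electron-transport coefficients 4 and 8 (NADPH basis). Because
curves are measured at saturating light (PPFD 1500 µmol m⁻² s⁻¹), the
operating electron transport on the RuBP-limited branch is taken at its
maximum, J = Jmax; the fitted "Jmax" is therefore the
saturating-light plateau of electron transport. The limitation
transition is a hard minimum — each point gets a reproducible
`rubisco`/`rubp` label at the fitted optimum — rather than a smoothed
hyperbolic mixture.

Day respiration is fixed at RL = Rdark/2 (half the pre-dawn dark
respiration, the study's rule); a free-RL mode exists for sensitivity
analysis. O = 21 kPa throughout the C3 calculations.

### Mesophyll conductance

Two estimators are provided:

* **Variable-J** (default): per-point
  gm = AN / (Ci − Γ*(ETR + 8(AN+RL)) / (ETR − 4(AN+RL))), from combined
  gas exchange and fluorescence. Points where ETR ≤ 4(AN+RL), where the
  implied drawdown is non-positive, or where AN < 0 are flagged
  inadmissible, excluded and logged — never fatal for a curve (a curve
  needs ≥ 5 surviving points). By default the admissible per-point
  values are averaged to one curve-level gm before the Cc conversion
  (`gm_mode="scalar"`); a per-point mode exists. The averaged-scalar
  default reflects that per-point gm estimates share the same
  measurement channel as the curve being fitted, so carrying their full
  point-to-point scatter into Cc would re-use noise.
* **Finite-gm quadratic fit** (Ethier-style): the quadratic closed form
  of A = FvCB(Ci − A/gm) is fitted on the Ci basis with one shared gm
  across the curve, jointly with Vcmax and Jmax. On data simulated with
  constant gm the two estimators agree with the generating value
  (variable-J to ~1e-14 noiseless; quadratic fit within 2%), and they
  correlate positively across noisy replicate ensembles.

Unit convention: gm is reported in mol m⁻² s⁻¹ bar⁻¹;
1 µmol m⁻² s⁻¹ Pa⁻¹ = 0.1 mol m⁻² s⁻¹ bar⁻¹. Mole fractions
(µmol mol⁻¹) convert to partial pressures through the per-record
atmospheric pressure (default 101.325 kPa — instruments report mole
fractions and the source tables never state pressure, so the default is
standard atmosphere; override per record).

### C4: enzyme-limited von Caemmerer model

    Cm = Ci − A/gm                                   (supply)
    A  = Cs Vcmax/(Cs + Kc(1+O/Ko)) (1 − γ*O/Cs) − RL  (bundle sheath)
    A  = Cm Vpmax/(Cm + Kp) − gbs(Cs − Cm) − Rm        (PEPC pump − leak)

Fixed constants: O = 210 mbar, gbs = 3 mmol m⁻² s⁻¹,
gm = 2 mol m⁻² s⁻¹, identical across treatments. γ* is dimensionless
(Γ*/O; 0.000193 at 25 °C for the standard parameter set) — the only
reading under which the bundle-sheath term is dimensionally consistent;
species-specific Γ* (Pa) is divided by O at the module boundary.
Rm = 0.5·RL (= Rdark/4), the usual convention for the mesophyll share
of day respiration; configurable.

Diffusion arithmetic runs on mole fractions with conductances per mole
fraction; kinetic constants convert from Pa to mole fractions via Patm
only inside the enzyme terms.

Given (Vcmax, Vpmax), eliminating Cm and Cs leaves a residual in A that
is strictly decreasing (raising A lowers Cm, hence the pump rate, hence
Cs, hence the bundle-sheath rate), so the solution is unique inside the
physical bracket [−RL−Rm−5, min(Vcmax, gm·Ci)] and is found by 80
bisection steps (resolution far below 1e-9 µmol m⁻² s⁻¹; agreement
with an independent dense-scan solver is ≤ ~5e-9 over 1000 random
parameter draws).

Before fitting, curves are smoothed with a non-rectangular hyperbola
and evaluated on a Ci grid with 5 µmol mol⁻¹ step (falling back to
monotone PCHIP interpolation with a warning if the hyperbola does not
converge); a raw-points mode exists for sensitivity checks. The exact
estimation sequence used with this model in the literature (which Ci
windows feed Vpmax vs Vcmax) is not fully specified anywhere, so this
package adopts an explicit joint least-squares of (Vcmax, Vpmax)
through the forward solver on the smoothed grid.

## Kinetic constants

* **Species-specific ("own")**: in-vitro constants for rice, wheat and
  maize at 25 and 38 °C, stored verbatim in
  `data/rubisco_pepc_constants.csv` (Kc in Pa, Ko in kPa, Γ* in Pa,
  Kp in Pa, each with its SE). Sco is not printed in the source table;
  the packaged value is back-derived from Γ* via Sco = 0.5·O/Γ* at
  O = 21 kPa and marked as derived. Dissolved-phase constants convert
  to partial pressures with the CO₂/O₂ solubilities at the assay
  temperatures (0.0334 / 0.0243 mol L⁻¹ bar⁻¹ for CO₂ and
  0.00126 / 0.00102 for O₂ at 25 / 38 °C). Ko can be recovered from Kc
  assayed at 0 % and 21 % O₂ via Ko = O/(Kc21/Kc0 − 1); a
  non-inhibited pair (Kc21 ≤ Kc0) raises a non-identifiability error.
* **Temperature scaling of own constants**: a two-point Arrhenius law
  (ln k linear in 1/T_K) exactly constrained by the 25/38 °C pair —
  the assays provide exactly two temperatures, so any extra-parameter
  response would be under-determined. The endpoints reproduce the table
  bit-exactly; interpolation is strictly monotone between them. A Q10
  alternative is available via `mode="q10"`. Extrapolation is limited
  to 0–60 °C.
* **Standard ("tobacco") constants**: configuration data in
  `data/tobacco_temperature_responses.json`, two variants — the
  intercellular-CO₂-basis set (Kc 40.49 Pa, Ko 27.84 kPa, Γ* 4.275 Pa
  at 25 °C; ΔHa 79.43/36.38/37.83 kJ mol⁻¹) and the
  chloroplastic-CO₂-basis set derived with finite mesophyll conductance
  (Kc 27.238 Pa, Ko 16.582 kPa, Γ* 3.743 Pa; ΔHa 80.99/23.72/24.46).
  The Cc-basis set is the default because this pipeline fits curves on
  a Cc basis; the Ci-basis set is selectable. Published values in
  µbar/mbar/µmol mol⁻¹ are converted to Pa/kPa at 1 bar.
* **C4 standard**: Kc 65 Pa, Ko 45 kPa, Kp 8 Pa, γ* 0.000193 at 25 °C;
  Rubisco constants follow the tobacco Ci-basis activation energies
  with temperature while Kp is held invariant.

## Indices and comparison analysis

TSI = Y(CT-25)/Y(CT-38) and TAI = Y(HT-38)/Y(CT-25) are plain ratios
of treatment means; both are scale-invariant and no algebraic relation
between them is enforced (they share the CT-25 mean but answer
different questions — do not multiply them). Ratio SEs propagate by the
delta method for independent means, and "differs from 1" uses a
two-sided t on the log ratio — the source analysis used rank-style
post-hoc tests on raw values, so the stars produced here are a
documented divergence, not a reproduction.

The bias analysis regresses the own-kinetics estimate on the
standard-kinetics estimate (own on the vertical axis — the direction
that reproduces the published slopes from the packaged treatment
means), with intercept, on treatment means rather than replicates.
Percent overestimation per row is 100·(standard/own − 1), pooled as an
unweighted mean. On the packaged 8-row tables this yields slope 0.980
(rice) and 0.861 (wheat), r² 0.993/0.992, pooled overestimation
14.7 %. `refit_with_kinetics` reruns the identical pipeline — including
gm re-estimation with the alternative Γ* — under the standard source.

## Synthetic data

The generator emulates the study conditions: 3 species × 2 growth
temperatures (25/38 °C) × 2 irrigation levels (WW/WD) × 2 measurement
temperatures × 4 replicates = 96 curves, Ca swept over 50–2000
µmol mol⁻¹ (12 points), Gaussian noise on A_N with sd 0.5
µmol m⁻² s⁻¹ by default (optional multiplicative gs noise).

Each point is an exact steady state of the coupled supply/demand
system. For C3, stomata and mesophyll act as series resistances, so
A = FvCB(Ca − A(1.6/gs + 1/gm)) solves in closed (quadratic) form; Ci
and Cc follow from the supply line. For C4 the stomatal resistance
folds into the model's mesophyll conductance and the triple solves in
one bracketed root find. Fluorescence is emitted consistently with the
operating electron transport at the true steady state
(J = Vcmax(4Cc+8Γ*)/(Cc+Kapp) on the Rubisco-limited branch, Jmax on
the RuBP branch), so the variable-J inversion is admissible by
construction at every point above the compensation point, and recovers
the generating gm exactly in the noiseless limit. Sub-compensation
points (Cc ≤ Γ*) are dropped — there is no meaningful variable-J signal
there.

True-parameter magnitudes per treatment cell are scenario presets taken
from the study's fitted treatment means (e.g. rice CT-WW-25 °C
Vcmax ≈ 103, Jmax ≈ 184; maize CT-WW-25 °C Vcmax ≈ 30, Vpmax ≈ 134), so
synthetic outputs are physiologically scaled; they are presets for
testing, not ground truth about any real plant. Quantities the study
does not tabulate were fixed once at field-realistic values: gs(WW)
0.35/0.30/0.25 mol H₂O m⁻² s⁻¹ for rice/wheat/maize (×1.1 at 38 °C
measurement), WD gs = 0.55 × WW (the ≥40 % reduction that defines water
deficit), gm 0.28/0.25 mol m⁻² s⁻¹ bar⁻¹ for rice/wheat (×0.8 at
38 °C, ×0.8 under WD), Rdark 0.8 / 3.2 µmol m⁻² s⁻¹ at 25 / 38 °C
(giving an Rdark temperature-sensitivity ratio of 0.25, in the
observed range for these crops).

Randomness: one integer seed feeds a `numpy` `SeedSequence`; one child
stream is spawned per (treatment cell, replicate), so cells are
statistically independent and the whole dataset is bitwise reproducible
under a fixed seed.

What the generator does **not** emulate: instrument drift and chamber
leaks, the multi-flash fluorescence protocol, plant-to-plant parameter
variability within a cell (replicates differ only by measurement
noise), triose-phosphate-utilization limitation, and light-limited C4
behaviour. Passing recovery tests therefore demonstrate correctness of
the estimation machinery under the model's own assumptions, not
robustness to every artefact of real gas-exchange data.

## Numerical choices

* All nonlinear fits are multi-start `scipy.optimize.least_squares`
  (trf, bounds, tolerances 1e-10, ≤300 evaluations per start) over
  fixed coarse grids of initial values, iterated in deterministic
  order; the best candidate by cost is accepted even when the
  evaluation cap formally stops a start, because the min(Ac,Aj) kink
  can stall the optimizer after it has already reached an excellent
  solution. No randomness enters the fitting path.
* Parameter SEs come from the residual covariance,
  (JᵀJ)⁻¹·SSE/(n−p).
* Jmax is flagged non-identifiable when a pure Rubisco-limited fit
  explains the curve as well as the joint fit; Vpmax when the curve has
  no points with Ci ≤ 100 µmol mol⁻¹ (no initial slope).
* Fit failures raise a `FitError` carrying diagnostics — never silent
  defaults; in batch refits failures are logged per curve and skipped.
* Degenerate inputs: non-positive conductances, Fs > Fm′, negative
  Rdark, zero-variance regressors and unknown solubility pairs raise
  typed errors at the boundary rather than propagating NaNs.

## Known limitations

* Variable-J gm shares its measurement channel with the fitted curve,
  so gm noise propagates into Vcmax with a small negative bias at
  realistic noise (≈−3 % at sd 0.2); median factorial recovery stays
  within 5 %. The fitter itself is unbiased (<0.1 %) when Cc is known.
* The Jmax = J assumption is only valid at saturating light; curves
  measured at sub-saturating PPFD would need a light-response model.
* Arrhenius interpolation between 25 and 38 °C cannot represent
  deactivation above the thermal optimum; no Rubisco-activase
  limitation is modelled.
* The C4 fit inherits the fixed gbs/gm/O assumptions; misspecifying
  gbs mainly moves Vpmax (shown by the doubling sensitivity test).
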