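# Methods

This note records the models implemented in `pteroshell`, the constants
and defaults they carry, the numerical choices behind them, and what the
synthetic-data generators do and do not emulate.

## Carbonate-system speciation

The solver treats seawater as the standard marine CO₂ system at surface
pressure on the total hydrogen-ion pH scale. Given a (DIC, TA) pair at
salinity S and temperature T, it finds the unique pH at which the
modelled total alkalinity

TA = [HCO₃⁻] + 2[CO₃²⁻] + [B(OH)₄⁻] + [OH⁻] − [H⁺]ᶠ − [HSO₄⁻] − [HF]

matches the measured value, then derives pCO₂ = [CO₂*]/K₀ and
ΩAr = [Ca²⁺][CO₃²⁻]/K*sp,ar*. Nutrient (phosphate/silicate) alkalinity
is taken as zero: the datasets this targets report no nutrients, and at
lab-carboy conditions the omitted terms are small against the carbonate
and borate terms.

Constant formulations (all evaluated in mol/kg-SW): K₀ from Weiss
(1974); K₁/K₂ from the Mehrbach measurements as refit by Dickson &
Millero (1987), converted from the seawater to the total scale; KB from
Dickson (1990b); KW from Millero (1995); KS from Dickson (1990a); KF
from Dickson & Riley (1979); aragonite solubility from Mucci (1983);
[Ca²⁺] proportional to salinity (Riley & Tongudai convention,
0.02128/40.087 × S/1.80655).

**Boron–salinity ratio.** Both the Uppström (1974) and Lee et al. (2010)
total-boron relations are implemented; **Lee is the default**. The
choice is empirical: against the published seasonal treatment table
(the package's reference dataset in `datasets.py`), Lee reproduces all
15 ΩAr values to ±0.007 and pCO₂ to within 5%, whereas Uppström leaves
ΩAr residuals up to 0.024. The higher Lee boron raises borate
alkalinity, lowering the carbonate alkalinity inferred from a DIC–TA
pair.

**pH root-finding.** The alkalinity residual is strictly monotone in pH
at fixed DIC, so the root on pH ∈ [5.5, 9.5] is unique; it is found by
Brent's bracketed method (a bisection/inverse-quadratic hybrid,
unconditionally convergent on a sign-changing bracket) to |ΔTA| < 10⁻³
μmol/kg. The test suite checks the solver against an independent
grid-plus-bisection search written out from the same constants.

**Measured versus computed pH.** Time-averaged *measured*
(spectrophotometric) pH and the pH *computed* from time-averaged DIC/TA
need not agree: the two are sampled on different schedules and the
carbonate system is over-determined. In the reference table the
discrepancy reaches +0.08 for the January rows even though pCO₂ and
ΩAr from the same DIC–TA means are reproduced almost exactly. Users
comparing solver output against measured pH should expect offsets of
this order in drifting incubations; no constant choice removes them.

## Shell transparency scoring

Shells are bleached, dried, and photographed on a pure-white background
(greyscale 255). Segmentation thresholds the image (default fixed
cutoff 250 — slightly below the background to tolerate vignetting; Otsu
available), removes user-supplied exclusion polygons (apertures, drill
holes), and keeps the largest 8-connected component to reject detached
debris. Transparency is the mean greyscale over the mask divided by
255. Raster convention: origin top-left, row-major; polygons are
(row, col) vertex lists so masks are exchangeable between tools.
Exclusion polygons replace interactive manual cropping so the procedure
is reproducible and batchable.

## Respiration

Mass-specific oxygen consumption is (ΔO₂ × chamber volume)/(elapsed
time × animal wet mass), with chamber volume from chamber wet-minus-dry
mass at 1.0 g/ml. Rates are normalized to 8.0 °C by
R_f = R_i · Q₁₀^((8−T_i)/10) with Q₁₀ = 2, mid-range for congener
measurements; over the observed temperature span (5.6–8.6 °C) the
correction factor stays within [2⁻⁰·⁰⁶, 2⁰·²⁴], so moderate error in
Q₁₀ barely moves the corrected rates. Bacterial background from
control chambers (<5% of animal consumption) is not subtracted by
default; subtraction per season × treatment group is available behind a
flag. Animals dead at final inspection are excluded before statistics;
negative computed rates are flagged, never clipped.

## Transparency calibration chain

1. **Per-season power law.** At the 4-day time point, T = α_s·Ω^(b_s) is
   fit by OLS on log T vs log Ω (a multiplicative-error reading —
   deterministic and scale-consistent; nonlinear least squares in the
   original scale is available as an option).
2. **Cross-season exponent.** b is the arithmetic mean of the five
   per-season exponents, SE = SD/√n. The seasons differ in their
   intercepts, not their exponents.
3. **α calibration line.** Fitted α_s regressed on the season's field
   ("Day 0") transparency; the published line is α = 1.0293·T₀ − 0.1087,
   giving α = 0.82 at the pristine T₀ = 0.90.
4. **Duration deficit.** Each duration-experiment record gets
   D4T = α_s·Ω^b; the deficit (observed − D4T) is regressed on duration
   for medium/high treatments only (ambient water sits above the
   Ω ≈ 1.5 response threshold and shows no duration effect), yielding
   deficit = slope·D + β with slope ≈ −0.0238 d⁻¹.

**Floor censoring.** Transparency has a biological floor near 0.40;
records at the floor are censored observations, not linear responses,
and OLS over them attenuates the duration slope. The duration fit
therefore excludes records at or below the floor by default
(`floor=None` keeps them) — the published regression was likewise built
from the late-year datasets whose shells stayed above the floor. A
small attenuation (~2% of the slope) remains from noise-driven
selection near the floor; the deficit-level recovery (below) is free of
it.

## Constants profiles and exposure inversion

The published account of the model prints slightly different constants
in different places (α 0.82 vs 0.81; β 0.1026 vs −0.0344 vs 0.0555;
slope −0.0238 vs −0.0239; exponent 0.255, once printed as 0.0255).
These are preserved verbatim as named profiles rather than reconciled:
`results_text`/`self_consistent` (α 0.82, b 0.255, slope −0.0238,
β 0.1026), `eq5_verbatim` (α 0.81, β −0.0344; default for intensity
inversion) and `eq6_verbatim` (α 0.82, exponent 0.0255 as printed,
slope −0.0239, β 0.0555; default for duration inversion and envelopes).
Within any one profile the forward model and both inversions are exact
mutual inverses; across profiles small inconsistencies are inherent to
the printed constants — e.g. the emergence time (duration at which a
pristine shell's deficit reaches zero, β/(−slope)) is 2.3 days under
`eq6_verbatim` but 4.3 days under `results_text`.

The exposure envelope evaluates the duration inversion on an Ω grid
(default 0.5–1.5, step 0.01, spanning the treatment range up to the
response threshold) and drops points below the 2-day emergence floor.
Negative inverted durations are returned flagged, never clamped, since
a transparency above the pristine day-4 prediction is informative.
One transparency cannot discriminate intensity from duration; the
envelope is the honest summary of what it constrains.

## Biomarker screen

Per-gene Pearson correlation of log(1+x)-transformed TMM expression
against per-sample ΩAr, pooled across seasons and treatments (per-season
grouping can be done by subsetting the sample table). Natural log is the
default; the base only rescales transformed values and leaves R
untouched. Filters are applied to R itself (|R| > 0.5; R² > 0.4, which
implies |R| > 0.632 and is therefore nested), matching a
variance-explained framing rather than hypothesis testing; BH q-values
are emitted for reference but never used by the filters. Zero-variance
genes have undefined R and are flagged and excluded from pass counts.

## Synthetic-data generators

The generators encode the study conditions: five seasonal campaigns ×
three CO₂ treatments with the published ΩAr means/SDs, durations
{1.5, 4, 8, 15} days, seven individuals per cell, transparency noise
SD 0.03, and a floor of 0.40. Per-season α is drawn uniformly from
(0.55, 0.82) — the range the α calibration line maps to the observed
field transparencies — and each season's Day-0 transparency is the
exact inverse of that line, so the line is recoverable from generated
data. The residual-noise SD is not reported anywhere for this system;
0.03 is this package's choice, sized so that individual points scatter
visibly around the power law while the cross-season exponent spread
stays at the order of the published SE (0.032).

The duration deficit is applied to medium/high treatments as
slope·(D − 4), anchored at the 4-day calibration point so that 4-day
records follow the bare power law — the model's own definition of D4T
makes the deficit zero there, and anchoring avoids imprinting the
rounding slop of the printed β onto the power-law stage. A second,
deficit-level generator emulates the duration regression's own view of
the data (deficit = slope·D + β + noise at all four durations) for
direct recovery checks.

Shell micrographs are white-background ellipses whose integer pixel
intensities are dithered and pair-jittered so the mean equals
target × 255 to within one grey level; optional punched holes are dark
discs covered by matching exclusion polygons. Expression matrices carry
36 samples (four seasons × three treatments × three replicates); the
229 planted "strong" genes (30 of them "very strong") are constructed
on the log scale with *exact* sample correlation against Ω (|R| in
0.52–0.60 and 0.68–0.85 respectively, random sign) by combining the
centred Ω direction with an orthogonal random direction, so screen pass
counts equal the planted counts up to background false positives;
background genes are Ω-independent with gene-level seasonal block
effects. All generators are pure functions of (config, seed).

**What passing tests do not show.** The generators reproduce the
*structure* the analysis assumes — not measurement drift, within-carboy
covariance, mortality, ontogenetic shifts, or sequencing count noise.
Recovery of the generating constants from synthetic data validates the
estimation chain, not the biological claim; quantities that depend on
the real biological data (differential-expression counts, the literal
229/30 correlated-gene counts, alignment rates, observed transparency
extrema) are reconstructed synthetically, not reproduced.

## Problem sizes and tolerances

Replicate simulations use 200 replicates (the recovery SE on the
exponent is then ~0.001, an order below the published SE of 0.032);
synthetic micrographs are 96×96 px, ample for exact mean-intensity
bookkeeping at 25×-style framing. Solver tolerance is |ΔTA| < 10⁻³
μmol/kg (pH stable to ~10⁻⁸); inversion round-trips hold to 10⁻⁶;
image round-trips to ±0.01 transparency.

## Known limitations

- The carbonate solver is a lab/surface configuration: no pressure
  correction, no alternative pH scales, no air–sea flux.
- The calibration is for *Limacina retroversa*-type shells scored by
  transmitted-light transparency; opacity-on-black protocols and SEM
  dissolution indices are different instruments with different scales.
- The transparency floor (~0.40) truncates information: severities
  beyond it are indistinguishable.
- The inversion profiles inherit the printed constants' mutual
  inconsistencies; cross-profile comparisons mix conventions and the
  package deliberately does not average them.
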