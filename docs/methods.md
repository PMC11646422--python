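# Methods

`algafuel` turns a GC-FID FAME profile of a microalgal lipid into predicted
biodiesel fuel properties and standard-compliance verdicts, and provides the
surrounding batch-culture arithmetic (growth kinetics, assay formulas) plus a
seeded synthetic-data generator. This note records the models, the
assumptions behind them, the numerical choices, and what the synthetic tests
do and do not demonstrate.

## FAME profiles and the average degree of unsaturation

A profile is a set of identified fatty acids, each written in
`C<carbons>:<double bonds>[n-<omega series>]` shorthand with a mass
percentage of total fatty acids, plus an unidentified "others" share; the
whole must close to 100 % within a configurable tolerance (default 0.5
percentage points). The central summary statistic is the average degree of
unsaturation,

    ADU = Σᵢ Nᵢ · Mfᵢ ,

with Nᵢ the C=C double-bond count and Mfᵢ the mass fraction (mass %/100) of
identified species *i*.

Two conventions matter and change every downstream number:

* **The unidentified share is excluded** from ADU, the class totals, and
  every correlation term. Unassigned chromatogram peaks carry no structural
  information; treating them as zero-unsaturation mass would bias ADU
  downward by 30–40 % on profiles like these. Verified by back-calculation:
  only the identified-species convention reproduces the published ADU
  column from the published composition table.
* **Acids are addressed by structure** where a correlation names an acid:
  the "C18:3" flash-point term and the "linolenic" compliance limit are the
  sum of the γ (n-6) and α (n-3) isomers, and lookups like C18:1 cover any
  omega variant. (Again verified by back-calculation: 0.46 × 40.2
  reproduces the published flash point at the 1.0 M condition.)

Duplicate notations in an input file are rejected rather than merged; in lab
data a repeated row is more likely a transcription error than a split peak.

## Fuel-property correlations

Six properties are affine in ADU (kinematic viscosity, density, cloud point,
cetane number, iodine value, higher heating value); the cold-filter plugging
point is affine in the long-chain saturated factor
LCSF = 0.1·C16:0 + 0.5·C18:0 + 1·C20:0 + 1.5·C22:0 + 2·C24:0 (wt %, absent
acids zero); the flash point is a multi-term linear form over individual
acid contents; and oxidative stability follows the combined linoleic +
linolenic content X as

    OS = 117.9295 / X + 2.5905   (hours).

The division form is deliberate. The source literature also circulates a
multiplicative form (117.9295·X + 2.5905), which is dimensionally and
physically wrong here: it would assign ~4,000 h induction periods to highly
polyunsaturated oils, whose instability is the entire reason the statistic
exists, and it reproduces none of the published values. The inverse form
reproduces all five. OS is undefined (reported as `None`) for a profile
with no polyunsaturates; a standard that limits OS then fails, since
conformity cannot be demonstrated.

All correlations are evaluated on **unrounded** intermediates (ADU, LCSF,
X); rounding happens only at the reporting boundary, half-up, via
`round_for_report`.

### Reproduction tolerance and the two anomalous cells

`algafuel reproduce-paper` recomputes the published fuel-property table from
the packaged composition table and compares each cell at its printed
precision with tolerance 0.011 on the printed scale. The tolerance absorbs
the reference table's occasional truncation-instead-of-rounding (e.g. an
ADU of 1.067 printed as 1.06) while still catching real disagreement. Two
cells disagree beyond any rounding convention: the cloud point at 1.0 M
(printed 1.24 °C; the correlation on ADU 1.401 gives 1.28 °C) and the CFPP
at 3.0 M (printed −4.31 °C; LCSF 2.83 gives −7.59 °C). These are treated as
print errors: they ship in a commented whitelist file, are always reported
as mismatches together with the computed values, and do not fail the run.
No attempt is made to guess the intended values.

## Compliance checking

Standards ship as an editable JSON file: per-property lower/upper bounds,
each flagged strict or non-strict following the printed glyphs (a value
exactly at a "≥" bound passes; exactly at the ">" oxidative-stability bound
fails). EN 14214's CFPP limit is climate-grade dependent; the packaged
default is the +5 °C grade, overridable per run. The per-property margin is
the signed distance from the value to the nearest bound.

## Growth kinetics

The two-point specific growth rate is µ = ln(N₂/N₁)/(t₂−t₁) and the
doubling time k = ln 2/µ (natural logarithm throughout; k is derived from
µ, so µ·k = ln 2 identically). Condition summaries report mean ± sample SD
(n−1), with k averaged over per-replicate doubling times rather than
recomputed from the mean µ — 1/µ is convex, so the two differ.

For a full curve, µ is the least-squares slope of ln N against t inside a
window. When the caller gives no window, the exponential phase is located
automatically:

1. fit every contiguous run of ≥ 4 observations;
2. estimate the counting-noise floor as the median residual mean square of
   the minimal (4-point) windows;
3. discard windows whose residual mean square exceeds 3× that floor — these
   are the fits bent by the lag or stationary phase;
4. among the survivors, keep the window with the greatest fitted
   log-increase (slope × span), ties to the larger window then the earlier
   start.

The selection statistic was chosen with care. Maximising raw R² fails:
R² is not comparable across window sizes, and under realistic count noise a
short, spuriously collinear window routinely outscores the true exponential
stretch. Maximising window length alone fails differently, picking long
noise-flat stationary stretches. The log-increase criterion prefers the
longest clean stretch of genuine rise, which is the quantity an
exponential-phase fit is supposed to describe. On noiseless
exponential-with-lag input the procedure recovers the generative rate
exactly and the reported window starts at the end of the lag; the window
used is always part of the result.

**Known limitation.** On a saturating (logistic) curve sampled every two
days there is *no* window with sustained slope µ: every admissible
log-linear fit underestimates the generative rate, by ~15–20 % under the
default study conditions (quantified in the test suite). This is a property
of batch-culture data, not of the estimator, and it is why published growth
rates from such curves depend on an unstated window choice. Parameter
recovery is therefore validated in the exponential (unbounded-capacity)
regime, where the estimator is consistent; the logistic bias is asserted,
not hidden, in its own test.

## Assay arithmetic

* Lipid content: (W₂ − W₁)/M × 100, % of dry cell weight.
* Chlorophyll a: (12.7·A₆₆₃ − 2.69·A₆₄₅)·V/(1000·m) mg g⁻¹, and total
  carotenoids (7.6·A₄₈₀ − 1.49·A₅₁₀)·V/(1000·m). The printed forms of such
  equations are often ambiguous about parenthesisation; the
  difference-first (Arnon-style) form is used, under which both pigment
  contents are homogeneous of degree zero in (V, m) — doubling extract
  volume and biomass together changes nothing, as it must.
* Crude protein: elemental N % × 4.78, the microalgal nitrogen-to-protein
  factor (the general-purpose 6.25 overstates protein in algae because of
  non-protein nitrogen); a product above 100 % triggers a warning rather
  than an error, flagging an impossible composition.
* Cell volume: prolate spheroid V = (π/6)·L·W². The geometric model is an
  assumption — wall-less *Dunaliella* cells are ellipsoid-to-ovoid — and
  mean-dimension volumes computed this way sit slightly below published
  per-cell averages (Jensen's inequality: averaging after cubing exceeds
  cubing the average), so volumes are reported as model values, not
  reproductions.
* Salinity conversion: g L⁻¹ / 58.44 g mol⁻¹ for NaCl, molar mass
  overridable.

## Synthetic-data generator

The generator's defaults encode the emulated study design: five NaCl
levels (0.5–4.0 M) in triplicate, inoculum 10⁶ cells mL⁻¹, counts every
2 days for 35 days, 5 % multiplicative measurement noise.

* **Growth**: density holds at the inoculum through a 3-day lag, then
  follows a logistic K/(1 + (K/N₀ − 1)e^(−µ(t−lag))); K = ∞ degenerates to
  pure exponential growth. Per-salinity rates are 0.39 d⁻¹ at the 1.0 M
  optimum and 0.11 d⁻¹ at 4.0 M (the reported extremes); the intermediate
  values 0.35/0.30/0.22 d⁻¹ interpolate the reported monotone decline, and
  the capacities (5.2, 6.0, 5.0, 4.4, 2.2 ×10⁷ cells mL⁻¹) are set so
  day-30 densities land on the reported counts (≈5.7×10⁷ at 1.0 M). Noise
  is mean-one lognormal, so noisy counts are unbiased.
* **FAME profiles**: each condition's template is the packaged reference
  profile. Non-zero components (species and the unidentified share) are
  perturbed in log space and the whole composition renormalised to 100 %,
  so closure is exact to 1e−9, masses stay positive, and absent acids stay
  absent.
* **Assays**: readings are exact algebraic inversions of the assay formulas
  at a configured true composition (defaults: the published per-salinity
  composition and pigment tables), with fixed bench constants (50 mg lipid
  input, 10 g vial tare, 100 mL extract from 20 mg biomass, band-shape
  ratios A₆₄₅/A₆₆₃ = 0.35 and A₅₁₀/A₄₈₀ = 0.20) and optional mean-one
  lognormal noise. Zero-noise readings round-trip to the truth at machine
  precision; noisy readings recover it without bias.

Determinism: every generator is a pure function of (config, salinity,
replicate seed); the master seed spawns independent streams per generator ×
salinity × replicate via `numpy` seed sequences, so changing the replicate
count never shifts other replicates' draws.

**What the synthetic tests do not show.** The generator reproduces the
statistical *shape* of the study (phases, closure, noise structure), not
its biology: no osmoregulation, no light/temperature dynamics, no coupling
between salinity stress and the FAME template beyond the template columns
themselves. Passing recovery tests demonstrates the estimators are correct
on data satisfying their assumptions; they say nothing about model
misspecification on real cultures beyond the logistic-bias test described
above.

## Problem sizes and runtimes

The packaged analyses are closed-form and effectively instant (the
whole-table reproduction runs in well under a second). Simulation-backed
tests use 100–500 seeded replicates per claim: 200 curves for growth-rate
recovery, 200 draws for compositional-noise calibration, 500 for assay
unbiasedness — enough for the binomial/mean checks they support while
keeping the full suite around ten seconds.
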