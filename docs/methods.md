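# Methods

This note records the quantitative model behind `cryotrace`, the default
parameter values with their units, what the synthetic-experiment generator
does and does not emulate, and the numerical/design decisions a user should
know before interpreting output.

## 1. Experimental design assumed by the pipeline

Two sites (an agricultural and a forest soil) are incubated at two
temperatures (11 °C and 1 °C) with four field-plot replicates. Each plot is
split between the two incubators, so temperature contrasts are paired within
plot. Rates are assessed over two windows — an immediate window (0–42 h) and
an acclimation window (144–186 h) — under two amendments (glucose or water).
Two assay sets run in parallel:

- the **¹⁸O assay** (27 mL vials) with a labelled and a natural-abundance arm
  per condition, yielding DNA isotope pairs and headspace CO₂ for total
  respiration;
- the **¹³C assay** (50 mL vials, 15 mL headspace sampling at window start)
  with ¹³C-glucose or unlabelled water, yielding δ¹³C-resolved headspace CO₂,
  fumigation pairs and PLFA profiles.

## 2. Computation chain

### Isotope conversions
Atom fraction from delta notation: `af = R·(δ/1000+1) / (1 + R·(δ/1000+1))`
with the ¹³C reference ratio R = 0.0111802 (VPDB). Natural-abundance
backgrounds default to 1.08 at% ¹³C and 0.2005 at% ¹⁸O. Atom-percent excess
below background is clipped to zero and flagged, never returned negative.

### Respiration
Headspace CO₂ (ppm) converts to mass via the ideal gas law,
`µg C = ppm·1e-6 · P·V/(R_gas·T) · 12.011` with R_gas = 0.082057 L atm
mol⁻¹ K⁻¹. The start-of-window mass is corrected for the sampling event:
`m_t0_adj = m_t0·(1 − V_sampled/V) + m_replacement`. The rate is
`(m_t1 − m_t0_adj) / (t · g_dry)·1000` in ng C h⁻¹ g⁻¹ dry soil. By default
the headspace volume is the vial volume minus the soil volume
(bulk density 1.3 g cm⁻³); setting `Settings(bulk_density=None)` treats the
nominal vial volume as headspace. Negative rates are kept but flagged.
Because both arms of the ¹⁸O assay measure the same condition, the pipeline
averages total respiration over the two arms of each vial pair.

### Growth and CUE
`DNA_produced = O_DNA·(at%_L − at%_na)/at%_sw·100/31.21` (31.21 = mean oxygen
mass percent of DNA). Growth = `DNA_produced/DNA_total · MBC · 1000/t`.
CUE = growth/(growth+respiration) is computed **per replicate** and then
averaged; a ratio of condition means is deliberately not the default because
it cannot carry a standard error. Both rates zero → CUE is a flagged missing
value, not zero.

### ¹³C partitioning
MBC = (EOC_fum − EOC_nonfum)/k_EC with k_EC = 0.45; a negative flush is a
flagged missing value. Label fractions use two-pool mixing,
`f = (at%_pool − at%_bg)/(at%_tracer − at%_bg)`, clipped to [0, 1] with
flags. Label in MBC is the *difference of label amounts* in the fumigated and
non-fumigated extracts; division by k_EC is **off by default**
(`Settings(kec_correct_label=True)` enables it) because the flush difference
is itself the conventional "incorporated label" quantity. Label-derived
respiration applies the mixing model at both timepoints; replacement air
carries natural-abundance CO₂ and hence no label. Backgrounds for all mixing
calculations come from the matched water-amended control of the same plot,
temperature and window.

### PLFA
Markers are quantified against the 19:0 internal standard
(`amount = area/area_IS · IS_nmol / g_dry`). The allocation partition is
disjoint: *fungal* = {18:1ω9cis, 18:2ω6,9}; *bacterial* = union of the
gram-positive and bacterial marker lists {a15:0, i16:0, 16:1ω7, 10Me16:0,
a17:0, cy17:0, 10Me18:0, cy19:0}; *general* = all remaining markers.
Saturation is classified from the nomenclature (`:N` with N ≥ 1 double bonds
is unsaturated; cyclopropane and methyl-branched chains are saturated).
Label allocation weights each marker's carbon by its mixing fraction and
normalises within the grouping; a completely unlabelled profile returns a
missing allocation rather than 0/0.

### Response ratios
RR = R11/R1 computed per matched field plot, then summarised as mean ± SE
across plots. Site-contrast ratios (forest/agricultural at 11 °C, 42 h,
glucose) are rounded half-away-from-zero to one decimal.

## 3. Synthetic-experiment generator

The generator is the measurement model run forwards: design rates per
condition are produced from the 11 °C glucose-amended reference rates via the
response ratios (1 °C), acclimation multipliers (186 h window) and
glucose-effect divisors (water amendment); observations are then constructed
so that the pipeline's formulas invert them exactly at zero noise (verified
to ~1e-15 relative). Key default parameters:

| Parameter | Agricultural | Forest | Units |
| --- | --- | --- | --- |
| SOC | 8 864 | 45 641 | µg C g⁻¹ |
| MBC | 45.15 | 294.3 | µg C g⁻¹ |
| EOC baseline | 40 | 250 | µg C g⁻¹ |
| Total DNA | 8 | 55 | µg g⁻¹ |
| Total PLFA | 145.3 | 1 975 | nmol C g⁻¹ |
| Respiration (11 °C) | 119.9 | 975.2 | ng C h⁻¹ g⁻¹ |
| Growth (11 °C) | 87.98 | 569.9 | ng C h⁻¹ g⁻¹ |
| Label respiration (11 °C) | 23.11 | 101.1 | ng C h⁻¹ g⁻¹ |
| Label in MBC (11 °C, rate basis) | 58.29 | 229.4 | ng C h⁻¹ g⁻¹ |
| Glucose dose | 10 | 50 | µg C g⁻¹ |
| Water holding capacity | 0.385 | 0.75 | g g⁻¹ |

Tracer enrichments default to 20 at% ¹⁸O (final soil water) and 10 at% ¹³C
(glucose). Noise is multiplicative, mean-preserving lognormal for amounts and
areas (`exp(σz − σ²/2)`, `σ = sqrt(ln(1+cv²))`) and additive Gaussian on the
at% scale for isotope values; defaults are 3 % (gas), 5 % (extracts, areas),
0.02 at% absolute (isotopes), plus a 10 % between-plot lognormal multiplier
shared across temperatures so response ratios pair cleanly within plot.

The generator emulates measured tables only. It does **not** model pool
turnover dynamics within a window (rates are constant over each window),
freeze–thaw physics, microbial community change, or instrument drift;
per-condition truth values are stored alongside the tables for recovery
testing.

## 4. Statistical behaviour of the estimators

At zero noise the pipeline inverts the generator exactly. Under instrument
noise, replicate means converge to truth (all estimators are unbiased up to a
second-order `E[1/X]` term of ≈ cv² ≈ 0.25 % for the DNA-pool division).
One estimator is intrinsically noisy: MBC is a *difference of two extracts*
divided by 0.45, so with a 5 % extract CV the per-replicate MBC CV is
`0.05·sqrt(EOC_f² + EOC_nf²)/flush` — about 19 % for the agricultural
defaults (flush ≈ 20 µg C g⁻¹ on a ~40 µg C g⁻¹ EOC baseline) and about
11 % for the forest defaults. Growth multiplies by MBC, so with 100
replicates the standard error of a mean growth estimate is ≈ 1.7–2.2 %, and
a fixed ±2 % recovery band on growth is a near-coin-flip at any given seed;
respiration (direct, arm-averaged) and CUE recover well inside their bands.
This is a property of the fumigation-difference method at these pool sizes,
not of the implementation, and is why the test suite checks growth recovery
for statistical consistency (within 3 SE) while holding respiration to the
fixed 2 % band.

## 5. Design decisions

- **Per-replicate CUE** (then averaged), matching how a mean ± SE can be
  reported; the ratio-of-means is available downstream from the summary
  table.
- **RR pairing by field plot**: plots are the replication unit and each plot
  is split across the two incubators.
- **MBC entering growth** is the matched same-treatment, same-window
  fumigation MBC (configurable).
- **k_EC applies to bulk MBC only** by default, not to the label difference.
- **Flags, not silent fixes**: below-background excess, negative flushes,
  clipped label fractions, negative respiration and undefined CUE/RR are all
  carried as QC flags with missing values where appropriate.
- **Determinism**: one master seed; per-table child generators derived
  deterministically; identical seeds produce byte-identical CSV output.

## 6. Problem sizes and runtime

Default experiment: 2 sites × 4 plots × 2 temperatures × 2 windows × 2
amendments with both assays ≈ 1 900 table rows; simulation plus full
processing takes ~1–2 s. The 100-plot noise-recovery experiment runs in
~10 s on one CPU. The full test suite (including property-based tests) runs
in under 30 s.
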