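# Methods

## Steady-state physiology

The chemostat model is the standard one: at steady state the specific
growth rate equals the dilution rate D (h⁻¹), and volumetric rates are
D times concentrations. Carbon and nitrogen are tracked as **elemental
grams** (g C, g N) throughout. This is the only convention under which
the published yield table is internally consistent: with NH4Cl fixed at
1 g/l (0.2619 g N/l), total CDW as ΔX, and residuals read as g element
per liter, the recomputed Y_X/C and Y_X/N match all six printed
coefficients within 1.3 %.

Conventions that matter and why:

* **Feed decanoate is decanoic-acid equivalents** (MW 172.26 g/mol,
  10 C). The 8.70 g/l feed then gives a molar feed ratio of 27.0,
  matching the printed 26.97 within 0.3 %; the sodium-salt mass
  (194.25 g/mol) does not reproduce the printed ratios.
* **ΔX includes stored PHA.** Y_X/N = 17.7 for the nitrogen-limited
  culture is only reachable with total CDW (4.63 g/l) in the numerator.
  Specific rates, by contrast, are normalized to the PHA-free residual
  biomass X = CDW·(1 − f), the catalytically active fraction.
* **Boundary equation uses integer masses 14 and 12**, as conventional
  for the Egli dual-limitation criterion; all other conversions use
  14.007/12.011. The difference is below 0.1 % and documented so the
  two ratio scales are not mixed.
* **Below-detection residuals count as zero consumption.** The
  nitrogen assay's detection limit (1.9 mg N/l) is retained on the
  record as an uncertainty bound, not subtracted.
* **Boundary values classify as dual** (closed interval): the borders
  are the edges of the dual-limitation window.

The carbon balance converts each sink to C-mol/l: PHA-free biomass at
27 g/C-mol; PHA via the monomer composition (repeat units C6H10O2,
C8H14O2, C10H18O2 at 114.14/142.20/170.25 g/mol with 6/8/10 carbons);
CO2 as CER/D, with CER from off-gas fractions at 1 atm and 25 °C
(molar volume 24.45 l/mol) and an ambient inlet fraction of 4·10⁻⁴.
Closure is outputs over consumed; values above 1.05 flag over-closure
with a warning rather than an exception, since measurement noise can
legitimately overshoot.

Steady-state detection follows the operational criterion: every
monitored on-line channel (OD, dissolved O2, off-gas CO2) must stay
within 5 % relative deviation of its window mean over a trailing window
of four residence times (40 h at D = 0.1 h⁻¹). Both the tolerance and
the window length are configuration knobs; the detector is validated
against an exhaustive window-scan oracle.

## PHA quantification

Single-point internal-standard calibration
(mass = area/area_IS · m_IS · rf) with unit response factors by
default; response factors are per-monomer configurable because GC
response of methyl esters varies with chain length but no calibration
curves are published. Quantification is expressed in polymer
repeat-unit equivalents (what a composition table states), not
methyl-ester masses.

## Differential expression

The array reduction deliberately replaces model-based microarray
preprocessing (normexp background, vsn, moderated t) with a simpler,
fully specified chain: background subtraction floored at half the
smallest positive corrected intensity per array (keeps ratios finite),
log2(test/ref), per-array median centering, a per-locus one-sample
t-test across replicate arrays, and Benjamini–Hochberg step-up
adjustment. BH is implemented directly (it is a specified primitive
here) and cross-checked in tests against statsmodels and a brute-force
step-up oracle.

Call rules follow the published wording exactly: transcripts need the
fold change to *exceed* 2 (strict >) with adjusted p < 0.05; the strict
secondary screen needs fold > 3.5 with raw p < 0.03; proteins need
ratio ≥ 2 ("twofold or higher", inclusive) or ≤ 0.5 with p < 0.05 from
a Welch t-test on log2 spot volumes across triplicate gels (the
original test is unstated; Welch is the conservative default). Signed
fold changes use the microarray-table convention (−6.7 = 6.7-fold
down). Spots detected in only one condition pass through as
presence/absence calls.

With three replicates the per-feature t-test has 2 degrees of freedom,
and BH at 10,000 features demands very small p-values once discoveries
are few. This produces a sharp power cliff in the replicate log-ratio
noise: the pipeline's recall of ≥4-fold planted effects is essentially
complete when the replicate log2 sd is near 0.1 and collapses by
sd 0.25. The generator default (sd 0.10) therefore represents
well-normalized arrays whose replicate scatter is technical-dominated;
the parameter is exposed for studying the degradation, and the power
estimate at 2-fold effects and sd 0.25 is tested against an
independent Monte-Carlo oracle.

## Metabolomics

Retention indices use the linear (temperature-programmed) Kovats form,
piecewise linear between bracketing alkanes, exact (100·n) on ladder
points; extrapolation beyond the ladder span must be requested
explicitly. The match factor is the cosine of √-scaled intensities
over the union of integer m/z bins — the metric family used by common
GC-MS deconvolution tools — with acceptance at ≥ 0.75 and candidate
gating to a ±5 RI-unit window (both configurable; the original tool's
settings are not published). Quantification is relative:
area / IS(ribitol) area / g CDW, which cancels injection volume and
biomass differences and makes planted concentration ratios recoverable
up to one global constant.

QC reports RSD = 100·sd/mean (sample sd) per metabolite × condition ×
replicate class; technical means within-fermentor, biological across
independent cultivations. Pearson correlation between condition mean
profiles is computed on log10 abundances to stabilize variance across
the orders-of-magnitude spread of metabolite pools. Metabolites whose
biological RSD exceeds a ceiling (default 60 %) are excluded from
level-change calls — mirroring the practice of dropping metabolites
too variable across cultivations — and report "n.d.". Level-change
calls use a 1.5-fold threshold on condition means vs the carbon-limited
reference; the published table is qualitative, so the threshold is a
documented knob rather than a derived constant.

## Synthetic study generator

The generator emulates the study design: three conditions (carbon,
dual, nitrogen limitation) at D = 0.1 h⁻¹, three biological
replicates, condition parameters seeded from the published steady-state
table (so the demo run reproduces a familiar summary shape). Planted
steady states close the carbon balance exactly — the per-condition CER
is derived as consumed − biomass − PHA carbon — and all measurements
are then perturbed with multiplicative lognormal noise (mean 1), the
simplest model consistent with RSD-style QC: 22 % RSD for offline
assays (CDW, PHA fraction, residuals, GC areas), 32/28/49 % biological
RSD for metabolite pools per condition, and 1 % for on-line sensor
channels (OD, dissolved O2, off-gas), which are far steadier than
offline assays and would otherwise be incompatible with a 5 %
steady-state tolerance. Traces follow first-order wash-in
x(t) = x_ss(1 − e^(−Dt)), which reaches the 5 % band at t = ln(20)/D ≈
30 h at D = 0.1 h⁻¹, so a four-residence-time window first qualifies
between five and eight residence times — the range reported for real
runs.

Arrays plant symmetric up/down log2 effects (default magnitude uniform
on [1, 5], mirroring published fold-change ranges of roughly 2–28) on
5 % of features over a lognormal intensity baseline with an additive
scanner background. Gel spots sample array loci so transcript and
protein directions agree on the planted subset; a fraction appear in
only one condition. Metabolite peaks are laid down at retention times
back-interpolated from library retention indices with spectra
proportional to (reproducible pseudo-)library spectra; a ribitol
internal-standard peak is injected per sample. The library spectra and
per-metabolite base levels are deterministic functions of the compound
name, and every generator is deterministic in its seed.

**What passing on synthetic data does not show:** the generator
enforces the study's accounting identities rather than any growth
kinetics, uses independent features (no probe cross-hybridization or
co-elution), perfectly known backgrounds, and spectra without shared
fragment structure beyond one common silyl marker ion. Recovery rates
on this data are upper bounds for real instruments; the tests validate
the pipeline's arithmetic and decision rules, not instrument
performance.

## Problem sizes

Simulation-based checks use 100 array datasets of 10,000 features × 3
replicates, 100 replicate physiology studies for yield-recovery bias,
200 random traces against the steady-state oracle, and 1,000 random
vectors against the BH oracle — sizes chosen to keep Monte-Carlo error
well below the tolerances being checked while the whole suite runs in
seconds.

## Known limitations

* The CO2 evolution rate assumes dry off-gas at 1 atm/25 °C and a
  fixed inlet fraction; no inert-gas (N2) balance correction is
  applied.
* Protein spot statistics assume log-scale volumes; saturated or
  merged spots are out of scope, as is identification.
* The regime borders are computed from the two single-limitation
  conditions; with more conditions a regression-based border estimate
  would be preferable.
* No growth kinetics: the generator cannot produce transient
  phenomena (washout, oscillations), only wash-in to a planted steady
  state.
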