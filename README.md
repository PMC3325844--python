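# phaomics

Quantitative analysis pipeline for chemostat multi-omics studies of
polyhydroxyalkanoate (PHA) production in *Pseudomonas putida*.

Continuous cultures fed decanoate (carbon) and NH4Cl (nitrogen) can sit
in three growth regimes — carbon-limited, dual (carbon–nitrogen)
limited, and nitrogen-limited — depending on the molar feed ratio
C0/N0. This package implements the steady-state accounting that maps
measurements to those regimes and the reduction steps for the
accompanying omics layers:

* **Physiology** — elemental yield coefficients
  `Y_X/C = ΔX/ΔC`, `Y_X/N = ΔX/ΔN` (g biomass per g elemental C or N),
  biomass-specific rates `q_PHA = PHA·D / X_PHA-free`, the Egli
  dual-limitation boundary `C0/N0 = (Y_X/N·14)/(Y_X/C·12)` mol/mol,
  regime classification, a C-mol carbon balance over biomass
  (27 g/C-mol), PHA and off-gas CO2, and steady-state detection
  (constant OD / dissolved O2 / off-gas over four residence times).
* **PHA quantification** — GC peak tables with internal-standard
  calibration to monomer masses (C6/C8/C10 3-hydroxyacyl repeat units),
  mol% composition, PHA content as % CDW, and PHA carbon for the
  balance.
* **Differential expression** — two-channel array log-ratios with
  background flooring and median centering, one-sample t-tests,
  Benjamini–Hochberg FDR, the standard call rule (fold > 2, adjusted
  p < 0.05) and a strict screen (fold > 3.5, raw p < 0.03); 2-D-gel
  spot calls (ratio ≥ 2 or ≤ 0.5, p < 0.05, presence/absence flags);
  comparison overlap and transcript–protein concordance.
* **Metabolomics** — Kovats retention indices against a C10–C36
  n-alkane ladder, cosine match factor on √-scaled spectra with the
  ≥ 0.75 acceptance rule, ribitol/CDW normalization, RSD and Pearson
  QC, and level-change calls against the carbon-limited reference.
* **Synthetic study generator** — a planted-truth emulation of the full
  design (3 conditions × 3 replicates at D = 0.1 h⁻¹, multiplicative
  lognormal noise) so every stage is testable offline.

## Worked example

The package carries the published steady-state measurements as its
worked-example dataset. Recomputing the physiology table:

```sh
python analysis/02_physiology.py
```

prints

```
           c0_n0   y_xc    y_xn  border_lower  border_upper    regime  q_pha
carbon      5.83  1.115   9.742        10.191        20.165    carbon  0.035
dual       16.56  1.170  16.612        10.191        20.165      dual  0.163
nitrogen   26.97  1.023  17.681        10.191        20.165  nitrogen  0.415
```

Reading: each condition's biomass yields on elemental carbon and
nitrogen are recomputed from feed, CDW and residual nutrients; the
dual-limitation window (borders in mol C/mol N) comes from the carbon-
and nitrogen-limited yields, and the three feed ratios fall on the
carbon side, inside, and on the nitrogen side of it. The
nitrogen-limited culture converts stored carbon fastest: q_PHA ≈ 0.41 g
PHA per g PHA-free biomass per hour at D = 0.1 h⁻¹.

The full analysis chain runs as numbered scripts:

```sh
python analysis/01_simulate.py                 # synthetic study inputs
python analysis/02_physiology.py               # yields, borders, balance
python analysis/03_differential_expression.py  # arrays + gels
python analysis/04_metabolomics.py             # annotation, QC, levels
python analysis/05_report.py                   # summary tables
```

Each writes its tables under `results/`. The same stages are available
as a CLI (`phaomics simulate|physiology|regimes|balance|de|metab|report`).

## Layout

```
src/phaomics/       library (physiology, pha_gc, omics_de,
                    metabolomics, synthetic, io, reference, cli)
analysis/           numbered narrative drivers
tests/              pytest suite (unit, property and end-to-end)
scripts/            acceptance recomputation
docs/methods.md     models, parameters, numerical choices
```
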