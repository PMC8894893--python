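# ferriflux

Computational core for acetate-fed anaerobic batch incubations probing
competition between iron-oxide reduction and methanogenesis:

* **`ferriflux.thermo`** — a reaction free-energy ("thermodynamic ladder")
  engine. A built-in registry of five element- and charge-balanced,
  per-mole-acetate reactions (magnetite, ferrihydrite, goethite and hematite
  reduction plus acetoclastic methanogenesis) with standard reaction
  energies; in-situ `delta_g` via `dG = dG0 + RT ln Q` (solids and water at
  unit activity, H+ from pH, concentrations treated as activities, defaults
  T = 298 K and R = 8.314e-3 kJ/mol/K); per-decade sensitivities;
  favorability ladders with documented tie-breaking; crossover activities by
  bisection; gridded energy landscapes.
* **`ferriflux.headspace`** — headspace methane quantification for sealed
  500 mL bottles (300 mL headspace over 200 mL liquid): last-five readout
  averaging of multi-ion RGA scans (m/z 2, 15, 16, 18, 28, 32, 44; CH4
  quantified on 15 only, CO2 on 44), linear calibration of CH4:N2 and CO2:N2
  signal ratios, mole fractions `F = R / (R_CH4 + R_CO2 + 1)` (the CO2
  fraction takes `R_CO2` in the numerator), ideal-gas conversion at 1 atm /
  298 K, headspace growth from ~6 mL liquid withdrawals, and cumulative
  production corrected for the ~7 mL of gas the analyzer consumes per
  measurement. Windowed production rates and max-rate window search.
* **`ferriflux.iron`** — Ferrozine/HCl-extraction bookkeeping: dilution
  correction (1.5 mL sample into 1.5 mL acid), Fe(II)/Fe(III) split with an
  assay-noise clamping tolerance, interval-valued solid-phase Fe(II) bounds
  (the aqueous pool's valence is unknown), and the acetate electron budget
  (8 mol Fe(III) per mol acetate vs. 1 mol CH4 per mol acetate).
* **`ferriflux.synth`** — seeded synthetic incubations (latent truth plus
  forward-modelled RGA scans and wet-chemistry tables) with presets for
  ferrihydrite / goethite / hematite / no-iron control conditions: ~2 mmol
  logistic methane curves with condition-dependent lag, a ~6 mM Fe(II)
  plateau by ~day 10 for ferrihydrite (<1 mM otherwise), an acetate pool
  rising to ~15 mM then drawn down stoichiometrically, and realistic
  settling transients plus Gaussian noise on every instrument channel. At
  zero noise the processing pipeline recovers the truth to machine
  precision.

## Command line

```sh
ferriflux thermo-table --out table.tsv            # registry energies (TSV)
ferriflux landscape --species Fe2+ --log10-min -8 --log10-max -2 --out scape.tsv
ferriflux simulate --condition ferrihydrite --seed 1 --outdir sim/
ferriflux gas-process --scans sim/scans.csv --events sim/events.csv \
    --calibration sim/calibration.csv --out gas.csv
ferriflux fe-process --in sim/fe_samples.csv --out speciation.csv
ferriflux budget --delta-fe2-mol 0.002 --delta-ch4-mol 0.002
```

All numeric output is fixed to 12 significant digits, so reruns on
identical inputs and seed are byte-identical. `--log-level info` surfaces
per-timepoint correction logging in `gas-process`.

### CSV dialects

| table | columns |
| --- | --- |
| scans | `bottle, day, elapsed_s, mz, signal` (long format) |
| events | `bottle, day, liquid_mL, gas_mL` |
| calibration | `analyte, mz, slope, intercept` |
| iron samples | `bottle, day, fe2_raw_mM, fetot_raw_mM, aqueous_mM, dilution` |
| gas output | `bottle, day, volume_mL, f_ch4, f_co2, f_n2, n_present_mol, n_removed_cum_mol, n_produced_mol` |

Days are floats (since inoculation), concentrations mM, moles mol.

## Bookkeeping switches

* `--include-current-removal/--no-include-current-removal` — whether the
  current measurement's own analyzer gas consumption is credited back into
  that timepoint's cumulative production (default: yes; the first timepoint
  always reports only the methane present).
* Liquid withdrawals enlarge the headspace for strictly later measurements
  (the initial 300 mL applies unchanged at the first timepoint).
* `--pressure-atm` — total headspace pressure, fixed at 1 atm by default.
* `--nominal-gas-ml` — override per-event analyzer consumption with a fixed
  nominal volume (e.g. 7 mL for a 3-minute scan at 1 mL per 26 s).

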