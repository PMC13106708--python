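# diatom-sync

Simulation and analysis toolkit for light-gated collective "wobbling" in
populations of elongated, sinking diatom cells. The package models a
blue/far-red–activated, red-deactivated photoreceptor that gates both
cell-to-cell coupling and the response to pulsed light, a laser-diffraction
(LISST-style) observation model that turns cell orientations into 32-bin
size-class volume concentrations and the scalar orientation proxy
`Ratio = ΣVD1/ΣVD2`, and the spectral analysis used to quantify collective
oscillations (prominence-gated Gaussian peak fits, Pk/FWHM amplitudes,
entrainment indices).

## Modules

| module           | purpose |
|------------------|---------|
| `lightfield`     | Multiband illumination protocols (constant / sinusoidal bands) and the two-state photoreceptor photostationary model |
| `population_sim` | Kuramoto-type coupled phase-oscillator population with photoreceptor-gated coupling and forcing; the synthetic-data generator |
| `ld_forward`     | Orientation → 32 log-spaced size classes → `Ratio` orientation proxy |
| `fluorescence`   | Two-band (λ>645 nm, λ>715 nm) chlorophyll autofluorescence observation model |
| `spectra`        | Variance-normalized periodogram, peak prominences, fit-mode gate, Gaussian peak characterization, entrainment index |
| `experiments`    | Config-driven experiment families (wavelength scan, composed red:blue, pulsed light, fluorescence) with triplicate summaries and CSV/JSON outputs |

## Command line

```bash
# run an experiment family end-to-end (defaults used when --config omitted)
diatom-sync run wavelength_scan --out out/scan
diatom-sync run pulsed --config my_pulsed.json --out out/pulsed

# spectral characterization of an externally supplied Ratio CSV
# (columns: time_s, ratio, valid)
diatom-sync analyze --ratio-csv ratio.csv --out out/analysis

# emit small canned datasets for smoke tests
diatom-sync fixtures --out fixtures/
```

Experiment configurations are JSON documents (see
`ExperimentSpec.to_json()`); every run is reproducible bit-for-bit from its
config and seed list.

## Model notes

- Coupling and forcing sensitivities are multiplied by the photoreceptor
  activation fraction, which is ratiometric in band irradiances
  (photostationary state); knockout genotypes have the gate pinned to 0.
- The first 100 s of every run are a mixing phase (phases re-randomized
  each step) and are excluded from all spectral analyses.
- The laser-diffraction model is a geometric projection proxy, not a Mie
  inversion: each cell splits its volume between the bin of its apparent
  (projected) major extent and the bin of its minor axis, with weights
  linear in apparent length.
- The main-peak/full-spectrum fit-mode gate (sample std of the leading
  relative prominences > 1) is calibrated for instrument-scale records
  (~2 h at 1 Hz); much shorter records may mis-gate noise spectra.
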