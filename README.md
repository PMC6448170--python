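# ctmcdose

A desk-scale simulator of a characterized wide-beam CT scanner for radiation
dosimetry: an x-ray source model (spectrum filtration, bowtie filter, z-axis
beam profile / heel effect, axial/helical/TCM tube trajectories) feeding a
lightweight voxel Monte Carlo photon-transport kernel (Woodcock delta
tracking, photoelectric / Klein-Nishina Compton / Thomson Rayleigh under the
collision-kerma approximation) with energy-deposition and track-length
energy-fluence tallies and batch statistics.

## Modules

| module | contents |
| --- | --- |
| `ctmcdose.spectrum` | binned fluence spectra, Beer-Lambert filtration, air kerma, HVL, two-layer equivalent-filter fit, analytic fallback tube spectrum, packaged attenuation tables |
| `ctmcdose.scanner_model` | bowtie thickness fit from normalized exposure ratios, beam-profile FWHM and discretization, sampling PDFs, total source strength Q |
| `ctmcdose.acquisition` | scan protocols (axial / helical / static), TCM tables, tube-state sampling, photon emission |
| `ctmcdose.phantom` | HU -> density and HU -> elemental-composition calibration, DICOM voxelization, couch merging, fixture phantoms (CTDI body, air chamber, water cylinder, couch, block) |
| `ctmcdose.transport` | material cross-section mixing, Woodcock transport engine, tallies, batch statistics, fluence-to-kerma conversion |
| `ctmcdose.dosimetry` | CTDI and couch-attenuation correction factors, start-angle averaging, measurement-error propagation, dose reports |
| `ctmcdose.dicomio` | minimal Explicit-VR-Little-Endian CT series reader/writer (test-data generation and voxelization input) |

## CLI

```sh
# characterize a source: equivalent filter from kerma + HVL targets
ctmcdose fit-filter --spectrum spec.csv --target-kerma 30.5 --target-hvl 7.0

# fit bowtie + beam profile into a reusable scanner-model JSON
ctmcdose fit-bowtie --measurements bowtie.csv --profile profile.csv --out model.json

# generate a fixture phantom and simulate
ctmcdose make-fixture ctdi_body --out phantom/
ctmcdose simulate --phantom phantom/ --tally isocenter_chamber \
    --n 1e6 --batches 10 --seed 7 --out report.json

# apply correction factors
ctmcdose report --dose-report report.json \
    --ctdi-measured 0.84 --ctdi-simulated 0.90 \
    --table-with 0.90 --table-without 0.94
```

Protocol files are flat `key = value` text (`mode`, `kv`, `ma` or `tcm_file`,
`rotation_time_s`, `exposure_time_s`, `pitch`, `collimation_mm`,
`start_angle_deg`, `start_z_mm`, `direction`). Measurement CSVs:
`distance_cm,normalized_exposure` (bowtie) and `z_mm,normalized_intensity`
(beam profile); TCM CSVs: `slice_z_mm,ma`.

## Packaged data

* `data/xs/*.csv` - photon mass attenuation / energy-absorption coefficients
  (cm^2/g, 1-160 keV) for the calibration elements and common compounds,
  generated from the xraylib compilation by `scripts/generate_xs_tables.py`
  (only needed to regenerate the tables).
* `data/hu_composition.csv`, `data/hu_density.csv` - the HU calibration.
* `data/bowtie_measurement.csv`, `data/beam_profile_80mm.csv` - synthetic
  characterization measurements so the full pipeline runs self-contained.

## Physics scope and approximations

* Collision kerma = absorbed dose (no electron transport): secondary-electron
  ranges are sub-voxel at CT energies; energy transferred to electrons is
  deposited at the interaction site.
* Compton scattering uses the free-electron Klein-Nishina cross section (no
  binding or Doppler broadening); Rayleigh uses the Thomson angular shape
  with tabulated coherent channel probabilities.
* The packaged energy-absorption channel is photoelectric plus the
  Klein-Nishina mean energy-transfer fraction of the incoherent channel,
  exactly consistent with the transport kernel's deposition model.
* Photon cutoff 1 keV; photons below it deposit locally.
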