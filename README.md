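# nanoswitch

Analysis toolkit for transient mid-infrared near-field nanoscopy of
photoswitchable lipid vesicles: a multilayer finite-dipole forward model of
s-SNOM contrast, vesicle segmentation and shape statistics, sigmoidal
photoswitching-kinetics fitting with detection-significance statistics, and
nano-FTIR interferogram-to-spectrum processing — all exercised against a
seeded synthetic-scene generator that pairs every artifact with an analytic
ground-truth record.

## Modules

| Module | Purpose |
| --- | --- |
| `nanoswitch.forward_model` | Quasi-static finite-dipole model over a layered sample (transfer-matrix `beta(q)`, momentum-weighted `beta_eff`, harmonic demodulation, referenced spectra, hanging-sphere vs flattened-disc lateral profiles) |
| `nanoswitch.synthetic_scene` | Seeded generators: vesicle images (flat-top discs with raised-cosine fringes), state pairs with controlled area/circularity changes, sigmoid switching traces with boxcar sampling, asymmetric-Michelson interferograms |
| `nanoswitch.image_analysis` | Background subtraction, 1/e-of-peak or absolute-threshold segmentation, sub-pixel area/perimeter/circularity (4πA/p²), Gaussian line-profile FWHM, switching-series tables |
| `nanoswitch.transient_analysis` | Epoch splitting by illumination label, moving averages, logistic-step fits f(t) = C + L/(1+e^−(t−t_d)/τ), plateau step statistics, Monte-Carlo detection power vs sampling time |
| `nanoswitch.nanoftir` | Interferogram → complex amplitude/phase spectrum, referencing, complex averaging, white-light reduction |
| `nanoswitch.cli_io` | TIFF/text + JSON-sidecar images, CSV traces/interferograms/spectra, config loading, acquisition-duration and irradiance bookkeeping |

## CLI

All subcommands exit 0 on success, 1 on user error, 2 on internal error.

```sh
# acquisition bookkeeping: 1200 pts x 35 ms x 20 averages, 30 mW over 0.25 mm^2
nanoswitch plan --points 1200 --tp 0.035 --averages 20 --power-mw 30 --area-mm2 0.25

# synthetic artifacts (spec files are plain JSON/YAML; see tests for examples)
nanoswitch simulate image --spec scene.json --seed 7 --out out/
nanoswitch simulate trace --spec trace.json --seed 7 --out out/

# forward model: referenced contrast spectrum for a stack JSON
nanoswitch forward --stack stack.json --nu-min 1400 --nu-max 1800 \
    --harmonic 2 --reference si --out spectrum.csv

# segmentation and switching series
nanoswitch segment --amplitude img_amplitude.tif --pixel-size 10 \
    --criterion efold --seed-x 64 --seed-y 64 --out metrics.json
nanoswitch series --manifest states.csv --seed-x 64 --seed-y 64 --out series.csv

# trace kinetics and detection power
nanoswitch fit-trace --trace trace.csv --channel amplitude --out fits.json
nanoswitch power --tp 0.03,0.1,0.5 --seeds 500 --out power.csv

# nano-FTIR processing
nanoswitch spectrum --ig ig.csv --reference ref.csv --band 1200,2000 --out spec.csv
```

Stack JSON layers go ambient-first, substrate-last; interior layers carry a
`thickness_nm`, half-spaces use `null`:

```json
{"layers": [
  {"eps": [1.0, 0.0], "thickness_nm": null},
  {"material": "sin_membrane", "thickness_nm": 10},
  {"material": "lipid_trans", "thickness_nm": 4},
  {"material": "d2o", "thickness_nm": null}
]}
```

Material names resolve against the editable oscillator table in
`src/nanoswitch/data/materials.csv` (illustrative surrogates, not literature
fits).

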