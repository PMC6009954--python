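# spotassay

Spectrophotometer-free read-out for radical-scavenging (DPPH•) assays.
Reaction mixtures dropped on a TLC plate are scanned; each spot's **colour
value** (mean grey value in a circular ROI) is measured, and the
half-maximal scavenging concentration is estimated two ways:

* **SC50** — spectrophotometric branch: the concentration halving the
  initial 517 nm absorbance, by linear interpolation on the mean curve.
* **CSC50** — colour branch: the concentration raising the spot colour
  value halfway from the zero-scavenging blank to the complete-reduction
  maximum, either by direct half-maximum read-off (`csc50_halfmax`) or from
  the first-derivative curve, Δcolour/Δconcentration, taking the
  concentration of the steepest rise (`csc50_derivative`).

Validation metrics (LOD = 3.3σ/S, LOQ = 10σ/S, CV, cross-method OLS R²)
and a fully seeded synthetic plate simulator (logistic scavenging model,
soft-edged spot rendering, scanner brightness/contrast transform, Gaussian
noise) round out the pipeline so every stage is testable against ground
truth.

## Modules

| module               | contents                                                                 |
|----------------------|--------------------------------------------------------------------------|
| `plate_model`        | `PlateLayout`, `DilutionSeries`, `SpotMeasurement`, curves/results, `build_serial_dilution`, `layout_to_wells` |
| `image_quant`        | `to_grey`, `mean_grey_value`, `refine_spot_centres`, `quantify_plate`    |
| `dose_response`      | `aggregate_curve`, `blank_correct_extract`, `percent_scavenging`, `sc50_from_absorbance`, `csc50_halfmax`, `derivative_curve`, `csc50_derivative` |
| `validation_metrics` | `cv`, `lod_loq`, `response_noise_and_slope`, `method_agreement`          |
| `synthetic_plate`    | `ScavengingModel`, `render_plate`, `simulate_absorbance_series`, `end_to_end_recovery` |
| `io_cli`             | CSV readers/writers, `run_pipeline`, the `spotassay` CLI                 |

## CLI

```bash
# render a synthetic plate + absorbance ladder from a JSON config
spotassay simulate --config sim.json --out-dir fixtures/ --seed 4

# measure all layout wells on a scanned plate image
spotassay quantify --image fixtures/plate.png --layout fixtures/layout.json \
    --out spots.csv [--no-refine]

# estimate CSC50 (colour) or SC50 (absorbance) per sample
spotassay fit --measurements spots.csv --kind colour \
    --methods halfmax,derivative --out csc50.csv
spotassay fit --measurements fixtures/absorbance.csv --kind absorbance --out sc50.csv

# LOD/LOQ/CV and cross-method agreement
spotassay validate --measurements spots.csv --blanks blanks.csv --out validation.csv
spotassay compare --a sc50.csv --b csc50.csv --out agreement.csv
```

Shared flags: `--seed`, `--force` (outputs are never silently overwritten),
`--log-level`. A simulate config looks like:

```json
{
  "format_version": 1,
  "sample_id": "std",
  "model": {"true_c50": 200.0, "hill": 2.0, "form": "logistic_log"},
  "ladder": {"top_concentration": 3000.0, "dilution_factor": 2.0, "n_levels": 9, "unit": "uM"},
  "layout": {"n_rows": 3, "n_cols": 10, "origin": [24, 24], "pitch_x": 36, "pitch_y": 36, "spot_radius": 10},
  "render": {"background_grey": 230, "dpph_dark_depth": 150, "noise_sd": 2.0},
  "n_replicates": 3,
  "absorbance": {"a0": 1.0, "noise_sd": 0.02}
}
```

## Conventions

* A "1:1" serial dilution means two-fold: level k holds `top / 2**k`.
* RGB→grey uses 0.299/0.587/0.114 luminance weights, rounded half-up;
  ROI membership is pixel-centre-in-disc (integer pixel counts).
* Higher mean grey value = lighter spot = more radical scavenged; values
  are never inverted.
* Interpolation is on the linear concentration axis; the derivative uses
  raw forward differences assigned to pair midpoints, no smoothing.
* Concentration units are opaque labels; mixing them in one curve errors.

## Tests and acceptance report

```bash
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script regenerates everything from scratch (seeded) and
reports the pooled SC50↔CSC50 agreement R² at low noise, the worst
simulator→quantifier round-trip grey error, and the worst noiseless
recovery error of CSC50 against the generative model.
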