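# insolegait

Signal-processing toolkit for pressure-sensitive insoles built on
optoelectronic force sensors ("tactels"). It covers the full computation
chain of such a device, plus a synthetic gait simulator so everything is
testable without hardware:

- **transduction** — quartic voltage-to-force calibration model
  (`F = p1·V⁴ + p2·V³ + p3·V² + p4·V + p5`) with a piecewise zero branch above
  the noise-floor voltage, its numerical inverse, the system contact
  threshold (`n_sensors · f(V_thresh)` ≈ 3 N for 16 sensors), and calibration
  fitting from quasi-static load–unload cycles.
- **layout** — 16-tactel insole geometry and antero-posterior density weights
  (`1 / tactels-per-AP-bin`) that de-bias the centroid for clustered sensors.
- **biomech** — per-frame conversion of voltage streams into vGRF and the
  antero-posterior center of pressure (CoP_AP, NaN during swing); causal, so
  batch and one-sample-at-a-time processing are bit-identical.
- **events** — threshold-based heel-strike/toe-off detection with two-pass
  debouncing, stride tables, and temporal parameters (median/IQR).
- **validation** — comparison battery against a reference force plate:
  trigger alignment and 200→100 Hz resampling, median-absolute-error of event
  times (s and % of stance), stance-normalized profiles, Pearson ρ and RMSE
  between average profiles, within-device repeatability, and body-mass
  normalized peaks.
- **simulator** — parametric double-bump stance vGRF and logistic heel-to-toe
  CoP, Gaussian per-tactel force allocation, inverse transduction with
  first-order sensor lag and voltage noise, and ground-truth stride tables
  anchored at the reference 20 N threshold.
- **placement** — sensor ranking by event responsivity/amplitude and
  synchrony scoring of reduced sensor subsets against the full grid.
- **io / cli** — versioned delimited-text formats and a `click` CLI.

## CLI

```sh
# generate a synthetic trial bundle (insole stream, reference, ground truth)
insolegait simulate --out bundle/ --seed 7 --n-strides 20

# voltage stream -> vGRF/CoP signals + stride table
insolegait process bundle/insole_stream.csv \
    --calibration bundle/calibration.json --layout bundle/layout.json \
    --out-signals signals.csv --out-strides strides.csv

# detect events on an existing signals file
insolegait events signals.csv --threshold 3.074 --out strides.csv

# validate insole signals against the reference recording
insolegait validate signals.csv bundle/reference.csv \
    --body-mass 66.2 --out report.json

# sensor-reduction study
insolegait rank-sensors bundle/insole_stream.csv \
    --layout bundle/layout.json --out ranking.json
insolegait eval-subset bundle/insole_stream.csv \
    --layout bundle/layout.json --subset subset.json --out eval.json
```

`insolegait -v <command>` raises log verbosity (config hash and seed are
logged for reproducibility).

## File formats

All time series are plain CSV with a versioned schema comment line
(`# insolegait-csv v1 <kind> ...`); calibrations, layouts, reports and
manifests are JSON. Undefined CoP samples are written as empty fields.
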