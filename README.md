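# quantpk

A tested, reusable pipeline for bioanalytical LC-MS/MS pharmacokinetic
drug-drug-interaction (DDI) studies in small animals:

- **`quantpk.simulate`** — synthetic study generator: one-compartment oral
  absorption for each parent drug, first-order formation/elimination of a
  metabolite, log-normal between-subject variability, proportional+additive
  assay noise and BLQ censoring; plus stage-tagged calibration/QC response
  batches. Seeded runs are bit-reproducible.
- **`quantpk.calibration`** — least-squares calibration lines (unweighted by
  default, 1/x and 1/x² optional) with the full regression statistics
  (r, S_a, S_b, S_y/x), back-calculation with range flags, LLOD/LLOQ
  determination by blank-signal ratios plus accuracy/precision gates, and
  dilution correction.
- **`quantpk.validation`** — method-validation metrics with acceptance rules:
  accuracy/precision (recovery %, Er %, RSD %), extraction recovery, matrix
  effect, selectivity, carryover, stability, dilution integrity, and a
  battery runner producing per-metric pass/fail records.
- **`quantpk.nca`** — non-compartmental analysis (Cmax/tmax by inspection,
  terminal Kel from a best-adjusted-R² log-linear window, t½ = 0.693/Kel,
  linear-trapezoidal AUC0–t, AUC0–∞ extrapolation, CL/F) and the DDI
  statistics: relative bioavailability %, metabolite/parent ratio %, and
  pooled/Welch two-sample t-tests, summarized in a single-vs-combination
  table.
- **`quantpk.io_config`** — CSV profile I/O with schema validation, YAML
  configuration with strict key checking, and report writing with a
  reproducibility header.

## CLI

```bash
quantpk --seed 1 --out-dir out simulate            # profiles + calibration batch
quantpk --out-dir out calibrate --standards out/standards.csv
quantpk --out-dir out validate --batch out/calibration_batch.csv [--strict]
quantpk --seed 1 --out-dir out nca --profiles out/profiles.csv
quantpk --seed 1 --out-dir out compare --profiles out/profiles.csv
quantpk --seed 1 --out-dir out report              # full pipeline in one shot
```

`--config path.yaml` points at a YAML file overriding any default (doses,
sampling schedule, noise, acceptance limits, DDI effect size, ...); unknown
keys are rejected. `--strict` makes `validate` exit nonzero when the battery
fails. `--debug` logs every computed quantity.

## Library example

```python
import quantpk as q

dataset = q.simulate_study(q.default_design(seed=1), q.default_base_params())
results = [q.run_nca(p) for p in dataset.profiles]
single = {a: [r for r in results if r.group in ("I", "II") and r.analyte == a]
          for a in ("DSV", "TAM", "TOH")}
combo = {a: [r for r in results if r.group == "III" and r.analyte == a]
         for a in ("DSV", "TAM", "TOH")}
print(q.format_table5(q.build_table5(single, combo)))
```
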