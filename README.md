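# bbbccs

Collision-cross-section (CCS) based evaluation of blood-brain-barrier (BBB)
permeation of drugs, as a tested, reusable pipeline:

- **compound_model** — typed compound records, CSV table I/O (standard and
  single-SMILES batch dialects), dataset summaries (counts, class ratio).
- **adducts** — charge-aware adduct selection ((M+H)+ for positive/neutral,
  (M−H)− for negative compounds) and adduct mass arithmetic.
- **mason_schamp** — low-field drift-tube conversion between arrival time
  and CCS in nitrogen, and its exact inverse.
- **sphere_geometry** — hard-sphere conversion of CCS into projected ion
  radii/areas (`r_i = sqrt(CCS/π) − r_B`), the momentum-transfer correction
  (CCS/1.4), endpoint spread propagation, and pore-passage verdicts against
  the built-in 10 Å membrane-kink and 8–10 Å claudin pore models.
- **bbb_classifier** — the threshold decision rules: BBB+ iff CCS < 200 Å²
  (strict boundary) and the combined rule XlogP3 > −1 OR CCS < 200 Å²;
  custom rules via a small YAML schema.
- **evaluation** — confusion/accuracy/class-error reports, Z-score
  normalization, random-forest descriptor importance (mean decrease
  accuracy via out-of-bag permutation), stepwise 8→6→4 descriptor
  reduction, stratified split and k-fold cross-validation.
- **synthetic_data** — simulated two-class compound libraries with
  group-specific Gaussian descriptor laws (BBB+ CCS ~ N(174, 25) Å²),
  a CCS–MW rank correlation via a Gaussian copula, presets matching the
  four published library count pairs, and closed-form accuracy oracles.
- **pipeline / cli** — end-to-end workflow with a reproducibility manifest.

## CLI

```sh
bbbccs simulate --preset adenot --seed 1 --out library.csv
bbbccs classify --input library.csv --rule ccs200 --out predictions.csv
bbbccs evaluate --input library.csv --rule ccs-xlogp3 --cross-validate
bbbccs importance --input library.csv --trees 1000 --seed 123456
bbbccs geometry --ccs 174
bbbccs ccs-from-drift --arrival-time 20 --field 15 --length 78 \
    --pressure 4 --temperature 300 --ion-mass 300
bbbccs run --preset adenot --seed 1 --outdir run/
```

`bbbccs run` writes `predictions.csv`, `classification_report.json`,
`importance.csv`, `geometry.csv` and `manifest.json`; reruns with the same
config and seed reproduce the artifacts byte-for-byte.

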