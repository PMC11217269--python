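# icealgae

Single-cell FTIR biomolecular profiling of sea-ice algae, as a tested,
reproducible pipeline:

- **`icealgae.synthetic`** — synthetic point spectra (Gaussian band mixtures
  over a polynomial baseline with seeded noise), cohort designs with known
  group effects and ground-truth tables, and plausible ice-core/water
  records. Everything downstream is testable without any instrument data.
- **`icealgae.spectra`** — `Spectrum` data model, wide-CSV I/O with a
  metadata sidecar, and the preprocessing chain: Savitzky–Golay smoothing +
  second derivative (9-point window, cubic polynomial, single pass) followed
  by Standard Normal Variate normalisation over the analysis ranges
  (3050–2800 and 1770–1000 cm⁻¹). Stage tags enforce the order.
- **`icealgae.bands`** — nine-band IR registry (unsaturated/saturated lipid
  CH stretches, ester carbonyl, amide II, carboxylate, phosphodiester,
  carbohydrate, silica), rectified trapezoidal band-area integration on
  second-derivative spectra, per-cell aggregation, Shapiro–Wilk normality
  checks with log₁₀ fallback, and the SAFA:USFA ratio.
- **`icealgae.environment`** — brine salinity `Sb = 1000/(1 − 54.11/T)` and
  brine volume fraction (density-ratio form; Cox–Weeks variant behind a
  switch), albedo, molar N:Si / Si:P ratios with amended-Redfield
  (106C:16N:15Si:1P) limitation flags, detection-limit handling, seasonal
  summaries, and the packaged site × date ice-core table.
- **`icealgae.fatty_acids`** — "C:D n-x" nomenclature parser,
  SAFA/MUFA/PUFA classification by double-bond count, class and omega-series
  sums (EPA+DHA, dominant-four), and the packaged community FA table.
- **`icealgae.mvstats`** — self-implemented Bray–Curtis dissimilarity,
  Clarke's ANOSIM (exhaustive enumeration when ≤ 10,000 relabellings,
  seeded sampling otherwise), PCA by SVD, RDA with a Monte-Carlo
  permutation pseudo-F test and forward model selection, and univariate OLS
  with F = (R²/(1−R²))·(n−2).
- **`icealgae.pipeline` / `icealgae.cli`** — staged orchestration
  (read → preprocess → quantify → stats) from a YAML config, with seeds and
  a config hash stamped into every output CSV.

## CLI

```sh
icealgae simulate --out sim/ --seed 1 --n-cells 26          # synthetic cohort
icealgae preprocess --spectra sim/spectra.csv --out proc.csv
icealgae quantify --spectra sim/spectra.csv --out profiles.csv
icealgae stats --profiles profiles.csv --out-dir stats/
icealgae run --config config.yaml                           # full pipeline
icealgae reproduce-paper                                    # numeric targets
```

A minimal `config.yaml`:

```yaml
spectra_path: sim/spectra.csv
output_dir: out
seed: 1
n_permutations: 999
```

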