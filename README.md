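# psireg

Quantifying stem water potential regulation in trees from optical-dendrometer
time series: the pipeline turns raw branchlet-width and microclimate records
into steady-state daily-maximum soil-to-stem water potential gradients
(ΔΨ), fits a hierarchical Bayesian changepoint model of ΔΨ as a joint
function of vapour pressure deficit (VPD) and soil water potential, and
translates the fitted surface into a normalized whole-plant diffusive
conductance prediction.

## Model

The daily-maximum gradient follows a saturating curve in VPD,

    ΔΨ = θ(Ψ_soil) · (1 − exp(−λ(Ψ_soil) · VPD)) + ε,   ε ~ N(0, σ²),

whose asymptote θ and curvature rate λ are constant (θ₀, λ₀) while the
soil is wetter than a changepoint Ψ_threshold and change exponentially
(rates α, β) below it.  θ₀ and λ₀ carry correlated log-scale random
effects per plant-year.  The posterior is sampled with a self-contained
No-U-Turn sampler (analytic gradients, dual-averaging step size, windowed
diagonal mass matrix); diagnostics include rank-normalized split R-hat,
PSIS-LOO, LOO and Bayesian R², and posterior-predictive coverage (via
arviz).  Whole-plant conductance is predicted as g_c ∝ ΔΨ/VPD under
constant soil-to-leaf hydraulic conductance and normalized to its maximum.

## Layout

- `psireg.microclimate` — Buck (1981) VPD, per-plant width→Ψ_stem calibration
- `psireg.extraction` — steady-state daily minima, predawn humid-night soil
  anchors, soil-potential interpolation, daily-record assembly
- `psireg.model` — the changepoint mean surface and Gaussian likelihood
- `psireg.inference` — NUTS fit, convergence and predictive diagnostics
- `psireg.conductance` — normalized conductance surface
- `psireg.simulate` — synthetic studies (daily records or raw 15/30-min
  signals) with known parameters for end-to-end verification
- `psireg.cli` — the `psireg` command

## CLI

```sh
# synthetic study → full pipeline (ingest → extract → fit → diagnose → g_c)
psireg run --study study/ --out out/ --seed 1 --simulate

# or stage by stage
psireg simulate --seed 1 --out study/
psireg ingest  --study study/ --out out/ingest
psireg extract --inputs out/ingest --out out/extract
psireg fit     --records out/extract/records.csv --seed 1 --out out/posterior
psireg diagnose --posterior out/posterior
psireg predict-gc --posterior out/posterior --vpd 0.05:4:0.05 --psi 0:-4:0.05 --out gc.csv
```

A study directory holds `climate.csv` (`timestamp,temp_c,rh_pct`),
`widths.csv` (`timestamp,plant_id,width_um`) and `calibration.csv`
(`plant_id,timestamp,psi_bomb_mpa,width_um`).  Every threshold of the
protocol (0.05 kPa night-VPD rule, 5% steady-state tolerance, 2-h
averaging window, 11:00–15:00 diurnal window, site coordinates, sampler
settings) is a YAML config key with the protocol value as default; pass
`--config config.yaml` with sections `site:`, `extraction:`, `fit:`,
`simulate:`.

The `fit` stage exits non-zero when any population-parameter R-hat exceeds
the configured limit (default 1.01); diagnostics are still written.

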