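# nirferm

Synthetic near-infrared (NIR) bioprocess monitoring: simulate lactic
fermentations and their NIR spectra, build and validate multivariate
calibrations (MLR on a 19-filter on-line analyzer, NIPALS PLS on an in-line
immersion probe), transfer calibrations across organisms, and run
closed-loop fermentation strategies in which the controller observes only
NIR-predicted concentrations.

## Layout

| module | contents |
|---|---|
| `nirferm.simulate` | Monod / Luedeking-Piret batch & open-loop fermentation kinetics, noisy reference assays, trajectory-based calibration designs |
| `nirferm.spectra` | instrument models (19-filter wheel, full-spectrum, 1800 nm-capped probe), Gaussian pure-component bands, bubble/scatter baselines, 4 AU saturation |
| `nirferm.chemometrics` | Norris gap-segment second derivative, PCA/Mahalanobis screening, MLR, NIPALS PLS1, leave-one-out PRESS selection, SEC/SECV/SEP/RMSEP statistics, paired NIR-vs-lab test |
| `nirferm.pipeline` | study orchestration: build / externally validate / transfer calibrations, mean-spectrum discrimination |
| `nirferm.control` | closed-loop strategies: repeated batch, repeated fed-batch, turbidostat, chemostat, microfiltration RBC; steady-state detection |
| `nirferm.io_files`, `nirferm.cli` | CSV/JSON/YAML formats, run manifests, `nirferm` command-line tool |

## CLI

Every command takes `--config <yaml>`, `--seed` (overrides the config) and
`--out`, and writes a `<out>.manifest.json` audit record.

```sh
cat > study.yaml <<EOF
study: heterolactic   # or: homolactic
seed: 1
EOF

nirferm simulate     --config study.yaml --out traj.csv
nirferm spectra      --config study.yaml --trajectory traj.csv --out spectra.csv
nirferm calibrate    --config study.yaml --analyte glucose --out model.json
nirferm validate     --config study.yaml --model model.json --out stats.json
nirferm transfer     --config study.yaml --model model.json --target hetero_rod --out transfer.json
nirferm discriminate --config study.yaml --target hetero_rod --out verdict.txt
nirferm control      --config study.yaml --strategy chemostat --setpoint 35 --out loop.csv
nirferm report       --config study.yaml --out report.txt
```

Config documents may instead assemble a study from parts
(`organism`, `instrument`, `method`, `n_calibration`, `noise: {...}`,
`hydro: {...}`, `pretreatment: {...}`, `kinetics: {...}` overrides).

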