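# neurotracer

Analysis toolkit for dual-tracer ¹³C brain-metabolism studies, plus
hippocampal fEPSP/LTP electrophysiology. It covers the full path from
NMR-style peak areas to group-level biology:

- **`neurotracer.core`** — data model (label patterns like `[4,5-13C]Glu`),
  validated CSV/TSV readers and writers for isotopomer, total-pool,
  calibration, and peak tables.
- **`neurotracer.labelsim`** — a discrete-turn, two-compartment
  (neuron/astrocyte) ¹³C label-propagation simulator for
  [1-¹³C]glucose + [1,2-¹³C]acetate co-infusion, with succinate-stage
  scrambling, glutamate→GABA and glutamate↔glutamine transfer, group flux
  scaling, log-normal replicate noise, and synthetic peak/calibration
  generation.
- **`neurotracer.quantify`** — standard-curve fitting (peak area vs known
  ¹³C concentration), internal-standard normalization, area→concentration
  inversion, and fractional enrichment against HPLC totals.
- **`neurotracer.metrics`** — glucose/acetate cycling ratios,
  acetate-vs-glucose utilization indices, glycolytic index, percent change,
  two-tailed t-tests (Student/Welch, raw or summary statistics), SUV and
  pAKT/AKT helpers, and Table-style group-comparison reports.
- **`neurotracer.ephys`** — fEPSP slope extraction (two cursors 1 ms apart
  on the ascending phase), I/O curves (100–350 μA grid), baseline
  normalization, final-window LTP values, and a synthetic TBS recording
  generator.
- **`neurotracer.datasets`** — the bundled published reference dataset
  (group mean ± dispersion isotopomer concentrations and HPLC totals,
  n = 4 per group).

## CLI

```sh
neurotracer simulate --seed 3 --out-prefix out/sim
neurotracer quantify --peaks peaks.csv --calibration cal.csv --out out/q
neurotracer analyze  --iso iso.csv --totals totals.csv \
                     --control CTL --treated KO --out out/a
neurotracer ltp      --recording rec.csv --tbs-time-s 600 --out out/ltp
neurotracer run      --config pipeline.yaml --out out/run
```

`run` executes simulate → peak synthesis → quantify → analyze → LTP from a
single YAML config (or ingests external `inputs.iso`/`inputs.totals`
tables) and writes a `manifest.json` with the seed, version, and input
hashes; reruns with the same config are byte-identical.

Example pipeline config:

```yaml
seed: 5
simulation: {n_replicates: 4, cv: 0.05, turns: 2}
analysis:   {control: CTL, treated: KO, t_flavor: student}
ltp:        {n_slices: 10, control_potentiation: 1.2, treated_potentiation: 1.6}
```

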