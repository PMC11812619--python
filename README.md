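# biovalor

Kinetics, statistics, and mass/energy-flow modelling for organic-waste
valorization lines that combine alkaline/thermal pretreatment, mesophilic
acidogenic fermentation, and anaerobic digestion, and for comparing such a
multistep line against single-step digestion.

The package covers four layers:

* **`biovalor.synthetic_data`** — seeded generators for batch methane-potential
  (BMP) bottle campaigns (duplicate bottles, inoculum-only blanks, sparse
  gas-chromatography day grids, Gaussian volume noise) and daily fermenter
  monitoring series.
* **`biovalor.bmp_kinetics`** — k-nearest-neighbour imputation of gas
  composition (inverse-distance weighting on the day axis), blank correction
  and replicate averaging, first-order and modified-Gompertz model fitting by
  multi-start nonlinear least squares, and batch indicators (SMP, SGP, biogas
  yield, maximum CH4 content).
* **`biovalor.fermentation_stats`** — fermentation performance indicators
  (COD solubilization, VFA yield on COD and acid-mass bases, ammonia/phosphate
  release, VFA/SCOD ratio), VFA weight-ratio spectra, stability summaries, and
  a paired two-tailed Student t-test.
* **`biovalor.flowsheet` / `biovalor.energy_economics`** — a steady-state
  mass-balance model of the two scenarios with per-unit conservation checks,
  plus stream heating, reactor wall losses, CHP conversion, and an
  income/payback economics layer.

## Command line

```bash
biovalor synth bmp --seed 1 --out out/            # synthetic BMP campaign
biovalor synth fermenter --seed 1 --out out/      # fermenter monitoring CSV
biovalor bmp-fit --readings out/bmp_readings.csv --bottles out/bmp_bottles.csv --out out/fits
biovalor fermenter-stats --input out/fermenter_series.csv --hrt 4.5 --out out/stats
biovalor scenario --scenario 1 --out out/s1       # mass + energy + economics
biovalor compare --out out/                       # two-scenario table
```

`--config file.yaml` on `scenario` deep-merges overrides onto the defaults in
`biovalor.flowsheet.default_config`; every printed reference parameter
(screw-press capture, feed TS fractions, reactor volumes, conversion yields,
prices) is an explicit key there. Each output directory gets a `meta.json`
recording the seed and a SHA-256 hash of the effective configuration.

## Conventions worth knowing

* Specific yields are Nm3/kg-VS (numerically L/g-VS); the Gompertz maximum
  rate is kept in mL/(g-VS·d) as conventionally reported.
* Aqueous streams use a 1000 kg/m3 density to link mass flows with HRT/OLR
  and g/L concentrations.
* Wall-loss geometry defaults to a vertical cylinder with height = diameter
  and a 20% buried fraction; absolute surplus-energy figures depend on this
  choice, scenario comparisons are directional.
* The paired t-test differences are `d = y - x`, so a larger first series
  gives a negative t statistic.
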