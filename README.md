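# metphase

Design and REML analysis of **multi-phase** (field + laboratory),
**multi-environment** (multi-trial) phenotype screening experiments, built
around a two-year barley straw sugar-release campaign layout:

* **designs** — spatial row-column field layouts with resolvable replicate
  blocks, and partially replicated (p-rep) 96-well plate designs that
  re-randomise field samples, duplicate 3–5 % of cultivars across plates,
  and keep standards in plate columns 11–12;
* **simulate** — phenotype tables drawn from the exact variance-component
  structure the analysis assumes (per-trial field/laboratory random terms,
  per-trial genetic variances with a cross-trial genetic correlation,
  technical-replicate residuals), with presets reproducing the published
  trial means and variance magnitudes;
* **mixed_model** — sparse REML for three nested model variants:
  `A` (trial means + cultivar effects only), `B` (adds all field and
  laboratory random terms per trial), `C` (adds a free cross-trial genetic
  covariance).  Produces EBLUPs, prediction error variance, generalized
  heritability `1 - a / (2 * genetic variance)` (with `a` the average
  pairwise PEV), likelihood-ratio tests, genetic correlation, and
  percent-of-total variance tables;
* **ranking** — top-k cultivar lists per trial, cross-trial and cross-model
  concordance, and weighted selection indices;
* **pipeline / cli** — an end-to-end driver (`design → simulate → fit →
  rank`) with CSV/JSON artifacts and a manifest of seeds and checksums.

The REML engine solves the mixed-model equations with a block-absorption
(Schur complement) factorisation: sample-level terms form tiny independent
clusters that are eliminated analytically, the dense remainder is
Cholesky-factorised, and the selected inverse supplies **exact analytic
gradients**, making repeated fits fast enough for simulation studies.  A
sparse-LU fallback handles large systems, and a dense direct-formula
oracle verifies both backends in the test suite.

## CLI

```bash
metphase write-config --preset reduced -o config.yaml
metphase design-field --cultivars cultivars.txt --blocks 5 --rows 8 --seed 1 -o field.csv
metphase design-lab --field field.csv --dup-frac 0.03 --plates-per-day 4 --seed 2 -o lab.csv
metphase simulate --config config.yaml -o phenotypes.csv
metphase fit --model C --data phenotypes.csv --config config.yaml -o fitC
metphase rank --fit fitC_eblups.csv --k 40 -o ranking.csv
metphase run --preset reduced --seed 1 --out-dir runs/demo
```

`design-field` and `design-lab` are also installed as standalone console
scripts.

## Layout

```
src/metphase/
  designs.py       field + laboratory design generators, confounding checks
  simulate.py      phenotype simulation, missingness injection
  presets.py       published layout counts, variance components, trial means
  mixed_model/     spec, incidence matrices, REML engine, fitting, summaries
  ranking.py       top-k, overlap, selection index, concordance
  recovery.py      simulation-based validation harnesses
  io.py            CSV schemas, fit serialisation
  config.py        pipeline configuration (YAML)
  pipeline.py      end-to-end driver
  cli.py           click-based CLI
tests/             pytest suite; test_acceptance.py holds the acceptance criteria
scripts/acceptance.py   acceptance report generator
```
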