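# rdnaclock

An epigenetic age-clock toolkit for targeted bisulphite amplicon data on
ribosomal DNA, built around the workflow used to age European lobsters from
CpG methylation:

1. **simdata** — a synthetic-data generator (CpG panels with linear
   methylation–age trajectories, negative-binomial read coverage, binomial
   methylation calls with bisulphite non-conversion error, batch/sex
   offsets, von Bertalanffy body sizes) so the whole pipeline is testable
   offline.
2. **methylation** — percent-methylation calling from Bismark-style
   coverage files, locus QC (minimum coverage in every individual, no
   missing data), matrix export.
3. **screen** — per-locus OLS regression of percent methylation on age,
   Holm step-down multiple-testing correction, saturation-age
   extrapolation.
4. **clock** — ridge / elastic-net / lasso age models on a 100-value
   log-spaced λ grid (10⁻³–10³) with 10-fold tuning on median MAE, fully
   nested leave-one-out validation, model comparison, a reduced
   top-k-locus OLS model, and cohort/sex diagnostics.
5. **growth** — von Bertalanffy growth models in the standard and Francis
   parameterisations with exact conversion between them and nonparametric
   bootstrap confidence intervals.
6. **workflow** — an orchestrated, seeded, reproducible run producing a
   markdown + CSV/JSON report bundle.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end property checks (exact QC
rules, Holm oracle agreement, OLS exactness, elastic-net sanity, nested
LOOCV protocol verification, a study-scale parameter-recovery experiment,
sex-effect null calibration, VBGM recovery/bootstrap coverage, and
byte-level run determinism).

## CLI

```sh
# full pipeline from a YAML config
rdnaclock run --config run.yaml

# or stage by stage
rdnaclock simulate --config sim.yaml --out data/ --seed 1
rdnaclock quantify --counts data/ --samples data/samples.csv --min-reads 10 --out matrix.csv
rdnaclock screen   --matrix matrix.csv --samples data/samples.csv --out screen.csv
rdnaclock train    --matrix matrix.csv --samples data/samples.csv --alpha 0.5 --seed 1 --out model.json
rdnaclock validate --matrix matrix.csv --samples data/samples.csv --seed 1 --out loocv.csv
rdnaclock predict  --model model.json --matrix wild.csv --out predictions.csv
rdnaclock growth   --data sizes.csv --form francis --boot 1000 --seed 1 --out growth.json
```

Example `run.yaml`:

```yaml
out_dir: results/run1
seed: 1
min_reads: 10
alpha: 0.5
folds: 10
k_reduced: 15
n_boot: 1000
growth_form: standard
sim:            # omit and set counts_dir/samples_csv to use real data
  n_loci: 355
  frac_informative: 0.60
stages:         # all stages on by default
  reduced: true
```

Exit codes: 0 success, 2 configuration error, 3 stage failure.

### Data formats

- Per-sample coverage files (`<sample_id>.cov`): tab-separated
  `chromosome start end percent_methylation count_methylated count_unmethylated`,
  1-based inclusive coordinates, rDNA region name (18S/ITS1/ITS2/28S) as
  the chromosome.
- `samples.csv`: `sample_id, age_months (empty for unknown-age samples),
  tissue, sex, cohort, batch, carapace_length_mm`.
- Methylation matrix CSV: samples as rows, `region_position` column headers.
- Models serialize to JSON and reproduce predictions exactly when reloaded.

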