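# qsarpipe

A tested, reusable pipeline for QSAR model building and validation on
descriptor/activity tables (the CSV dialect produced by descriptor
calculators such as PaDEL):

- **Kennard–Stone** maximin division into training and test partitions,
  plus spreadsheet-convention descriptive statistics per partition.
- **Pretreatment**: low-variance filtering, deterministic greedy
  de-redundancy on pairwise |r|, and min/max normalization (two variants:
  the conventional [0,1] map and the (X−Xmax)/(Xmax−Xmin) map into [−1,0];
  they are affinely equivalent and all downstream statistics are
  identical).
- **GFA-MLR**: a genetic search over descriptor subsets fitted by ordinary
  least squares and scored by the Friedman lack-of-fit
  `(SSE/M) / (1 − (c + d·p)/M)²`, with rank selection, one-point
  crossover, swap/grow/shrink mutation, elitism, and a 1:5
  term-to-sample guard.
- **Validation battery**: R², adjusted R², SEE, F, leave-one-out Q²
  (explicit refits), external-set R² (standard and literal variants),
  Y-randomization with cRp² = R·sqrt(R² − Rr²), standardized coefficient
  contributions, Pearson matrix, VIF, per-coefficient t/p inference, and
  a pass/fail model-quality checklist.
- **Applicability domain**: hat-matrix leverages, warning leverage
  h* = 3(p+1)/n (or 3p/n), standardized residuals, per-compound
  in/out-of-domain flags, and an optional Williams plot.
- **Synthetic data**: a generator with correlated descriptor blocks,
  near-constant columns, and a sparse linear ground truth, so every stage
  is testable end to end without any external dataset.

## CLI

Each stage is a subcommand; `run` wires them together:

```bash
qsarpipe simulate --n-compounds 50 --n-descriptors 300 --seed 1 --out data.csv
qsarpipe pretreat data.csv --variance-tol 1e-6 --r-threshold 0.95 --out clean.csv
qsarpipe split clean.csv --n-train 36 --out split.json
qsarpipe train train.csv --pop 100 --gens 500 --max-terms 6 --seed 1
qsarpipe validate --model model.json --train train.csv --test test.csv --yrand 10 --seed 1
qsarpipe domain --model model.json --train train.csv --test test.csv --plot williams.png
qsarpipe run --config config.yaml --seed 1 --out-dir results/
```

`run` accepts a YAML config (see `qsarpipe.pipeline.RunConfig` for every
key), derives a deterministic sub-seed per stochastic stage from the
global seed, and writes per-stage artifacts plus a combined
`report.json`/`report.md`. Identical config + seed gives byte-identical
output.

Library use mirrors the CLI:

```python
import qsarpipe as qp

dataset, truth = qp.generate_dataset(qp.SyntheticSpec(seed=1))
dataset, _ = qp.remove_low_variance(dataset, 1e-6)
dataset, _ = qp.correlation_filter(dataset, 0.95)
split = qp.kennard_stone_split(dataset, n_train=36)
train, test = dataset.subset(split.train_ids), dataset.subset(split.test_ids)
models = qp.gfa_search(train, qp.GFAConfig(seed=1, max_terms=6))
report = qp.validate_model(models[0][0], train, test)
ad = qp.williams_table(models[0][0], train, test)
```

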