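# catsplitrf

Random forests with interchangeable splitting strategies for **nominal
(unordered categorical) predictors** — for biostatisticians and machine
learning practitioners who work with variables like genotypes, geographical
regions, medication types or cell types and want to know how the choice of
categorical-split algorithm affects prediction.

A binary tree must assign each of a nominal predictor's `k` categories to
one of two child nodes.  The classical exhaustive search scans all
`S(k, 2) = 2^(k-1) - 1` two-partitions; this package implements that search
and four alternatives behind a single switch:

| method        | idea                                              | candidates per split |
|---------------|---------------------------------------------------|----------------------|
| `partition`   | try every 2-partition of the present categories   | `2^(m-1) - 1`        |
| `order_split` | order categories in each node, then threshold     | `m - 1`              |
| `order_once`  | order categories once on the full training data   | `k - 1`              |
| `dummy`       | expand into `k - 1` binary indicators             | 1 per indicator      |
| `ignore`      | treat codes as ordinal in label order             | `k - 1`              |

Orderings are outcome-appropriate: within-category outcome mean for
regression and binary classification (where ordered splitting provably
attains the exhaustive optimum), the first principal component of the
weighted covariance of per-category class-probability vectors
(`S_a = v . p^a`) for multiclass, and per-category means of log-rank scores
`a_i = delta_i - sum_{j<=gamma_i} delta_j / (N - gamma_j + 1)` for censored
survival outcomes.  Split criteria are the Gini-impurity decrease, the
sum-of-squares decrease, and the two-sample log-rank statistic
`(O - E)^2 / V`; survival forests predict via ensemble Nelson-Aalen
cumulative hazards.  See `docs/methods.md` for the full model description.

The package also ships the simulation test bed (Digit, SNP, Group predictor
types under all four outcome types, with controllable censoring) and the
comparison protocol (paired replicates, `mtry` tuning by five-fold CV,
nested CV, paired and corrected-paired t-tests, integrated Brier score).

## Worked example

```python
from catsplitrf import ScenarioConfig, ForestConfig, simulate, fit
from catsplitrf.bench import score_forest

# Digit scenario: 4 nominal predictors (digits 0-9), 16-class parity pattern
data = simulate(ScenarioConfig(predictor_type="digit",
                               outcome_type="multiclass", n=100, seed=1))

for method in ("ignore", "order_once"):
    cfg = ForestConfig(n_trees=50, mtry=4, nominal_method=method, seed=3)
    forest = fit(data.train, data.schema, cfg)
    err = score_forest(forest, data.valid, data.schema)
    print(f"{method:12s} misclassification {err:.3f}")
```

prints

```
ignore       misclassification 0.860
order_once   misclassification 0.050
```

The parity signal (odd vs even digits) is invisible to threshold splits on
the raw digit codes — `ignore` misclassifies 86% of the validation data,
barely better than the 93.75% of random guessing among 16 classes — while
ordering the categories once by their principal-component scores makes the
same forest nearly perfect (5% error).

The same comparison from the shell:

```sh
catsplitrf bench --scenario digit --outcome multiclass --n 100 \
    --methods ignore,order_once --reps 20 --seed 7 --out results/
```

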