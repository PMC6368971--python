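"""The method-comparison protocol: tuning, simulation studies, nested CV, tests.

The experimental design compares the five nominal-predictor methods under a
paired protocol: every method sees byte-identical replicate datasets, the
``mtry`` value is tuned per replicate by five-fold cross validation, a
50-tree forest is refitted at the tuned value, and validation error is
measured by the outcome-appropriate metric (MSE / misclassification
proportion / integrated Brier score).  Methods are compared to the
exhaustive Partition method with a two-sided paired t-test (simulations) or
the variance-corrected paired t-test for repeated cross validation (real
datasets).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import forest as rf
from .data import TrainingData, from_dataframe
from .metrics import integrated_brier_score, misclassification_rate, mse
from .nominal import PartitionLimitError, SurvivalOutcome
from .scenarios import ScenarioConfig, ScenarioData, replicate_config, simulate

__all__ = [
    "EvalResult",
    "mtry_grid",
    "tune_mtry",
    "score_forest",
    "run_simulation_study",
    "run_nested_cv",
    "paired_t_test",
    "corrected_paired_t_test",
    "censoring_sweep",
    "tree_size_and_absent_levels_study",
]


@dataclass
class EvalResult:
    """Per-method evaluation outcome of one study."""

    scenario: str
    method: str
    errors: np.ndarray
    mtry: np.ndarray
    p_vs_partition: float | None = None
    repeat_means: np.ndarray | None = None

    @property
    def median(self) -> float:
        return float(np.nanmedian(self.errors))

    @property
    def iqr(self) -> float:
        q1, q3 = np.nanpercentile(self.errors, [25, 75])
        return float(q3 - q1)

    def summary(self) -> dict:
        return {"scenario": self.scenario, "method": self.method,
                "median": self.median, "iqr": self.iqr,
                "n_replicates": int(np.sum(~np.isnan(self.errors))),
                "p_vs_partition": self.p_vs_partition}


# ---------------------------------------------------------------------------
# mtry tuning
# ---------------------------------------------------------------------------


def mtry_grid(method: str, n_predictors: int, n_encoded: int) -> list[int]:
    """The tuning grid: all values 1..p, except Dummy which uses ten values
    evenly distributed between 1 and the number of encoded columns
    (rounded, deduplicated)."""
    if method == "dummy":
        vals = np.unique(np.round(np.linspace(1, n_encoded, 10)).astype(int))
        return [int(v) for v in vals if v >= 1]
    return list(range(1, n_predictors + 1))


def _outcome_columns(schema: dict[str, str]) -> dict[str, str]:
    return {role: col for col, role in schema.items() if role.startswith("outcome")}


def score_forest(forest: rf.Forest, df: pd.DataFrame, schema: dict[str, str]) -> float:
    """Outcome-appropriate prediction error of a fitted forest on ``df``."""
    cols = _outcome_columns(schema)
    if forest.outcome_type == "regression":
        return mse(df[cols["outcome_regression"]].to_numpy(), forest.predict(df))
    if forest.outcome_type == "classification":
        return misclassification_rate(df[cols["outcome_classification"]].to_numpy(),
                                      forest.predict(df))
    surv = SurvivalOutcome(time=df[cols["outcome_time"]].to_numpy(np.float64),
                           status=df[cols["outcome_status"]].to_numpy(np.int64))
    return integrated_brier_score(surv, forest.predict(df))


def _make_folds(train: TrainingData, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold label per observation; stratified by class for classification."""
    n = train.n
    fold = np.empty(n, dtype=np.int64)
    if train.outcome_type == "classification":
        for cls in range(train.n_classes):
            idx = np.flatnonzero(train.y == cls)
            idx = rng.permutation(idx)
            fold[idx] = np.arange(idx.size) % n_folds
    else:
        fold[:] = np.arange(n) % n_folds
        fold = fold[rng.permutation(n)]
    return fold


def tune_mtry(df: pd.DataFrame, schema: dict[str, str], config: rf.ForestConfig,
              grid: list[int], rng: np.random.Generator, n_folds: int = 5) -> int:
    """Pick the grid value minimizing mean CV error; ties go to the smallest.

    Folds are drawn once (seeded, stratified by class for classification) and
    shared across grid values.  Grid values exceeding the number of encoded
    predictor columns are dropped with a warning.
    """
    if not grid:
        raise ValueError("empty mtry grid")
    train = from_dataframe(df, schema)
    n_encoded = len(rf._build_design(train, config).columns)
    usable = [g for g in sorted(set(grid)) if g <= n_encoded]
    dropped = sorted(set(grid) - set(usable))
    if dropped:
        warnings.warn(f"mtry values {dropped} exceed the {n_encoded} encoded "
                      f"columns and were dropped")
    if not usable:
        raise ValueError("no usable mtry value in grid")
    if len(usable) == 1:
        return usable[0]
    fold = _make_folds(train, n_folds, rng)
    fit_seed = int(rng.integers(0, 2**31 - 1))
    best, best_err = usable[0], np.inf
    for m in usable:
        errs = []
        for f in range(n_folds):
            tr = df.iloc[np.flatnonzero(fold != f)].reset_index(drop=True)
            te = df.iloc[np.flatnonzero(fold == f)].reset_index(drop=True)
            cfg = replace(config, mtry=m, seed=fit_seed + f)
            fitted = rf.fit(tr, schema, cfg)
            errs.append(score_forest(fitted, te, schema))
        mean_err = float(np.mean(errs))
        if mean_err < best_err:
            best, best_err = m, mean_err
    return best


# ---------------------------------------------------------------------------
# Statistical comparisons
# ---------------------------------------------------------------------------


def paired_t_test(errors_a: np.ndarray, errors_b: np.ndarray) -> float:
    """Two-sided paired t-test p-value over per-replicate error differences.

    Degenerate cases are resolved by convention: identical vectors give
    p = 1; a constant nonzero difference (zero variance, infinite t)
    gives p = 0.
    """
    a = np.asarray(errors_a, dtype=np.float64)
    b = np.asarray(errors_b, dtype=np.float64)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValueError("paired t-test needs at least two pairs")
    d = a - b
    if np.all(d == 0):
        return 1.0
    if np.var(d, ddof=1) == 0:
        return 0.0
    return float(sps.ttest_rel(a, b).pvalue)


def corrected_paired_t_test(errors_a: np.ndarray, errors_b: np.ndarray,
                            n_train: int, n_test: int) -> float:
    """Corrected resampled paired t-test for repeated cross validation.

    The naive paired t-test is anti-conservative on CV estimates because the
    J resampling estimates overlap; the corrected test inflates the variance
    term to ``(1/J + n_test/n_train) * var(d)`` before standardizing
    (Nadeau-Bengio correction), with J - 1 degrees of freedom.
    """
    a = np.asarray(errors_a, dtype=np.float64)
    b = np.asarray(errors_b, dtype=np.float64)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    J = a.size
    if J < 2:
        raise ValueError("corrected t-test needs at least two estimates")
    if n_train <= 0 or n_test < 0:
        raise ValueError("invalid train/test sizes")
    d = a - b
    if np.all(d == 0):
        return 1.0
    v = np.var(d, ddof=1)
    if v == 0:
        return 0.0
    t = d.mean() / np.sqrt((1.0 / J + n_test / n_train) * v)
    return float(2 * sps.t.sf(abs(t), df=J - 1))


# ---------------------------------------------------------------------------
# Simulation studies
# ---------------------------------------------------------------------------


def _replicate_seeds(seed: int, n: int) -> np.ndarray:
    return (np.random.SeedSequence(seed).generate_state(2 * n)[:n] & 0x7FFFFFFF).astype(np.int64)


def run_simulation_study(
    scenario: ScenarioConfig,
    methods: tuple[str, ...] = rf.NOMINAL_METHODS,
    n_replicates: int = 20,
    seed: int = 0,
    n_trees: int = 50,
    tune: bool = True,
    fixed_mtry: int = 2,
    base_config: rf.ForestConfig | None = None,
) -> dict[str, EvalResult]:
    """The simulation protocol: paired replicates, per-replicate tuning.

    For each replicate, ``n`` training and ``n`` validation observations are
    simulated; every method sees the same replicate (paired design).  With
    ``tune=True`` the ``mtry`` value is tuned per replicate and method by
    five-fold CV; otherwise ``fixed_mtry`` is used throughout (a desk-scale
    shortcut for qualitative checks).  Forest seeds are shared across
    methods, so split-equivalent methods yield identical error vectors.
    Partition-limit errors are recorded as missing (NaN) for that method.
    """
    rep_seeds = _replicate_seeds(seed, n_replicates)
    errors = {m: np.full(n_replicates, np.nan) for m in methods}
    mtries = {m: np.zeros(n_replicates, dtype=np.int64) for m in methods}
    base = base_config or rf.ForestConfig()
    scen_name = f"{scenario.predictor_type}/{scenario.outcome_type}/n={scenario.n}"
    for r in range(n_replicates):
        data = simulate(replicate_config(scenario, int(rep_seeds[r])))
        tune_rng_seed, fit_seed = [int(s) for s in
                                   np.random.SeedSequence(int(rep_seeds[r])).generate_state(2) >> 1]
        for method in methods:
            cfg = replace(base, n_trees=n_trees, nominal_method=method, seed=fit_seed)
            try:
                if tune:
                    train = from_dataframe(data.train, data.schema)
                    n_encoded = len(rf._build_design(train, cfg).columns)
                    grid = mtry_grid(method, scenario.p, n_encoded)
                    m = tune_mtry(data.train, data.schema, cfg, grid,
                                  np.random.default_rng(tune_rng_seed))
                else:
                    m = min(fixed_mtry, scenario.p)
                cfg = replace(cfg, mtry=m)
                fitted = rf.fit(data.train, data.schema, cfg)
                errors[method][r] = score_forest(fitted, data.valid, data.schema)
                mtries[method][r] = m
            except PartitionLimitError:
                errors[method][r] = np.nan
    results = {}
    for method in methods:
        p = None
        if "partition" in methods and method != "partition":
            try:
                p = paired_t_test(errors[method], errors["partition"])
            except ValueError:
                p = None
        results[method] = EvalResult(scenario=scen_name, method=method,
                                     errors=errors[method], mtry=mtries[method],
                                     p_vs_partition=p)
    return results


def run_nested_cv(
    df: pd.DataFrame,
    schema: dict[str, str],
    methods: tuple[str, ...] = rf.NOMINAL_METHODS,
    outer_folds: int = 10,
    inner_folds: int = 5,
    repeats: int = 1,
    seed: int = 0,
    n_trees: int = 50,
    base_config: rf.ForestConfig | None = None,
) -> dict[str, EvalResult]:
    """Nested cross validation: inner CV tunes mtry, outer folds score.

    Fold assignments are drawn per repeat and shared across methods.  The
    per-repeat mean errors (``repeat_means``) feed the corrected paired
    t-test; p-values reported here use that test with
    ``n_test/n_train = 1/(outer_folds - 1)``.
    """
    base = base_config or rf.ForestConfig()
    train_all = from_dataframe(df, schema)
    n = train_all.n
    p = train_all.p
    fold_errors = {m: [] for m in methods}
    fold_mtry = {m: [] for m in methods}
    repeat_means = {m: [] for m in methods}
    master = np.random.SeedSequence(seed)
    for rep_ss in master.spawn(repeats):
        rng = np.random.default_rng(rep_ss)
        fold = _make_folds(train_all, outer_folds, rng)
        rep_errs = {m: [] for m in methods}
        for f in range(outer_folds):
            tr = df.iloc[np.flatnonzero(fold != f)].reset_index(drop=True)
            te = df.iloc[np.flatnonzero(fold == f)].reset_index(drop=True)
            inner_seed, fit_seed = [int(s) for s in rng.integers(0, 2**31 - 1, 2)]
            for method in methods:
                cfg = replace(base, n_trees=n_trees, nominal_method=method, seed=fit_seed)
                try:
                    tr_data = from_dataframe(tr, schema)
                    n_encoded = len(rf._build_design(tr_data, cfg).columns)
                    grid = mtry_grid(method, p, n_encoded)
                    m = tune_mtry(tr, schema, cfg, grid,
                                  np.random.default_rng(inner_seed), n_folds=inner_folds)
                    fitted = rf.fit(tr, schema, replace(cfg, mtry=m))
                    err = score_forest(fitted, te, schema)
                except PartitionLimitError:
                    err, m = np.nan, 0
                fold_errors[method].append(err)
                fold_mtry[method].append(m)
                rep_errs[method].append(err)
        for method in methods:
            repeat_means[method].append(float(np.nanmean(rep_errs[method])))
    results = {}
    for method in methods:
        pval = None
        if "partition" in methods and method != "partition":
            try:
                pval = corrected_paired_t_test(
                    np.asarray(repeat_means[method]),
                    np.asarray(repeat_means["partition"]),
                    n_train=n * (outer_folds - 1) // outer_folds,
                    n_test=n // outer_folds,
                )
            except ValueError:
                pval = None
        results[method] = EvalResult(
            scenario="nested_cv", method=method,
            errors=np.asarray(fold_errors[method]),
            mtry=np.asarray(fold_mtry[method]),
            p_vs_partition=pval,
            repeat_means=np.asarray(repeat_means[method]),
        )
    return results


# ---------------------------------------------------------------------------
# Follow-up studies
# ---------------------------------------------------------------------------


def censoring_sweep(
    scenario: ScenarioConfig,
    methods: tuple[str, ...] = ("order_once",),
    fractions: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0, 0.1), 1)),
    n_replicates: int = 20,
    seed: int = 0,
    tune: bool = True,
    **study_kwargs,
) -> pd.DataFrame:
    """Rerun the survival study at each censoring fraction.

    Returns a tidy frame (fraction, method, replicate, error).  Replicate
    seeds are shared across fractions, and censoring uses a spawned RNG
    stream, so the underlying event times are identical across fractions:
    each row differs only in how much of the training data is censored.
    """
    if scenario.outcome_type != "survival":
        raise ValueError("censoring sweep requires a survival scenario")
    rows = []
    for frac in fractions:
        cfg = replace(scenario, censor_fraction=float(frac))
        res = run_simulation_study(cfg, methods=methods, n_replicates=n_replicates,
                                   seed=seed, tune=tune, **study_kwargs)
        for method, r in res.items():
            for i, e in enumerate(r.errors):
                rows.append({"fraction": float(frac), "method": method,
                             "replicate": i, "error": e})
    return pd.DataFrame(rows)


def tree_size_and_absent_levels_study(
    scenario: ScenarioConfig,
    methods: tuple[str, ...] = ("ignore", "order_once"),
    n_trees: int = 50,
    n_trees_availability: int = 500,
    mtry: int | None = None,
    seed: int = 0,
) -> dict:
    """Tree sizes under Ignore vs Order(once), and category availability.

    Fits one forest per method and records the per-tree node counts, then
    fits a larger forest to average, per tree depth, the number of distinct
    categories of the first nominal predictor still present in each node —
    the quantitative face of the absent-levels problem.
    """
    data = simulate(scenario)
    node_counts = {}
    for method in methods:
        cfg = rf.ForestConfig(n_trees=n_trees, mtry=mtry, nominal_method=method,
                              seed=seed)
        fitted = rf.fit(data.train, data.schema, cfg)
        node_counts[method] = rf.tree_node_counts(fitted)
    cfg = rf.ForestConfig(n_trees=n_trees_availability, mtry=mtry,
                          nominal_method=methods[0], seed=seed,
                          record_node_categories=True)
    fitted = rf.fit(data.train, data.schema, cfg)
    var = data.predictor_names[0]
    availability = rf.available_categories_by_depth(fitted, var)
    return {"node_counts": node_counts, "availability": availability,
            "variable": var}
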