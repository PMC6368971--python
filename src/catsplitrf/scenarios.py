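"""Simulation scenarios: Digit, SNP and Group predictors under four outcomes.

Each scenario draws ``n`` training and ``n`` validation observations with
``p`` nominal predictors and one of four outcomes (regression, binary,
multiclass, survival):

Digit
    Predictors are uniform digits 0-9.  The signal is parity: the linear
    predictor is (#odd - #even) across the p digits.  The multiclass label is
    the per-predictor parity pattern (2**p classes).
SNP
    Predictors are genotypes 0/1/2 drawn under Hardy-Weinberg equilibrium at
    a given minor allele frequency, with a purely heterozygous effect:
    each genotype equal to 1 adds ``effect`` to the linear predictor.
Group
    Predictors have ``k_group`` equally frequent categories whose effects
    differ between two latent observation groups; each (group, predictor,
    category) effect is drawn once per replicate from Uniform(1, 10), so no
    single category ordering fits both groups.

Survival outcomes are exponential with rate lambda taken from the scenario's
linear predictor; a fixed fraction of the *training* observations is censored
uniformly on (0, T).  Validation data is never censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .nominal import SurvivalOutcome

__all__ = ["ScenarioConfig", "ScenarioData", "simulate", "simulate_digit",
           "simulate_snp", "simulate_group", "simulate_survival_outcome"]

PredictorType = Literal["digit", "snp", "group"]
OutcomeType = Literal["regression", "binary", "multiclass", "survival"]


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one simulation scenario.

    Defaults are the study conditions: p=4 predictors, minor allele frequency
    0.25 with heterozygous effect size 3 (SNP), 10 equally frequent
    categories with Uniform(1,10) group effects (Group), 30% training
    censoring for survival.
    """

    predictor_type: PredictorType = "digit"
    outcome_type: OutcomeType = "regression"
    n: int = 100
    p: int = 4
    maf: float = 0.25
    effect: float = 3.0
    k_group: int = 10
    censor_fraction: float = 0.3
    noise_sd: float = 1.0       # additive noise of the SNP regression outcome
    integer_effects: bool = False  # Group: draw integer effect sizes 1..10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if not 0 < self.maf < 0.5:
            raise ValueError("maf must be in (0, 0.5)")
        if not 0 <= self.censor_fraction < 1:
            raise ValueError("censor_fraction must be in [0, 1)")


@dataclass(frozen=True)
class ScenarioData:
    """A paired train/validation replicate plus its schema."""

    train: pd.DataFrame
    valid: pd.DataFrame
    schema: dict[str, str]
    config: ScenarioConfig = field(repr=False)

    @property
    def predictor_names(self) -> list[str]:
        return [c for c, r in self.schema.items() if r == "nominal"]


def _schema(p: int, outcome_type: OutcomeType) -> dict[str, str]:
    schema = {f"x{j + 1}": "nominal" for j in range(p)}
    if outcome_type == "regression":
        schema["y"] = "outcome_regression"
    elif outcome_type in ("binary", "multiclass"):
        schema["y"] = "outcome_classification"
    else:
        schema["time"] = "outcome_time"
        schema["status"] = "outcome_status"
    return schema


def _pattern_label(indicator: np.ndarray) -> np.ndarray:
    """Encode a 0/1 matrix row-wise as an integer label (per-predictor pattern)."""
    p = indicator.shape[1]
    weights = 2 ** np.arange(p)
    return indicator @ weights


def simulate_survival_outcome(
    eta: np.ndarray,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    training: bool,
) -> SurvivalOutcome:
    """Exponential survival times with rate from the linear predictor.

    When the linear predictor is positive everywhere (Group), the rate is
    lambda_i = eta_i directly.  Otherwise (Digit and SNP, where eta can be
    zero or negative) the rate is exp(z_i) with z the standardized linear
    predictor of the replicate — a strictly positive, monotone transform that
    preserves the ordering of risks.

    For training data, exactly ``round(censor_fraction * n)`` observations
    are chosen without replacement and censored at a uniform time on
    (0, T_i).  Validation data is returned uncensored.  Censoring draws come
    from a spawned RNG stream, so the underlying event times (and everything
    simulated afterwards) are identical across censoring fractions — the
    censoring sweep compares like with like.
    """
    eta = np.asarray(eta, dtype=np.float64)
    n = eta.size
    if eta.min() > 0:
        lam = eta
    else:
        sd = eta.std()
        lam = np.exp((eta - eta.mean()) / sd) if sd > 0 else np.ones(n)
    T = rng.exponential(1.0 / lam)
    status = np.ones(n, dtype=np.int64)
    time = T.copy()
    if training and cfg.censor_fraction > 0:
        crng = rng.spawn(1)[0]
        n_cens = int(round(cfg.censor_fraction * n))
        idx = crng.choice(n, size=n_cens, replace=False)
        time[idx] = crng.uniform(0.0, T[idx])
        status[idx] = 0
    return SurvivalOutcome(time=time, status=status)


def _assemble(
    X: np.ndarray,
    cfg: ScenarioConfig,
    outcome: dict[str, np.ndarray],
) -> pd.DataFrame:
    df = pd.DataFrame({f"x{j + 1}": X[:, j] for j in range(cfg.p)})
    for col, vals in outcome.items():
        df[col] = vals
    return df


def _digit_outcome(X: np.ndarray, cfg: ScenarioConfig, rng: np.random.Generator,
                   training: bool) -> dict[str, np.ndarray]:
    odd = X % 2  # 1 for odd digits
    eta = odd.sum(axis=1) - (1 - odd).sum(axis=1)  # #odd - #even
    if cfg.outcome_type == "regression":
        return {"y": eta.astype(np.float64)}
    if cfg.outcome_type == "binary":
        return {"y": (eta > 0).astype(np.int64)}
    if cfg.outcome_type == "multiclass":
        return {"y": _pattern_label(odd)}
    surv = simulate_survival_outcome(eta, cfg, rng, training)
    return {"time": surv.time, "status": surv.status}


def simulate_digit(cfg: ScenarioConfig) -> ScenarioData:
    """Digit scenario: uniform digits 0-9, parity-driven outcomes."""
    rng = np.random.default_rng(cfg.seed)
    frames = []
    for training in (True, False):
        X = rng.integers(0, 10, size=(cfg.n, cfg.p))
        frames.append(_assemble(X, cfg, _digit_outcome(X, cfg, rng, training)))
    return ScenarioData(frames[0], frames[1], _schema(cfg.p, cfg.outcome_type), cfg)


def _snp_outcome(X: np.ndarray, cfg: ScenarioConfig, rng: np.random.Generator,
                 training: bool) -> dict[str, np.ndarray]:
    het = (X == 1).astype(np.int64)  # heterozygous effect: exactly one minor allele
    eta = cfg.effect * het.sum(axis=1).astype(np.float64)
    if cfg.outcome_type == "regression":
        return {"y": eta + rng.normal(0.0, cfg.noise_sd, size=eta.size)}
    if cfg.outcome_type == "binary":
        # intercept centers the linear predictor at its expectation
        intercept = -cfg.effect * cfg.p * 2 * cfg.maf * (1 - cfg.maf)
        prob = 1.0 / (1.0 + np.exp(-(eta + intercept)))
        return {"y": (rng.uniform(size=eta.size) < prob).astype(np.int64)}
    if cfg.outcome_type == "multiclass":
        return {"y": _pattern_label(het)}
    surv = simulate_survival_outcome(eta, cfg, rng, training)
    return {"time": surv.time, "status": surv.status}


def simulate_snp(cfg: ScenarioConfig) -> ScenarioData:
    """SNP scenario: Hardy-Weinberg genotypes with a heterozygous effect."""
    rng = np.random.default_rng(cfg.seed)
    q = cfg.maf
    probs = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
    frames = []
    for training in (True, False):
        X = rng.choice(3, size=(cfg.n, cfg.p), p=probs)
        frames.append(_assemble(X, cfg, _snp_outcome(X, cfg, rng, training)))
    return ScenarioData(frames[0], frames[1], _schema(cfg.p, cfg.outcome_type), cfg)


def simulate_group(cfg: ScenarioConfig) -> ScenarioData:
    """Group scenario: category effects that differ between two latent groups.

    The effect table e[group, predictor, category] is drawn once per
    replicate and shared between training and validation data.  The binary
    outcome thresholds the linear predictor at the median over the pooled
    (train + validation) replicate, computed before splitting.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.integer_effects:
        effects = rng.integers(1, 11, size=(2, cfg.p, cfg.k_group)).astype(np.float64)
    else:
        effects = rng.uniform(1.0, 10.0, size=(2, cfg.p, cfg.k_group))
    X_all, g_all = [], []
    for _ in range(2):
        X_all.append(rng.integers(0, cfg.k_group, size=(cfg.n, cfg.p)))
        g_all.append(rng.integers(0, 2, size=cfg.n))
    cols = np.arange(cfg.p)
    eta_all = [effects[g[:, None], cols[None, :], X].sum(axis=1)
               for X, g in zip(X_all, g_all)]
    pooled_median = np.median(np.concatenate(eta_all))
    frames = []
    for part, (X, g, eta) in enumerate(zip(X_all, g_all, eta_all)):
        training = part == 0
        if cfg.outcome_type == "regression":
            outcome = {"y": eta}
        elif cfg.outcome_type == "binary":
            outcome = {"y": (eta > pooled_median).astype(np.int64)}
        elif cfg.outcome_type == "multiclass":
            high = (effects[g[:, None], cols[None, :], X] >= 5.0).astype(np.int64)
            outcome = {"y": _pattern_label(high)}
        else:
            surv = simulate_survival_outcome(eta, cfg, rng, training)
            outcome = {"time": surv.time, "status": surv.status}
        frames.append(_assemble(X, cfg, outcome))
    return ScenarioData(frames[0], frames[1], _schema(cfg.p, cfg.outcome_type), cfg)


_GENERATORS = {"digit": simulate_digit, "snp": simulate_snp, "group": simulate_group}


def simulate(cfg: ScenarioConfig) -> ScenarioData:
    """Simulate one paired train/validation replicate for ``cfg``."""
    return _GENERATORS[cfg.predictor_type](cfg)


def replicate_config(cfg: ScenarioConfig, seed: int) -> ScenarioConfig:
    """The same scenario with a different replicate seed."""
    return replace(cfg, seed=seed)
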