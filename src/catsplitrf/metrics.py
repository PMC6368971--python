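"""Prediction-error measures: MSE, misclassification rate, integrated Brier score.

The integrated Brier score (IBS) follows the inverse-probability-of-censoring
weighting (IPCW) scheme of Graf et al.: squared differences between the
predicted survival curve S_i(t) and the observed at-risk indicator are
weighted by the Kaplan-Meier estimate G of the censoring distribution on the
evaluation data, using the left-continuous value G(t-) at event times.  With
fully uncensored evaluation data all weights are one and the IBS reduces to
the unweighted time-averaged Brier score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nominal import SurvivalOutcome

__all__ = [
    "SurvivalCurvePrediction",
    "mse",
    "misclassification_rate",
    "kaplan_meier",
    "censoring_survival",
    "integrated_brier_score",
]


@dataclass(frozen=True)
class SurvivalCurvePrediction:
    """Predicted survival probabilities on a shared time grid.

    ``surv[i, j]`` is S_i(times[j]) = exp(-CHF_i(times[j])), right-continuous
    and nonincreasing in j.
    """

    times: np.ndarray
    surv: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.float64)
        surv = np.atleast_2d(np.asarray(self.surv, dtype=np.float64))
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "surv", surv)
        if surv.shape[1] != times.size:
            raise ValueError("survival matrix width must match the time grid")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def at(self, t: float) -> np.ndarray:
        """S_i(t) by right-continuous step interpolation (S = 1 before the grid)."""
        j = np.searchsorted(self.times, t, side="right") - 1
        if j < 0:
            return np.ones(self.surv.shape[0])
        return self.surv[:, j]


def mse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean squared error."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    return float(np.mean((y_true - y_pred) ** 2))


def misclassification_rate(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Proportion of unequal labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    return float(np.mean(y_true != y_pred))


def kaplan_meier(time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier estimate of the survival function of ``event`` times.

    Returns the distinct event times and the right-continuous survival
    probabilities just after each.  Standard tie convention: subjects
    censored at t remain at risk for events at t.
    """
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event, dtype=np.int64)
    n = time.size
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order]
    grid = np.unique(t_sorted[e_sorted == 1])
    surv = np.empty(grid.size)
    s = 1.0
    for j, t in enumerate(grid):
        at_risk = n - np.searchsorted(t_sorted, t, side="left")
        d = np.sum(e_sorted[t_sorted == t])
        s *= 1.0 - d / at_risk
        surv[j] = s
    return grid, surv


def censoring_survival(surv_true: SurvivalOutcome) -> tuple[np.ndarray, np.ndarray]:
    """KM estimate G of the censoring distribution (status flipped)."""
    return kaplan_meier(surv_true.time, 1 - surv_true.status)


def _km_eval(grid: np.ndarray, surv: np.ndarray, t: np.ndarray, left: bool = False) -> np.ndarray:
    """Evaluate a KM step function at ``t``; ``left=True`` gives G(t-)."""
    t = np.asarray(t, dtype=np.float64)
    if grid.size == 0:  # no censoring events: G is identically 1
        return np.ones(t.shape)
    side = "left" if left else "right"
    j = np.searchsorted(grid, t, side=side) - 1
    return np.where(j >= 0, surv[np.clip(j, 0, None)], 1.0)


def _brier_at(
    surv_true: SurvivalOutcome,
    pred: SurvivalCurvePrediction,
    t: float,
    cg: np.ndarray,
    cs: np.ndarray,
    g_ti: np.ndarray,
) -> float:
    T = surv_true.time
    d = surv_true.status
    S_t = pred.at(t)
    # observation had the event by t: weight 1/G(T_i-)
    ev = (T <= t) & (d == 1)
    # observation still at risk past t: weight 1/G(t)
    at_risk = T > t
    g_t = _km_eval(cg, cs, np.array([t]))[0]
    contrib = np.zeros(T.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib[ev] = S_t[ev] ** 2 / g_ti[ev]
        if g_t > 0:
            contrib[at_risk] = (1.0 - S_t[at_risk]) ** 2 / g_t
    return float(np.mean(contrib))


def brier_score(surv_true: SurvivalOutcome, pred: SurvivalCurvePrediction, t: float) -> float:
    """IPCW Brier score at a single time ``t``."""
    cg, cs = censoring_survival(surv_true)
    g_ti = _km_eval(cg, cs, surv_true.time, left=True)
    return _brier_at(surv_true, pred, t, cg, cs, g_ti)


def integrated_brier_score(
    surv_true: SurvivalOutcome,
    pred: SurvivalCurvePrediction,
    tau: float | None = None,
) -> float:
    """IBS = (1/tau) * integral_0^tau BS(t) dt, by trapezoid over the grid.

    ``tau`` defaults to the 95th percentile of the evaluation event times
    (the integration horizon is a reporting choice; a fixed quantile keeps it
    data-driven and comparable across replicates).
    """
    if pred.times.size == 0:
        raise ValueError("empty prediction time grid")
    if tau is None:
        ev_times = surv_true.time[surv_true.status == 1]
        if ev_times.size == 0:
            ev_times = surv_true.time
        tau = float(np.quantile(ev_times, 0.95))
    if tau <= 0:
        raise ValueError("integration horizon tau must be positive")
    grid = pred.times[(pred.times > 0) & (pred.times < tau)]
    ts = np.concatenate([[0.0], grid, [tau]])
    cg, cs = censoring_survival(surv_true)
    g_ti = _km_eval(cg, cs, surv_true.time, left=True)
    bs = np.array([_brier_at(surv_true, pred, t, cg, cs, g_ti) for t in ts])
    return float(np.trapezoid(bs, ts) / tau)
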