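"""Random forests with interchangeable nominal-predictor splitting strategies.

Five strategies decide how an unordered categorical predictor enters the
binary-split search at every node:

``partition``
    Exhaustive search over all ``2**(m-1) - 1`` two-partitions of the ``m``
    categories present in the node (the classical CART approach).
``order_split``
    Categories present in the node are ordered by an outcome-appropriate
    statistic (outcome mean for regression/binary, first principal component
    of the weighted class-probability covariance for multiclass, mean
    log-rank score for survival) and the predictor is then treated as
    ordinal, leaving only ``m - 1`` threshold candidates.
``order_once``
    The same ordering is computed once on the full training data before any
    tree is grown; the predictor is ordinal for the entire forest.
``dummy``
    The predictor is expanded into binary indicator columns before growing.
``ignore``
    Category codes are used as if they were ordinal, in label-sort order.

Split quality is measured by the decrease in Gini impurity (classification),
the decrease in the sum of squares (regression) or the squared standardized
two-sample log-rank statistic (survival).  Trees aggregate by majority vote,
mean, or an ensemble Nelson-Aalen cumulative hazard estimator.

For regression and binary classification, ``partition`` and ``order_split``
are split-equivalent: the best threshold on mean-ordered categories attains
the exhaustive-partition optimum.  Both routes here evaluate candidate gains
through the same numerical kernel, and the partition search resolves exact
gain ties in favour of the mean-ordering prefix, so forests grown with the
two methods from the same seed are identical tree for tree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import nominal as nom
from .data import Predictor, TrainingData, from_dataframe
from .metrics import SurvivalCurvePrediction
from .nominal import (
    CategoryOrdering,
    NominalVar,
    PartitionLimitError,
    SurvivalOutcome,
)

__all__ = [
    "ForestConfig",
    "SplitRule",
    "TreeNode",
    "Tree",
    "Forest",
    "NOMINAL_METHODS",
    "gini_decrease",
    "variance_decrease",
    "logrank_split_statistic",
    "best_split_for_variable",
    "grow_tree",
    "fit",
    "tree_node_counts",
    "available_categories_by_depth",
]

NOMINAL_METHODS = ("partition", "order_split", "order_once", "dummy", "ignore")

#: default minimal terminal node sizes per outcome type
DEFAULT_MIN_NODE_SIZE = {"classification": 1, "regression": 5, "survival": 3}

#: relative tolerance when the partition search checks whether the
#: mean-ordering prefix attains the exhaustive optimum (regression/binary)
_PREFIX_TOL = 1e-12


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters.

    ``mtry`` defaults to ``floor(sqrt(p))`` of the encoded predictor columns
    when left as ``None``.  ``min_node_size`` defaults per outcome type
    (classification 1, regression 5, survival 3); a node is split only while
    it holds at least ``2 * min_node_size`` observations.  Sampling is the
    classical bootstrap (n draws with replacement) per tree.
    """

    n_trees: int = 50
    mtry: int | None = None
    min_node_size: int | None = None
    nominal_method: str = "order_once"
    absent_level_policy: str = "random"
    seed: int = 0
    partition_cap: int = nom.DEFAULT_PARTITION_CAP
    dummy_scheme: str = "dummy"
    pca_weighted_mean: bool = True
    record_node_indices: bool = False
    record_node_categories: bool = False

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.nominal_method not in NOMINAL_METHODS:
            raise ValueError(f"unknown nominal method {self.nominal_method!r}")
        if self.absent_level_policy not in ("random", "left", None):
            raise ValueError("absent_level_policy must be 'random', 'left' or None")


@dataclass(frozen=True)
class SplitRule:
    """A binary split: threshold on an encoded column, or a category set.

    ``threshold`` rules send observations with value <= threshold left.
    ``category_set`` rules send categories whose bit is set in ``left_mask``
    left; ``present_mask`` records which categories were present in the node
    when the rule was made (arbitrary-precision ints, so there is no
    machine-word limit on the category count).
    """

    var_index: int
    kind: str  # "threshold" | "category_set"
    threshold: float = np.nan
    left_mask: int = 0
    present_mask: int = 0

    def goes_left(self, code: int) -> bool | None:
        """Left/right routing for one category code; None if absent."""
        if self.kind != "category_set":
            raise ValueError("not a category split")
        if self.left_mask >> code & 1:
            return True
        if self.present_mask >> code & 1:
            return False
        return None


@dataclass
class TreeNode:
    """One tree node: either an internal split or a terminal payload."""

    depth: int
    n_node: int
    split: SplitRule | None = None
    gain: float = 0.0
    left: int = -1
    right: int = -1
    payload: object = None
    n_categories: tuple[int, ...] | None = None  # per original nominal var
    indices: np.ndarray | None = None

    @property
    def is_terminal(self) -> bool:
        return self.split is None


@dataclass
class Tree:
    nodes: list[TreeNode]
    bootstrap: np.ndarray
    event_grid: np.ndarray | None = None  # survival: pooled bootstrap event times


# ---------------------------------------------------------------------------
# Split criteria (public single-candidate forms)
# ---------------------------------------------------------------------------


def gini_decrease(parent: np.ndarray, left: np.ndarray, right: np.ndarray) -> float:
    """Weighted Gini impurity decrease of one candidate split.

    Gini(node) = 1 - sum_g f_g**2; the decrease is
    Gini(P) - (n_L/n) Gini(L) - (n_R/n) Gini(R).
    """
    parent = np.asarray(parent, dtype=np.float64)
    left = np.asarray(left, dtype=np.float64)
    right = np.asarray(right, dtype=np.float64)
    if not np.array_equal(left + right, parent):
        raise ValueError("left + right must equal parent counts")
    n, nl, nr = parent.sum(), left.sum(), right.sum()
    if nl == 0 or nr == 0:
        raise ValueError("both children must be non-empty")
    return float(((left**2).sum() / nl + (right**2).sum() / nr - (parent**2).sum() / n) / n)


def variance_decrease(
    parent_sum: float, parent_sumsq: float, n: int,
    left_sum: float, left_sumsq: float, n_left: int,
) -> float:
    """Sum-of-squares decrease SS(P) - SS(L) - SS(R) of one candidate split.

    Uses the identity SS = sum(y^2) - sum(y)^2 / n; tiny negative values from
    cancellation are clamped to zero below 1e-12.
    """
    n_right = n - n_left
    if n_left <= 0 or n_right <= 0:
        raise ValueError("both children must be non-empty")
    right_sum = parent_sum - left_sum
    right_sumsq = parent_sumsq - left_sumsq
    ss_p = parent_sumsq - parent_sum**2 / n
    ss_l = left_sumsq - left_sum**2 / n_left
    ss_r = right_sumsq - right_sum**2 / n_right
    dec = ss_p - ss_l - ss_r
    return 0.0 if -1e-12 < dec < 0 else float(dec)


def logrank_split_statistic(left: SurvivalOutcome, right: SurvivalOutcome) -> float:
    """Squared standardized two-sample log-rank statistic (O-E)^2 / V.

    Computed over the pooled distinct event times with the hypergeometric
    variance; returns 0 when the variance is 0.  Symmetric in left/right.
    """
    if len(left) == 0 or len(right) == 0:
        raise ValueError("both children must be non-empty")
    time = np.concatenate([left.time, right.time])
    status = np.concatenate([left.status, right.status])
    group = np.concatenate([np.zeros(len(left), dtype=np.int64),
                            np.ones(len(right), dtype=np.int64)])
    if status.sum() == 0:
        raise ValueError("log-rank statistic needs at least one event")
    D, R, grid = _risk_tables(time, status, group, 2)
    o_minus_e, v = _logrank_terms(D[:1], R[:1], D.sum(axis=0), R.sum(axis=0))
    return float(0.0 if v[0] <= 0 else o_minus_e[0] ** 2 / v[0])


def _risk_tables(time, status, codes, m):
    """Per-category event counts D[m, J] and at-risk counts R[m, J] on the
    grid of distinct event times."""
    grid = np.unique(time[status == 1])
    J = grid.size
    ev = status == 1
    tidx = np.searchsorted(grid, time[ev])
    D = np.bincount(codes[ev] * J + tidx, minlength=m * J).reshape(m, J).astype(np.float64)
    # at risk at grid[j]: time >= grid[j]; count leavers with time < grid[j]
    # observation i is at risk at grid[j] iff time_i >= grid[j]; it leaves the
    # risk set at the first index q with grid[q] > time_i
    leave = np.searchsorted(grid, time, side="right")
    gone = np.bincount(codes * (J + 1) + leave, minlength=m * (J + 1)).reshape(m, J + 1)
    counts = gone.sum(axis=1, keepdims=True).astype(np.float64)
    # #{i: leave_i <= j} = #{i: time_i < grid[j]} -> at risk = counts minus that
    R = counts - np.cumsum(gone, axis=1)[:, :J]
    return D, R, grid


def _logrank_terms(D1, R1, d_tot, r_tot):
    """Vectorized (O-E, V) for rows of left-group tables D1, R1."""
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(r_tot > 0, R1 / r_tot, 0.0)
        o_minus_e = (D1 - d_tot * frac).sum(axis=1)
        vterm = d_tot * frac * (1.0 - frac) * np.where(
            r_tot > 1, (r_tot - d_tot) / (r_tot - 1), 0.0
        )
        v = vterm.sum(axis=1)
    return o_minus_e, v


# ---------------------------------------------------------------------------
# Vectorized candidate-gain kernels
#
# All candidate sets for one variable are scored through the same kernel:
# a candidate is a row of a boolean "left membership" matrix over the node's
# m ordered levels (prefix rows for threshold searches, all canonical
# 2-partitions for the exhaustive search).  Sharing the kernel keeps the
# ordered and exhaustive routes bit-identical on common candidates.
# ---------------------------------------------------------------------------


from functools import lru_cache


@lru_cache(maxsize=64)
def _prefix_masks_cached(m: int) -> np.ndarray:
    masks = np.tril(np.ones((m, m), dtype=np.float64), 0)[:-1]
    masks.setflags(write=False)
    return masks


def _prefix_masks(m: int) -> np.ndarray:
    """Left-membership rows of the m-1 threshold candidates on m levels."""
    return _prefix_masks_cached(m)


def _gains_classification(masks: np.ndarray, cnt: np.ndarray) -> np.ndarray:
    """Gini decrease for each candidate row; cnt is the m x c count table."""
    n = cnt.sum()
    tot = cnt.sum(axis=0)
    L = masks @ cnt
    nl = L.sum(axis=1)
    nr = n - nl
    R = tot - L
    with np.errstate(divide="ignore", invalid="ignore"):
        g = (L**2).sum(axis=1) / nl + (R**2).sum(axis=1) / nr - (tot**2).sum() / n
        g = g / n
    g[(nl == 0) | (nr == 0)] = -np.inf
    return g


def _gains_regression(masks: np.ndarray, sums: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """SS decrease for each candidate row from per-level y-sums and counts."""
    n = counts.sum()
    s = sums.sum()
    sl = masks @ sums
    nl = masks @ counts
    nr = n - nl
    with np.errstate(divide="ignore", invalid="ignore"):
        g = sl**2 / nl + (s - sl) ** 2 / nr - s**2 / n
    g[(nl == 0) | (nr == 0)] = -np.inf
    return g


def _gains_survival(masks: np.ndarray, D: np.ndarray, R: np.ndarray,
                    counts: np.ndarray) -> np.ndarray:
    """Squared standardized log-rank statistic for each candidate row."""
    d_tot = D.sum(axis=0)
    r_tot = R.sum(axis=0)
    D1 = masks @ D
    R1 = masks @ R
    o_minus_e, v = _logrank_terms(D1, R1, d_tot, r_tot)
    n = counts.sum()
    nl = masks @ counts
    g = np.where(v > 0, o_minus_e**2 / np.where(v > 0, v, 1.0), 0.0)
    g[(nl == 0) | (nl == n)] = -np.inf
    return g


# ---------------------------------------------------------------------------
# Per-variable split search
# ---------------------------------------------------------------------------


@dataclass
class _Outcome:
    """Node-level view of the outcome used by the split search."""

    kind: str
    y: np.ndarray | None = None
    c: int = 0
    time: np.ndarray | None = None
    status: np.ndarray | None = None


def _level_stats(codes: np.ndarray, m: int, out: _Outcome):
    """Sufficient statistics per level for the gain kernels."""
    if out.kind == "classification":
        cnt = np.bincount(codes * out.c + out.y, minlength=m * out.c)
        return ("cls", cnt.reshape(m, out.c).astype(np.float64))
    if out.kind == "regression":
        sums = np.bincount(codes, weights=out.y, minlength=m)
        counts = np.bincount(codes, minlength=m).astype(np.float64)
        return ("reg", sums, counts)
    D, R, _ = _risk_tables(out.time, out.status, codes, m)
    counts = np.bincount(codes, minlength=m).astype(np.float64)
    return ("srv", D, R, counts)


def _gains(masks: np.ndarray, stats) -> np.ndarray:
    if stats[0] == "cls":
        return _gains_classification(masks, stats[1])
    if stats[0] == "reg":
        return _gains_regression(masks, stats[1], stats[2])
    return _gains_survival(masks, stats[1], stats[2], stats[3])


def _first_argmax(g: np.ndarray) -> tuple[int, float]:
    i = int(np.argmax(g))
    return i, float(g[i])


def _node_ordering_scores(codes: np.ndarray, m: int, out: _Outcome) -> np.ndarray:
    """Per-level ordering score: mean outcome, PC1 score, or mean log-rank score."""
    if out.kind == "regression" or (out.kind == "classification" and out.c == 2):
        y = out.y.astype(np.float64)
        sums = np.bincount(codes, weights=y, minlength=m)
        counts = np.bincount(codes, minlength=m)
        return sums / counts
    if out.kind == "classification":
        var = NominalVar(codes=codes, labels=tuple(str(i) for i in range(m)))
        ordering = nom.pca_order(var, out.y, out.c)
        # convert ordering to scores (rank works: stable ascending)
        return ordering.rank.astype(np.float64)
    scores = nom.logrank_scores(SurvivalOutcome(time=out.time, status=out.status))
    sums = np.bincount(codes, weights=scores, minlength=m)
    counts = np.bincount(codes, minlength=m)
    return sums / counts


def _ordering_from_scores(scores: np.ndarray) -> np.ndarray:
    """Stable ascending argsort: the level permutation of the ordering."""
    return np.argsort(scores, kind="stable")


def _threshold_search(codes: np.ndarray, m: int, out: _Outcome):
    """Best threshold on an already-ordered level domain 0..m-1.

    Returns (level_index, gain, n_candidates) or None; the split is
    value <= level_index.  Uses direct cumulative-sum kernels (prefix
    candidates are cumulative by construction).
    """
    if m < 2:
        return None
    if out.kind == "classification":
        c = out.c
        cnt = np.bincount(codes * c + out.y, minlength=m * c).reshape(m, c)
        cnt = cnt.astype(np.float64)
        n = codes.size
        tot = cnt.sum(axis=0)
        L = np.cumsum(cnt, axis=0)[:-1]
        nl = L.sum(axis=1)
        nr = n - nl
        R = tot - L
        with np.errstate(divide="ignore", invalid="ignore"):
            g = ((L * L).sum(axis=1) / nl + (R * R).sum(axis=1) / nr
                 - tot @ tot / n) / n
        g[(nl == 0) | (nr == 0)] = -np.inf
    elif out.kind == "regression":
        sums = np.bincount(codes, weights=out.y, minlength=m)
        counts = np.bincount(codes, minlength=m).astype(np.float64)
        n = codes.size
        s = sums.sum()
        sl = np.cumsum(sums)[:-1]
        nl = np.cumsum(counts)[:-1]
        nr = n - nl
        with np.errstate(divide="ignore", invalid="ignore"):
            g = sl * sl / nl + (s - sl) ** 2 / nr - s * s / n
        g[(nl == 0) | (nr == 0)] = -np.inf
    else:
        D, R, _ = _risk_tables(out.time, out.status, codes, m)
        counts = np.bincount(codes, minlength=m).astype(np.float64)
        d_tot = D.sum(axis=0)
        r_tot = R.sum(axis=0)
        D1 = np.cumsum(D, axis=0)[:-1]
        R1 = np.cumsum(R, axis=0)[:-1]
        o_minus_e, v = _logrank_terms(D1, R1, d_tot, r_tot)
        nl = np.cumsum(counts)[:-1]
        g = np.where(v > 0, o_minus_e**2 / np.where(v > 0, v, 1.0), 0.0)
        g[(nl == 0) | (nl == codes.size)] = -np.inf
    t, gain = _first_argmax(g)
    if not np.isfinite(gain):
        return None
    return t, gain, m - 1


def _category_split_search(codes, k, out: _Outcome, method: str, cap: int):
    """Best category-set split for a nominal column at one node.

    ``method`` is "partition" or "order_split".  Only categories present in
    the node are partitioned; the returned left/present masks are over the
    original category codes.
    """
    present = np.flatnonzero(np.bincount(codes, minlength=k))
    m = present.size
    if m < 2:
        return None
    # compress codes to the present-category domain
    compress = np.full(k, -1, dtype=np.int64)
    compress[present] = np.arange(m)
    ccodes = compress[codes]
    stats = _level_stats(ccodes, m, out)

    equivalence = out.kind == "regression" or (out.kind == "classification" and out.c == 2)

    perm = t_best = g_prefix = None
    if method == "order_split" or equivalence:
        scores = _node_ordering_scores(ccodes, m, out)
        perm = _ordering_from_scores(scores)  # level at each ordinal position
        rank = np.empty(m, dtype=np.int64)
        rank[perm] = np.arange(m)
        # prefix candidate rows in *level* space: level l left iff rank[l] <= t
        prefix = (rank[None, :] <= np.arange(m - 1)[:, None]).astype(np.float64)
        pg = _gains(prefix, stats)
        t_best, g_prefix = _first_argmax(pg)

    if method == "order_split":
        if not np.isfinite(g_prefix):
            return None
        left_levels = present[perm[: t_best + 1]]
        return left_levels, present, g_prefix, m - 1

    # exhaustive partition search (chunked so memory stays bounded)
    if m > cap:
        raise PartitionLimitError(
            f"Partition method: {m} categories present at a node exceed the "
            f"cap of {cap} ({nom.count_partitions(m)} candidate 2-partitions)"
        )
    n_cand = nom.count_partitions(m)
    i_best, g_best = -1, -np.inf
    chunk = 1 << 15
    for start in range(0, n_cand, chunk):
        stop = min(start + chunk, n_cand)
        bits = np.arange(start, stop, dtype=np.int64)
        masks = np.empty((stop - start, m), dtype=np.float64)
        masks[:, 0] = 1.0
        for j in range(1, m):
            masks[:, j] = (bits >> (j - 1)) & 1
        g = _gains(masks, stats)
        i_chunk, g_chunk = _first_argmax(g)
        if g_chunk > g_best:
            i_best, g_best = start + i_chunk, g_chunk
    if not np.isfinite(g_best):
        return None
    if equivalence and np.isfinite(g_prefix) and \
            g_prefix >= g_best - _PREFIX_TOL * max(1.0, abs(g_best)):
        # the mean-ordering prefix attains the optimum (split-equivalence
        # theorem); choosing it keeps partition and order_split identical
        left_levels = present[perm[: t_best + 1]]
        return left_levels, present, g_prefix, n_cand
    in_left = np.array([True] + [bool(i_best >> j & 1) for j in range(m - 1)])
    left_levels = present[in_left]
    if equivalence and perm is not None:
        # orient the split so the low-mean side goes left, as ordering does
        low = present[perm[0]]
        if low not in left_levels:
            left_levels = np.setdiff1d(present, left_levels)
    return left_levels, present, g_best, n_cand


def _bits(levels: np.ndarray) -> int:
    mask = 0
    for lv in levels:
        mask |= 1 << int(lv)
    return mask


# ---------------------------------------------------------------------------
# Design: method-specific encoding of the predictors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _DesignColumn:
    """One encoded predictor column as seen by the tree grower.

    kind "int": small ordered integer domain (ordinal ranks, recoded nominal
    ranks, dummy indicators); "float": continuous; "cat": raw nominal codes
    for the partition / order_split methods.
    """

    name: str
    orig: int  # index of the originating predictor
    kind: str
    data: np.ndarray
    m: int = 0  # int domain size / nominal k
    ordering: CategoryOrdering | None = None  # order_once / ignore recoding
    dummy_category: int = -1  # dummy: the category this indicator marks


@dataclass
class _Design:
    columns: list[_DesignColumn]
    method: str

    @property
    def p(self) -> int:
        return len(self.columns)


def _global_ordering(var: NominalVar, train: TrainingData, cfg: ForestConfig) -> CategoryOrdering:
    """A-priori ordering of one nominal variable on the full training data."""
    if train.outcome_type == "regression":
        return nom.order_by_mean(var, train.y)
    if train.outcome_type == "classification":
        if train.n_classes <= 2:  # degenerate one-class data: mean order is fine
            return nom.order_by_mean(var, train.y.astype(np.float64))
        return nom.pca_order(var, train.y, train.n_classes)
    return nom.order_by_logrank(var, train.surv)


def _build_design(train: TrainingData, cfg: ForestConfig) -> _Design:
    cols: list[_DesignColumn] = []
    method = cfg.nominal_method
    for j, pred in enumerate(train.predictors):
        if pred.kind == "numeric":
            cols.append(_DesignColumn(pred.name, j, "float", pred.values))
        elif pred.kind == "ordinal":
            cols.append(_DesignColumn(pred.name, j, "int",
                                      pred.values.astype(np.int64), m=pred.levels.size))
        else:
            var = pred.var
            if method == "ignore":
                ordering = CategoryOrdering(permutation=np.arange(var.k))
                cols.append(_DesignColumn(pred.name, j, "int", var.codes.copy(),
                                          m=var.k, ordering=ordering))
            elif method == "order_once":
                ordering = _global_ordering(var, train, cfg)
                cols.append(_DesignColumn(pred.name, j, "int",
                                          nom.apply_ordering(var, ordering),
                                          m=var.k, ordering=ordering))
            elif method == "dummy":
                X, names = nom.dummy_encode(var, cfg.dummy_scheme, name=pred.name)
                offset = 0 if cfg.dummy_scheme == "one-hot" else 1
                for jj in range(X.shape[1]):
                    cols.append(_DesignColumn(names[jj], j, "int",
                                              X[:, jj].astype(np.int64), m=2,
                                              dummy_category=jj + offset))
            else:  # partition / order_split
                if method == "partition" and var.k > cfg.partition_cap:
                    raise PartitionLimitError(
                        f"Partition method: predictor {pred.name!r} has {var.k} "
                        f"categories, above the cap of {cfg.partition_cap}"
                    )
                cols.append(_DesignColumn(pred.name, j, "cat", var.codes, m=var.k))
    return _Design(columns=cols, method=method)


# ---------------------------------------------------------------------------
# Tree growing
# ---------------------------------------------------------------------------


def _node_outcome(out_full: _Outcome, idx: np.ndarray) -> _Outcome:
    if out_full.kind == "survival":
        return _Outcome(kind="survival", time=out_full.time[idx], status=out_full.status[idx])
    return _Outcome(kind=out_full.kind, y=out_full.y[idx], c=out_full.c)


def _is_pure(out: _Outcome) -> bool:
    if out.kind == "classification":
        return np.all(out.y == out.y[0])
    if out.kind == "regression":
        return np.all(out.y == out.y[0])
    return out.status.sum() == 0  # no events left: nothing to split on


def _terminal_payload(out: _Outcome, event_grid: np.ndarray | None):
    if out.kind == "classification":
        return np.bincount(out.y, minlength=out.c)
    if out.kind == "regression":
        return float(out.y.mean())
    # Nelson-Aalen cumulative hazard of the node data on the tree grid
    grid = event_grid
    J = grid.size
    if J == 0:
        return np.zeros(0)
    ev = out.status == 1
    tidx = np.searchsorted(grid, out.time[ev])
    d = np.bincount(tidx, minlength=J).astype(np.float64)
    r = np.searchsorted(grid, out.time, side="left")
    gone = np.bincount(r, minlength=J + 1)
    at_risk = out.time.size - (np.cumsum(gone)[:J] - gone[:J])
    with np.errstate(divide="ignore", invalid="ignore"):
        hazard = np.where(at_risk > 0, d / at_risk, 0.0)
    return np.cumsum(hazard)


def _best_node_split(design: _Design, idx: np.ndarray, out_node: _Outcome,
                     candidates: np.ndarray, cfg: ForestConfig, audit: list | None):
    best = None  # (gain, col_index, rule)
    for col_j in map(int, candidates):
        col = design.columns[col_j]
        n_cand = 0
        found = None
        if col.kind == "int":
            res = _threshold_search(col.data[idx], col.m, out_node)
            if res is not None:
                t, gain, n_cand = res
                found = (gain, SplitRule(var_index=col_j, kind="threshold",
                                         threshold=t + 0.5))
        elif col.kind == "float":
            v = col.data[idx]
            levels, codes = np.unique(v, return_inverse=True)
            res = _threshold_search(codes, levels.size, out_node)
            if res is not None:
                t, gain, n_cand = res
                found = (gain, SplitRule(var_index=col_j, kind="threshold",
                                         threshold=float((levels[t] + levels[t + 1]) / 2)))
        else:
            res = _category_split_search(col.data[idx], col.m, out_node,
                                         design.method, cfg.partition_cap)
            if res is not None:
                left_levels, present, gain, n_cand = res
                found = (gain, SplitRule(var_index=col_j, kind="category_set",
                                         left_mask=_bits(left_levels),
                                         present_mask=_bits(present)))
        if audit is not None:
            audit.append({"n_node": idx.size, "column": col.name,
                          "n_candidates": n_cand,
                          "gain": found[0] if found else None})
        if found is not None and found[0] > 0 and (best is None or found[0] > best[0]):
            best = found
    return best


def _apply_rule(design: _Design, rule: SplitRule, idx: np.ndarray) -> np.ndarray:
    """Boolean go-left vector for training observations (all present)."""
    col = design.columns[rule.var_index]
    v = col.data[idx]
    if rule.kind == "threshold":
        return v <= rule.threshold
    left = np.zeros(col.m, dtype=bool)
    for code in range(col.m):
        if rule.left_mask >> code & 1:
            left[code] = True
    return left[v]


def grow_tree(design: _Design, out_full: _Outcome, bootstrap: np.ndarray,
              cfg: ForestConfig, rng: np.random.Generator,
              orig_codes: list[np.ndarray] | None = None,
              audit: list | None = None) -> Tree:
    """Grow one tree on a bootstrap sample by recursive best-gain splitting.

    At every node ``mtry`` candidate columns are drawn without replacement;
    growth stops when a node is pure, smaller than ``2 * min_node_size``, or
    no candidate achieves positive gain.
    """
    min_node = cfg.min_node_size
    if min_node is None:
        min_node = DEFAULT_MIN_NODE_SIZE[out_full.kind]
    mtry = cfg.mtry or max(1, int(np.sqrt(design.p)))
    mtry = min(mtry, design.p)

    event_grid = None
    if out_full.kind == "survival":
        bt = out_full.time[bootstrap]
        bs = out_full.status[bootstrap]
        event_grid = np.unique(bt[bs == 1])

    nodes: list[TreeNode] = []
    stack: list[tuple[np.ndarray, int, int, str]] = [(bootstrap, 0, -1, "")]
    while stack:
        idx, depth, parent, side = stack.pop()
        node_id = len(nodes)
        if parent >= 0:
            setattr(nodes[parent], side, node_id)
        out_node = _node_outcome(out_full, idx)
        node = TreeNode(depth=depth, n_node=idx.size)
        if cfg.record_node_indices:
            node.indices = idx
        if cfg.record_node_categories and orig_codes is not None:
            node.n_categories = tuple(np.unique(c[idx]).size for c in orig_codes)
        nodes.append(node)

        splittable = idx.size >= 2 * min_node and not _is_pure(out_node)
        best = None
        if splittable:
            candidates = rng.permutation(design.p)[:mtry]
            best = _best_node_split(design, idx, out_node, candidates, cfg, audit)
        if best is None:
            node.payload = _terminal_payload(out_node, event_grid)
            continue
        gain, rule = best
        node.split = rule
        node.gain = gain
        go_left = _apply_rule(design, rule, idx)
        # push right first so the left child is processed (and numbered) first
        stack.append((idx[~go_left], depth + 1, node_id, "right"))
        stack.append((idx[go_left], depth + 1, node_id, "left"))
    return Tree(nodes=nodes, bootstrap=bootstrap, event_grid=event_grid)


# ---------------------------------------------------------------------------
# Forest fitting and prediction
# ---------------------------------------------------------------------------


@dataclass
class Forest:
    """A fitted forest: trees plus everything needed to encode new data."""

    trees: list[Tree]
    config: ForestConfig
    outcome_type: str
    design: _Design = field(repr=False)
    predictors: tuple[Predictor, ...] = field(repr=False)
    classes: np.ndarray | None = None
    audit: list | None = None

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    # -- encoding new data -------------------------------------------------

    def _encode(self, df: pd.DataFrame) -> list[np.ndarray]:
        """Per design column: float values (NaN = unknown) or codes (-1)."""
        out = []
        for col in self.design.columns:
            pred = self.predictors[col.orig]
            raw = df[pred.name].to_numpy()
            if pred.kind == "numeric":
                out.append(raw.astype(np.float64))
            elif pred.kind == "ordinal":
                vals = raw.astype(np.float64)
                # rank of known levels; in-between values get half-ranks
                r = np.searchsorted(pred.levels, vals, side="left").astype(np.float64)
                exact = np.isin(vals, pred.levels)
                r[~exact] -= 0.5
                out.append(r)
            else:
                lookup = {lab: i for i, lab in enumerate(pred.var.labels)}
                codes = np.array([lookup.get(str(v), -1) for v in raw], dtype=np.int64)
                if col.kind == "cat":
                    out.append(codes)
                elif col.dummy_category >= 0:
                    vals = (codes == col.dummy_category).astype(np.float64)
                    out.append(vals)  # unknown labels become all-zero rows
                else:
                    ranks = np.where(codes >= 0, col.ordering.rank[np.clip(codes, 0, None)], -1)
                    out.append(np.where(codes >= 0, ranks.astype(np.float64), np.nan))
        return out

    def _route(self, tree: Tree, encoded: list[np.ndarray], n: int,
               policy_rng: np.random.Generator) -> np.ndarray:
        """Terminal node id of each observation."""
        leaf = np.full(n, -1, dtype=np.int64)
        node_idx: dict[int, np.ndarray] = {0: np.arange(n)}
        for i, node in enumerate(tree.nodes):
            idx = node_idx.pop(i, None)
            if idx is None or idx.size == 0:
                continue
            if node.is_terminal:
                leaf[idx] = i
                continue
            rule = node.split
            col = self.design.columns[rule.var_index]
            v = encoded[rule.var_index][idx]
            if rule.kind == "threshold":
                go_left = v <= rule.threshold
                unknown = np.isnan(v)
            else:
                k = max(col.m, 1)
                left = np.array([(rule.left_mask >> c) & 1 for c in range(k)], dtype=bool)
                present = np.array([(rule.present_mask >> c) & 1 for c in range(k)], dtype=bool)
                vc = v.astype(np.int64)
                safe = np.clip(vc, 0, k - 1)
                go_left = left[safe]
                unknown = (vc < 0) | ~present[safe]
            if unknown.any():
                policy = self.config.absent_level_policy
                if policy is None:
                    raise ValueError(
                        f"prediction data contains categories absent from this "
                        f"split of {col.name!r} and no absent_level_policy is set"
                    )
                if policy == "left":
                    go_left = np.where(unknown, True, go_left)
                else:
                    go_left = np.where(unknown, policy_rng.integers(0, 2, unknown.size) == 0,
                                       go_left)
            l_idx = idx[go_left]
            r_idx = idx[~go_left]
            if node.left >= 0:
                node_idx[node.left] = l_idx
            if node.right >= 0:
                node_idx[node.right] = r_idx
        return leaf

    # -- prediction --------------------------------------------------------

    def predict(self, df: pd.DataFrame):
        """Ensemble prediction for new data.

        Classification: per-tree terminal majority, then forest majority vote
        (ties to the lowest class index); returns original class labels.
        Regression: mean of tree means.  Survival: pointwise mean of the
        per-tree Nelson-Aalen cumulative hazards on the union event-time
        grid, returned as a :class:`SurvivalCurvePrediction`.
        """
        self._check_new_labels(df)
        n = len(df)
        encoded = self._encode(df)
        policy_rng = np.random.default_rng(
            np.random.SeedSequence([self.config.seed & 0x7FFFFFFF, 0x5EED])
        )
        if self.outcome_type == "survival":
            union = np.unique(np.concatenate(
                [t.event_grid for t in self.trees if t.event_grid.size]
            )) if any(t.event_grid.size for t in self.trees) else np.array([1.0])
            chf_sum = np.zeros((n, union.size))
            for tree in self.trees:
                leaf = self._route(tree, encoded, n, policy_rng)
                payload = np.vstack([
                    tree.nodes[i].payload if tree.nodes[i].payload.size else
                    np.zeros(max(tree.event_grid.size, 0)) for i in leaf
                ]) if tree.event_grid.size else np.zeros((n, 0))
                if tree.event_grid.size:
                    pos = np.searchsorted(tree.event_grid, union, side="right") - 1
                    vals = np.where(pos[None, :] >= 0,
                                    payload[:, np.clip(pos, 0, None)], 0.0)
                else:
                    vals = np.zeros((n, union.size))
                chf_sum += vals
            chf = chf_sum / self.n_trees
            return SurvivalCurvePrediction(times=union, surv=np.exp(-chf))
        votes = np.zeros((n, self.classes.size), dtype=np.int64) \
            if self.outcome_type == "classification" else None
        total = np.zeros(n)
        for tree in self.trees:
            leaf = self._route(tree, encoded, n, policy_rng)
            if self.outcome_type == "classification":
                cls = np.array([int(np.argmax(tree.nodes[i].payload)) for i in leaf])
                votes[np.arange(n), cls] += 1
            else:
                total += np.array([tree.nodes[i].payload for i in leaf])
        if self.outcome_type == "classification":
            return self.classes[np.argmax(votes, axis=1)]
        return total / self.n_trees

    def predict_cumulative_hazard(self, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        pred = self.predict(df)
        return pred.times, -np.log(np.clip(pred.surv, 1e-300, None))

    def _check_new_labels(self, df: pd.DataFrame) -> None:
        if self.config.absent_level_policy is not None:
            return
        offending = {}
        for pred in self.predictors:
            if pred.kind != "nominal":
                continue
            new = set(str(v) for v in df[pred.name].unique()) - set(pred.var.labels)
            if new:
                offending[pred.name] = sorted(new)
        if offending:
            raise ValueError(f"new categories at prediction time: {offending}")

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> dict:
        def node_dict(nd: TreeNode):
            d = {"depth": nd.depth, "n": nd.n_node}
            if nd.is_terminal:
                p = nd.payload
                d["payload"] = p.tolist() if isinstance(p, np.ndarray) else p
            else:
                d.update(var=nd.split.var_index, kind=nd.split.kind,
                         left=nd.left, right=nd.right, gain=nd.gain)
                if nd.split.kind == "threshold":
                    d["threshold"] = nd.split.threshold
                else:
                    d["left_mask"] = format(nd.split.left_mask, "x")
                    d["present_mask"] = format(nd.split.present_mask, "x")
            return d

        obj = {
            "outcome_type": self.outcome_type,
            "method": self.config.nominal_method,
            "config": {k: getattr(self.config, k) for k in
                       ("n_trees", "mtry", "min_node_size", "nominal_method",
                        "absent_level_policy", "seed", "dummy_scheme",
                        "partition_cap")},
            "classes": self.classes.tolist() if self.classes is not None else None,
            "predictors": [
                {"name": p.name, "kind": p.kind,
                 "labels": list(p.var.labels) if p.kind == "nominal" else None,
                 "levels": p.levels.tolist() if p.kind == "ordinal" else None}
                for p in self.predictors
            ],
            "design": [
                {"name": c.name, "orig": c.orig, "kind": c.kind, "m": c.m,
                 "ordering": (c.ordering.permutation.tolist()
                              if c.ordering is not None else None),
                 "dummy_category": c.dummy_category}
                for c in self.design.columns
            ],
            "orderings": [
                c.ordering.to_json(c.name, self.predictors[c.orig].var.labels)
                for c in self.design.columns
                if c.ordering is not None and self.predictors[c.orig].kind == "nominal"
            ],
            "trees": [
                {"event_grid": (t.event_grid.tolist() if t.event_grid is not None else None),
                 "nodes": [node_dict(nd) for nd in t.nodes]}
                for t in self.trees
            ],
        }
        if path is not None:
            Path(path).write_text(json.dumps(obj))
        return obj

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "Forest":
        """Rebuild a fitted forest from :meth:`to_json` output.

        The reconstruction carries everything prediction needs (encodings,
        orderings, split rules, terminal payloads); training arrays are not
        retained.
        """
        obj = source if isinstance(source, dict) else json.loads(Path(source).read_text())
        config = ForestConfig(**obj["config"])
        predictors = []
        for pd_ in obj["predictors"]:
            if pd_["kind"] == "nominal":
                var = NominalVar(codes=np.zeros(0, dtype=np.int64),
                                 labels=tuple(pd_["labels"]))
                predictors.append(Predictor(pd_["name"], "nominal", var=var))
            elif pd_["kind"] == "ordinal":
                predictors.append(Predictor(pd_["name"], "ordinal",
                                            levels=np.asarray(pd_["levels"])))
            else:
                predictors.append(Predictor(pd_["name"], "numeric"))
        columns = []
        for c in obj["design"]:
            ordering = (CategoryOrdering(permutation=np.asarray(c["ordering"]))
                        if c["ordering"] is not None else None)
            columns.append(_DesignColumn(c["name"], c["orig"], c["kind"],
                                         data=np.zeros(0), m=c["m"],
                                         ordering=ordering,
                                         dummy_category=c["dummy_category"]))
        trees = []
        for t in obj["trees"]:
            nodes = []
            for nd in t["nodes"]:
                node = TreeNode(depth=nd["depth"], n_node=nd["n"])
                if "payload" in nd:
                    p = nd["payload"]
                    node.payload = np.asarray(p) if isinstance(p, list) else p
                else:
                    node.left, node.right, node.gain = nd["left"], nd["right"], nd["gain"]
                    if nd["kind"] == "threshold":
                        node.split = SplitRule(nd["var"], "threshold",
                                               threshold=nd["threshold"])
                    else:
                        node.split = SplitRule(nd["var"], "category_set",
                                               left_mask=int(nd["left_mask"], 16),
                                               present_mask=int(nd["present_mask"], 16))
                nodes.append(node)
            grid = (np.asarray(t["event_grid"], dtype=np.float64)
                    if t["event_grid"] is not None else None)
            trees.append(Tree(nodes=nodes, bootstrap=np.zeros(0, dtype=np.int64),
                              event_grid=grid))
        classes = np.asarray(obj["classes"]) if obj["classes"] is not None else None
        return cls(trees=trees, config=config, outcome_type=obj["outcome_type"],
                   design=_Design(columns=columns, method=config.nominal_method),
                   predictors=tuple(predictors), classes=classes)


def fit(df: pd.DataFrame, schema: dict[str, str], config: ForestConfig,
        audit: bool = False) -> Forest:
    """Fit a forest on a DataFrame under the given column schema.

    Method preprocessing (a-priori orderings, dummy expansion, ordinal
    recoding) happens once here; each of the ``n_trees`` trees is then grown
    on an independent bootstrap sample with its own child RNG stream derived
    from ``config.seed``, so fits are reproducible.
    """
    train = from_dataframe(df, schema)
    return fit_training_data(train, config, audit=audit)


def fit_training_data(train: TrainingData, config: ForestConfig, audit: bool = False) -> Forest:
    design = _build_design(train, config)
    if config.mtry is not None and not 1 <= config.mtry <= design.p:
        raise ValueError(f"mtry must be in 1..{design.p} (encoded columns)")
    if train.outcome_type == "classification":
        out = _Outcome(kind="classification", y=train.y, c=train.n_classes)
    elif train.outcome_type == "regression":
        out = _Outcome(kind="regression", y=train.y)
    else:
        out = _Outcome(kind="survival", time=train.surv.time, status=train.surv.status)
    orig_codes = None
    if config.record_node_categories:
        orig_codes = [p.var.codes if p.kind == "nominal" else
                      np.zeros(train.n, dtype=np.int64) for p in train.predictors]
    audit_list: list | None = [] if audit else None
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_trees)
    trees = []
    n = train.n
    for child in children:
        rng = np.random.default_rng(child)
        bootstrap = rng.integers(0, n, n)
        trees.append(grow_tree(design, out, bootstrap, config, rng,
                               orig_codes=orig_codes, audit=audit_list))
    return Forest(trees=trees, config=config, outcome_type=train.outcome_type,
                  design=design, predictors=train.predictors,
                  classes=train.classes, audit=audit_list)


# ---------------------------------------------------------------------------
# Introspection helpers
# ---------------------------------------------------------------------------


def tree_node_counts(forest: Forest) -> np.ndarray:
    """Number of nodes of each tree."""
    return np.array([len(t.nodes) for t in forest.trees])


def available_categories_by_depth(forest: Forest, var: str) -> pd.Series:
    """Mean number of distinct categories of ``var`` per tree depth.

    Requires the forest to have been fitted with
    ``record_node_categories=True``.  Averages over all nodes at each depth
    across all trees.
    """
    j = next(i for i, p in enumerate(forest.predictors) if p.name == var)
    rows = []
    for tree in forest.trees:
        for node in tree.nodes:
            if node.n_categories is None:
                raise ValueError("fit with record_node_categories=True first")
            rows.append((node.depth, node.n_categories[j]))
    df = pd.DataFrame(rows, columns=["depth", "n_categories"])
    return df.groupby("depth")["n_categories"].mean()


def best_split_for_variable(var, outcome, outcome_type: str, method: str,
                            c: int | None = None,
                            config: ForestConfig | None = None):
    """Best split of one variable at one node; the per-method entry point.

    ``var`` is a :class:`NominalVar` (nominal) or a numeric array (treated as
    continuous).  Nominal variables are searched according to ``method``:
    exhaustive 2-partitions, node-local ordering, or — for ``order_once`` /
    ``ignore`` — threshold search on the supplied codes taken as ordinal.
    Returns ``(SplitRule, gain, n_candidates)`` or ``None`` when no candidate
    achieves positive gain.
    """
    config = config or ForestConfig(nominal_method=method)
    if outcome_type == "classification":
        y = np.asarray(outcome, dtype=np.int64)
        out = _Outcome(kind="classification", y=y, c=c or int(y.max()) + 1)
    elif outcome_type == "regression":
        out = _Outcome(kind="regression", y=np.asarray(outcome, dtype=np.float64))
    else:
        out = _Outcome(kind="survival", time=outcome.time, status=outcome.status)

    if isinstance(var, NominalVar):
        if method in ("partition", "order_split"):
            res = _category_split_search(var.codes, var.k, out, method, config.partition_cap)
            if res is None or res[2] <= 0:
                return None
            left_levels, present, gain, n_cand = res
            return (SplitRule(var_index=0, kind="category_set",
                              left_mask=_bits(left_levels), present_mask=_bits(present)),
                    gain, n_cand)
        if method == "dummy":
            X, _ = nom.dummy_encode(var, config.dummy_scheme)
            best = None
            total = 0
            for jj in range(X.shape[1]):
                res = _threshold_search(X[:, jj].astype(np.int64), 2, out)
                if res is None:
                    continue
                t, gain, n_cand = res
                total += n_cand
                if gain > 0 and (best is None or gain > best[1]):
                    best = (SplitRule(var_index=jj, kind="threshold", threshold=t + 0.5), gain)
            return None if best is None else (best[0], best[1], total)
        codes = var.codes
        if method == "order_once":
            raise ValueError("order_once needs a precomputed global ordering; "
                             "recode with apply_ordering and pass the ranks")
        res = _threshold_search(codes, var.k, out)  # ignore: codes as ordinal
        if res is None or res[1] <= 0:
            return None
        t, gain, n_cand = res
        return SplitRule(var_index=0, kind="threshold", threshold=t + 0.5), gain, n_cand

    v = np.asarray(var, dtype=np.float64)
    levels, codes = np.unique(v, return_inverse=True)
    res = _threshold_search(codes, levels.size, out)
    if res is None or res[1] <= 0:
        return None
    t, gain, n_cand = res
    thr = float((levels[t] + levels[t + 1]) / 2)
    return SplitRule(var_index=0, kind="threshold", threshold=thr), gain, n_cand
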