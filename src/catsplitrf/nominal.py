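"""Category ordering, partition enumeration and encoding for nominal predictors.

A binary tree can only split an unordered categorical (nominal) predictor by
assigning each of its ``k`` categories to one of the two child nodes.  This
module collects every strategy used to turn that combinatorial problem into
something tractable:

* exhaustive enumeration of all ``2**(k-1) - 1`` two-partitions,
* ordering categories by the within-category outcome mean (regression and
  binary classification, where ordering is provably loss-free),
* ordering by the first principal component of the weighted covariance of
  per-category class-probability vectors (multiclass classification),
* ordering by per-category means of log-rank scores (censored survival),
* dummy / one-hot encoding.

All orderings are deterministic: ties are broken by ascending category
index, and categories absent from the data at hand are appended after the
present ones, in index order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "NominalVar",
    "CategoryOrdering",
    "ClassProbabilityMatrix",
    "SurvivalOutcome",
    "PartitionLimitError",
    "count_partitions",
    "enumerate_partitions",
    "order_by_mean",
    "class_probability_matrix",
    "weighted_covariance",
    "pca_order",
    "logrank_scores",
    "order_by_logrank",
    "dummy_encode",
    "apply_ordering",
]

DEFAULT_PARTITION_CAP = 25


class PartitionLimitError(ValueError):
    """Raised when the Partition method would enumerate too many 2-partitions.

    Exhaustive partition search is exponential in the number of categories;
    implementations that store the left-child assignment in a machine word
    additionally cap the category count at 32/53/64.  This error reproduces
    that hard stop explicitly instead of silently degrading.
    """


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NominalVar:
    """Integer-coded nominal predictor column.

    Parameters
    ----------
    codes
        Integer codes in ``0..k-1``, one per observation.
    labels
        The ``k`` category names, in code order.
    """

    codes: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int64)
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("category labels must be unique")
        if self.k < 1:
            raise ValueError("a nominal variable needs at least one category")
        if codes.size and (codes.min() < 0 or codes.max() >= self.k):
            raise ValueError("codes must lie in 0..k-1")

    @property
    def k(self) -> int:
        """Number of categories."""
        return len(self.labels)

    @classmethod
    def from_values(cls, values: Sequence, labels: Sequence[str] | None = None) -> "NominalVar":
        """Factorize raw values into codes; labels default to sorted uniques."""
        values = np.asarray(values)
        if labels is None:
            labels = sorted(np.unique(values).astype(str).tolist())
        lookup = {lab: i for i, lab in enumerate(str(l) for l in labels)}
        codes = np.array([lookup[str(v)] for v in values], dtype=np.int64)
        return cls(codes=codes, labels=tuple(str(l) for l in labels))


@dataclass(frozen=True)
class CategoryOrdering:
    """A permutation of category indices plus its inverse (``rank``).

    ``permutation[i]`` is the category placed at ordinal position ``i``;
    ``rank[alpha]`` is the ordinal position of category ``alpha``.
    ``absent`` flags categories that were appended because they did not occur
    in the data used to build the ordering.
    """

    permutation: np.ndarray
    absent: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        perm = np.asarray(self.permutation, dtype=np.int64)
        object.__setattr__(self, "permutation", perm)
        k = perm.size
        if sorted(perm.tolist()) != list(range(k)):
            raise ValueError("permutation must be a bijection on 0..k-1")
        rank = np.empty(k, dtype=np.int64)
        rank[perm] = np.arange(k)
        object.__setattr__(self, "rank", rank)

    rank: np.ndarray = field(init=False)

    @property
    def k(self) -> int:
        return self.permutation.size

    def to_json(self, variable: str, labels: Sequence[str]) -> dict:
        return {"variable": variable, "order": [labels[i] for i in self.permutation]}


@dataclass(frozen=True)
class ClassProbabilityMatrix:
    """Per-category class frequency matrix P (rows: categories present).

    ``P[r, gamma]`` is the relative frequency of class ``gamma`` among
    observations with category ``categories[r]``; rows sum to one.  ``pbar``
    is the count-weighted mean row, so that the weighted covariance of the
    rows around ``pbar`` is a genuine covariance.
    """

    P: np.ndarray
    counts: np.ndarray
    categories: np.ndarray  # category index of each row
    n: int
    pbar: np.ndarray
    absent: frozenset[int] = field(default_factory=frozenset)


@dataclass(frozen=True)
class SurvivalOutcome:
    """Right-censored survival outcome: times ``Z`` and event indicators ``delta``."""

    time: np.ndarray
    status: np.ndarray

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=np.float64)
        status = np.asarray(self.status, dtype=np.int64)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "status", status)
        if time.shape != status.shape:
            raise ValueError("time and status must have equal length")
        if time.size and time.min() <= 0:
            raise ValueError("survival times must be positive")
        if status.size and not np.isin(status, (0, 1)).all():
            raise ValueError("status must be 0 (censored) or 1 (event)")

    def __len__(self) -> int:
        return self.time.size


# ---------------------------------------------------------------------------
# Partition enumeration
# ---------------------------------------------------------------------------


def count_partitions(k: int) -> int:
    """Number of 2-partitions of ``k`` categories, ``S(k, 2) = 2**(k-1) - 1``.

    Exact arbitrary-precision integer; there is no machine-word cap.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return 2 ** (k - 1) - 1


def enumerate_partitions(k: int, cap: int = DEFAULT_PARTITION_CAP) -> Iterator[frozenset[int]]:
    """Yield every 2-partition of ``0..k-1`` as its left-child category set.

    Canonical form: category 0 is always in the left set, and the remaining
    ``k-1`` categories are enumerated as a binary counter, so the order is
    deterministic and no set ever appears together with its complement.
    """
    if k < 2:
        raise ValueError("a 2-partition needs at least two categories")
    if k > cap:
        raise PartitionLimitError(
            f"Partition method: {k} categories would require "
            f"{count_partitions(k)} candidate 2-partitions (cap {cap})"
        )
    rest = list(range(1, k))
    for bits in range(2 ** (k - 1) - 1):
        yield frozenset([0] + [c for j, c in enumerate(rest) if bits >> j & 1])


def partition_masks(m: int) -> np.ndarray:
    """Boolean matrix of all canonical 2-partitions of ``m`` categories.

    Row ``i`` is the left-set indicator of the ``i``-th partition from
    :func:`enumerate_partitions`.  Shape ``(2**(m-1) - 1, m)``; intended for
    vectorized split search with modest ``m``.
    """
    n_parts = count_partitions(m)
    bits = np.arange(n_parts, dtype=np.int64)
    masks = np.empty((n_parts, m), dtype=bool)
    masks[:, 0] = True
    for j in range(1, m):
        masks[:, j] = (bits >> (j - 1)) & 1
    return masks


# ---------------------------------------------------------------------------
# Orderings
# ---------------------------------------------------------------------------


def _order_from_scores(k: int, present: np.ndarray, scores: np.ndarray) -> CategoryOrdering:
    """Ascending stable sort of present categories by score; absent appended."""
    present = np.asarray(present, dtype=np.int64)
    order = present[np.argsort(scores, kind="stable")]
    absent = np.setdiff1d(np.arange(k), present)
    return CategoryOrdering(
        permutation=np.concatenate([order, absent]),
        absent=frozenset(int(a) for a in absent),
    )


def order_by_mean(var: NominalVar, y: np.ndarray) -> CategoryOrdering:
    """Order categories by increasing within-category mean of ``y``.

    For a 0/1-coded binary outcome this is ordering by the proportion of
    ones.  For regression and binary classification, threshold splits on the
    resulting ranks recover the best split over all 2-partitions.
    """
    y = np.asarray(y, dtype=np.float64)
    if y.size == 0:
        raise ValueError("cannot order categories from an empty sample")
    counts = np.bincount(var.codes, minlength=var.k)
    sums = np.bincount(var.codes, weights=y, minlength=var.k)
    present = np.flatnonzero(counts)
    means = sums[present] / counts[present]
    return _order_from_scores(var.k, present, means)


def class_probability_matrix(var: NominalVar, y: np.ndarray, c: int) -> ClassProbabilityMatrix:
    """Contingency table of category x class, row-normalized to frequencies."""
    y = np.asarray(y, dtype=np.int64)
    if y.shape != var.codes.shape:
        raise ValueError("predictor and outcome lengths differ")
    if y.size and (y.min() < 0 or y.max() >= c):
        raise ValueError("class labels must lie in 0..c-1")
    N = np.bincount(var.codes * c + y, minlength=var.k * c).reshape(var.k, c).astype(np.float64)
    counts = N.sum(axis=1)
    present = np.flatnonzero(counts)
    P = N[present] / counts[present, None]
    n = int(counts.sum())
    pbar = (counts[present, None] * P).sum(axis=0) / n
    return ClassProbabilityMatrix(
        P=P,
        counts=counts[present].astype(np.int64),
        categories=present,
        n=n,
        pbar=pbar,
        absent=frozenset(int(a) for a in np.setdiff1d(np.arange(var.k), present)),
    )


def weighted_covariance(pm: ClassProbabilityMatrix, weighted_mean: bool = True) -> np.ndarray:
    """Weighted covariance of the class-probability rows.

    Sigma = 1/(n-1) * sum_alpha n_alpha (p^alpha - pbar)(p^alpha - pbar)^T.

    ``weighted_mean=False`` centers on the unweighted mean row instead of the
    count-weighted ``pbar``.
    """
    if pm.n < 2:
        raise ValueError("weighted covariance needs n >= 2")
    center = pm.pbar if weighted_mean else pm.P.mean(axis=0)
    D = pm.P - center
    return (D.T * pm.counts) @ D / (pm.n - 1)


def pca_order(var: NominalVar, y: np.ndarray, c: int) -> CategoryOrdering:
    """Order categories by first-principal-component scores of P's rows.

    The first principal component ``v`` of the weighted covariance of the
    per-category class-probability vectors defines scores
    ``S_alpha = v . p^alpha``; categories are sorted by ascending score.
    A degenerate (zero) covariance — all categories identically distributed —
    falls back to index order.  For two classes the resulting order coincides
    with ordering by the class-1 proportion, up to full reversal.
    """
    if var.k < 2 or c < 2:
        raise ValueError("pca_order needs k >= 2 categories and c >= 2 classes")
    pm = class_probability_matrix(var, y, c)
    sigma = weighted_covariance(pm)
    if np.abs(sigma).max() <= 1e-14:
        scores = np.zeros(pm.categories.size)
        return _order_from_scores(var.k, pm.categories, scores)
    eigvals, eigvecs = np.linalg.eigh(sigma)
    v = eigvecs[:, -1]
    pivot = int(np.argmax(np.abs(v)))  # first index of largest magnitude
    if v[pivot] < 0:
        v = -v
    scores = pm.P @ v
    return _order_from_scores(var.k, pm.categories, scores)


# ---------------------------------------------------------------------------
# Log-rank scores (survival)
# ---------------------------------------------------------------------------


def logrank_scores(surv: SurvivalOutcome, printed_form: bool = False) -> np.ndarray:
    """Per-observation log-rank scores for right-censored data.

    With observations ranked by time (events before censorings at tied
    times, then input order) and gamma_i the 1-based position of observation
    i, the score is::

        a_i = delta_i - sum_{j=1}^{gamma_i} delta_j / (N - gamma_j + 1)

    i.e. the event indicator minus the Nelson-Aalen-type cumulative hazard
    accumulated up to and including observation i.  The scores sum to zero
    exactly.  ``printed_form=True`` uses the constant denominator
    ``N - gamma_i + 1`` inside the sum (an alternative literal reading of the
    formula); it does not preserve the zero-sum identity and exists only for
    comparison.
    """
    N = len(surv)
    if N == 0:
        return np.zeros(0)
    # events (status 1) before censorings at tied times; stable in input order
    order = np.lexsort((1 - surv.status, surv.time))
    d_sorted = surv.status[order].astype(np.float64)
    ranks = np.arange(1, N + 1, dtype=np.float64)
    if printed_form:
        cum = np.array([np.sum(d_sorted[:g] / (N - g + 1)) for g in range(1, N + 1)])
    else:
        cum = np.cumsum(d_sorted / (N - ranks + 1))
    scores_sorted = d_sorted - cum
    scores = np.empty(N)
    scores[order] = scores_sorted
    return scores


def order_by_logrank(var: NominalVar, surv: SurvivalOutcome) -> CategoryOrdering:
    """Order categories by ascending mean log-rank score.

    High scores mark early events, so the category whose observations die
    earliest is placed *last*: ascending score order runs from long to short
    survival.
    """
    if len(surv) == 0:
        raise ValueError("cannot order categories from an empty sample")
    a = logrank_scores(surv)
    counts = np.bincount(var.codes, minlength=var.k)
    sums = np.bincount(var.codes, weights=a, minlength=var.k)
    present = np.flatnonzero(counts)
    return _order_from_scores(var.k, present, sums[present] / counts[present])


# ---------------------------------------------------------------------------
# Encodings
# ---------------------------------------------------------------------------


def dummy_encode(var: NominalVar, scheme: str = "dummy", name: str = "x") -> tuple[np.ndarray, list[str]]:
    """Expand a nominal column into binary indicator columns.

    ``one-hot`` produces ``k`` columns with exactly one 1 per row; ``dummy``
    drops the indicator of the reference category (category 0), producing
    ``k - 1`` columns with an all-zero row for the reference.

    Returns the ``n x (k or k-1)`` matrix and the column names
    ``"<name>=<label>"``.
    """
    if var.k < 2:
        raise ValueError("dummy coding needs at least two categories")
    if scheme not in ("dummy", "one-hot"):
        raise ValueError(f"unknown scheme {scheme!r}")
    eye = np.eye(var.k, dtype=np.float64)
    X = eye[var.codes]
    names = [f"{name}={lab}" for lab in var.labels]
    if scheme == "dummy":
        X = X[:, 1:]
        names = names[1:]
    return X, names


def apply_ordering(var: NominalVar, ordering: CategoryOrdering) -> np.ndarray:
    """Recode categories to their ordinal rank under ``ordering``.

    The resulting column is treated as ordered, with ``k - 1`` candidate
    thresholds between adjacent ranks.
    """
    if ordering.k != var.k:
        raise ValueError("ordering does not cover all categories")
    return ordering.rank[var.codes]
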