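"""Core analytic-hierarchy-process (AHP) mathematics.

The AHP derives priority weights for a set of items from a square positive
reciprocal *judgment matrix* ``A = (a_ij)`` whose entry ``a_ij`` states, on
Saaty's 1-9 ratio scale, how strongly item *i* is preferred over item *j*.
This module provides:

* :class:`JudgmentMatrix` -- validated container for such matrices;
* :func:`geometric_mean_weights` -- the geometric-mean (logarithmic
  least-squares) prioritization, W_i = (prod_j a_ij)^(1/n) normalized to
  sum 1;
* :func:`lambda_max` -- the maximal-eigenvalue estimate used in the
  consistency diagnostics, either as the row-ratio average
  (1/n) * sum_i (A w)_i / w_i or as the principal eigenvalue by power
  iteration;
* :func:`consistency_index` / :func:`consistency_ratio` -- CI = (lambda_max
  - n)/(n - 1) and CR = CI/RI with Saaty's tabulated random index RI;
  judgments are conventionally acceptable when CR < 0.1;
* :func:`synthesize` -- hierarchical synthesis of per-criterion alternative
  weights into overall priorities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RANDOM_INDEX",
    "CR_THRESHOLD",
    "SAATY_VALUES",
    "JudgmentMatrix",
    "PriorityVector",
    "ConsistencyReport",
    "HierarchyResult",
    "geometric_mean_weights",
    "lambda_max",
    "consistency_index",
    "consistency_ratio",
    "consistency_report",
    "synthesize",
]

#: Saaty's average random index RI(n) for matrix orders 1..10.  A random
#: reciprocal matrix of order n has expected consistency index RI(n); the
#: consistency ratio normalizes an observed CI by this baseline.
RANDOM_INDEX: dict[int, float] = {
    1: 0.00, 2: 0.00, 3: 0.58, 4: 0.90, 5: 1.12,
    6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49,
}

#: Conventional acceptability threshold for the consistency ratio.
CR_THRESHOLD: float = 0.1

#: Admissible quantized comparison values: the 9-point scale and reciprocals.
SAATY_VALUES: tuple[float, ...] = tuple(
    sorted({float(k) for k in range(1, 10)} | {1.0 / k for k in range(2, 10)})
)

_RECIPROCITY_RTOL = 1e-9


class JudgmentMatrix:
    """Square positive reciprocal pairwise-comparison matrix.

    Parameters
    ----------
    entries : array-like of shape (n, n)
        Comparison values; ``entries[i][j]`` is the preference ratio of item
        *i* over item *j*.  Must be strictly positive, have unit diagonal and
        satisfy ``entries[j][i] == 1/entries[i][j]`` to relative tolerance
        1e-9.
    labels : sequence of str, optional
        Item names; defaults to ``item0 .. item{n-1}``.
    """

    def __init__(self, entries, labels: Sequence[str] | None = None):
        A = np.asarray(entries, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"judgment matrix must be square, got shape {A.shape}")
        n = A.shape[0]
        if n < 2:
            raise ValueError("judgment matrix needs at least 2 items")
        if not np.all(np.isfinite(A)):
            i, j = np.argwhere(~np.isfinite(A))[0]
            raise ValueError(f"non-finite entry at ({i}, {j})")
        if np.any(A <= 0):
            i, j = np.argwhere(A <= 0)[0]
            raise ValueError(
                f"entry ({i}, {j}) = {A[i, j]} is not strictly positive"
            )
        bad_diag = np.nonzero(np.abs(np.diag(A) - 1.0) > _RECIPROCITY_RTOL)[0]
        if bad_diag.size:
            i = int(bad_diag[0])
            raise ValueError(f"diagonal entry ({i}, {i}) = {A[i, i]} != 1")
        resid = np.abs(A * A.T - 1.0)
        if np.any(resid > _RECIPROCITY_RTOL * np.maximum(1.0, np.abs(A * A.T))):
            i, j = np.argwhere(resid > _RECIPROCITY_RTOL)[0]
            raise ValueError(
                f"reciprocity violated at ({i}, {j}): "
                f"a_ij={A[i, j]!r}, a_ji={A[j, i]!r}"
            )
        if labels is None:
            labels = [f"item{i}" for i in range(n)]
        elif len(labels) != n:
            raise ValueError(f"{len(labels)} labels for a {n}x{n} matrix")
        self.entries = A
        self.labels = [str(x) for x in labels]

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    def __getitem__(self, key):
        return self.entries[key]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"JudgmentMatrix(n={self.n}, labels={self.labels})"

    def permuted(self, order: Sequence[int]) -> "JudgmentMatrix":
        """Return the matrix with rows/columns reordered by ``order``."""
        order = list(order)
        A = self.entries[np.ix_(order, order)]
        return JudgmentMatrix(A, [self.labels[i] for i in order])


@dataclass
class PriorityVector:
    """Normalized nonnegative weights over labelled items."""

    weights: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise ValueError("weights must be one-dimensional")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {self.weights.sum()}, expected 1")
        if not self.labels:
            self.labels = [f"item{i}" for i in range(len(self.weights))]
        if len(self.labels) != len(self.weights):
            raise ValueError("labels and weights length mismatch")

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.weights, dtype=dtype)

    def __len__(self) -> int:
        return len(self.weights)


@dataclass
class ConsistencyReport:
    """Consistency diagnostics for one judgment matrix."""

    lambda_max: float
    ci: float
    ri: float
    cr: float
    acceptable: bool

    def to_json(self) -> str:
        return json.dumps(
            {
                "lambda_max": self.lambda_max,
                "ci": self.ci,
                "ri": self.ri,
                "cr": self.cr,
                "acceptable": self.acceptable,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "ConsistencyReport":
        return cls(**json.loads(s))


@dataclass
class HierarchyResult:
    """Synthesis of criteria weights and per-criterion alternative weights."""

    criteria_weights: PriorityVector
    alternative_weights: list[PriorityVector]
    overall: np.ndarray
    best_index: int
    tie: bool = False

    @property
    def best_label(self) -> str:
        return self.alternative_weights[0].labels[self.best_index]


def _as_matrix(matrix) -> JudgmentMatrix:
    return matrix if isinstance(matrix, JudgmentMatrix) else JudgmentMatrix(matrix)


def geometric_mean_weights(matrix) -> PriorityVector:
    """Geometric-mean priority weights of a judgment matrix.

    W_i = (prod_j a_ij)^(1/n) / sum_i (prod_j a_ij)^(1/n), computed in log
    space so that extreme comparison products neither overflow nor
    underflow.  For a perfectly consistent matrix (a_ij = w_i / w_j) this
    recovers ``w`` exactly.
    """
    m = _as_matrix(matrix)
    logg = np.log(m.entries).mean(axis=1)
    logg -= logg.max()  # stabilize the exponential
    g = np.exp(logg)
    return PriorityVector(g / g.sum(), list(m.labels))


def lambda_max(matrix, weights=None, method: str = "row_ratio",
               rtol: float = 1e-10, maxiter: int = 10_000) -> float:
    """Maximal-eigenvalue estimate of a judgment matrix.

    ``method="row_ratio"`` (default) returns the row-ratio average
    (1/n) * sum_i (A w)_i / w_i evaluated at ``weights`` (the geometric-mean
    weights if not given).  ``method="eigen"`` returns the principal
    eigenvalue by power iteration to relative tolerance ``rtol``.  Both are
    >= n for valid reciprocal matrices (up to roundoff).
    """
    m = _as_matrix(matrix)
    if method == "eigen":
        A = m.entries
        v = np.full(m.n, 1.0 / m.n)
        lam = 0.0
        for _ in range(maxiter):
            Av = A @ v
            new_lam = float(Av @ v) / float(v @ v)
            v = Av / np.linalg.norm(Av)
            if abs(new_lam - lam) <= rtol * abs(new_lam):
                return new_lam
            lam = new_lam
        return lam  # pragma: no cover - convergence is immediate in practice
    if method != "row_ratio":
        raise ValueError(f"unknown lambda_max method {method!r}")
    if weights is None:
        weights = geometric_mean_weights(m)
    w = np.asarray(weights, dtype=float)
    if w.shape != (m.n,):
        raise ValueError(f"weights shape {w.shape} incompatible with n={m.n}")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive for the row-ratio estimate")
    return float(((m.entries @ w) / w).mean())


def consistency_index(lam: float, n: int) -> float:
    """CI = (lambda_max - n) / (n - 1); tiny rounding deficits clamp to 0."""
    if n < 2:
        raise ValueError("consistency index requires n >= 2")
    ci = (lam - n) / (n - 1)
    if ci < 0:
        if ci < -1e-6:
            raise ValueError(f"lambda_max={lam} is below n={n}")
        ci = 0.0
    return ci


def consistency_ratio(ci: float, n: int,
                      ri_table: dict[int, float] | None = None,
                      threshold: float = CR_THRESHOLD) -> ConsistencyReport:
    """CR = CI / RI(n) with the tabulated random index.

    For n in {1, 2} a reciprocal matrix is always consistent (RI = 0 makes
    the ratio undefined), so CI and CR are reported as 0 and the verdict is
    acceptable.  n outside the RI table's domain (n > 10) is an error.
    """
    ri_table = RANDOM_INDEX if ri_table is None else ri_table
    if n not in ri_table:
        raise ValueError(f"random index undefined for n={n} (table covers {sorted(ri_table)})")
    ri = ri_table[n]
    if n <= 2:
        ci = 0.0
        cr = 0.0
    else:
        cr = ci / ri
    lam = ci * (n - 1) + n
    return ConsistencyReport(lambda_max=lam, ci=ci, ri=ri, cr=cr,
                             acceptable=cr < threshold)


def consistency_report(matrix, weights=None, method: str = "row_ratio",
                       ri_table: dict[int, float] | None = None,
                       threshold: float = CR_THRESHOLD) -> ConsistencyReport:
    """Full lambda_max -> CI -> CR chain for one judgment matrix."""
    m = _as_matrix(matrix)
    lam = lambda_max(m, weights, method=method)
    if m.n <= 2:
        ri = (RANDOM_INDEX if ri_table is None else ri_table).get(m.n, 0.0)
        return ConsistencyReport(lambda_max=lam, ci=0.0, ri=ri, cr=0.0,
                                 acceptable=True)
    ci = consistency_index(lam, m.n)
    rep = consistency_ratio(ci, m.n, ri_table, threshold)
    rep.lambda_max = lam  # keep the unrounded estimate, not the back-computed one
    return rep


def synthesize(criteria: PriorityVector,
               per_criterion: Sequence[PriorityVector]) -> HierarchyResult:
    """Combine per-criterion alternative weights into overall priorities.

    overall_j = sum_c criteria_weights_c * alternative_weights_cj.  All
    per-criterion vectors must share one alternative label set; ties at the
    top break to the lowest index with a warning.
    """
    if len(per_criterion) != len(criteria):
        raise ValueError(
            f"{len(criteria)} criteria weights but {len(per_criterion)} "
            "alternative vectors"
        )
    labels = per_criterion[0].labels
    for k, pv in enumerate(per_criterion):
        if pv.labels != labels:
            raise ValueError(
                f"alternative labels of criterion {criteria.labels[k]!r} "
                f"({pv.labels}) do not match {labels}"
            )
    W = np.column_stack([np.asarray(pv) for pv in per_criterion])
    overall = W @ np.asarray(criteria)
    best = int(np.argmax(overall))
    tie = bool(np.sum(np.isclose(overall, overall[best], rtol=0, atol=1e-12)) > 1)
    if tie:
        warnings.warn(
            f"tie for best alternative; keeping earliest row {labels[best]!r}",
            stacklevel=2,
        )
    return HierarchyResult(
        criteria_weights=criteria,
        alternative_weights=list(per_criterion),
        overall=overall,
        best_index=best,
        tie=tie,
    )
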