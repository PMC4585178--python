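"""Single-factor screen pipeline: measured indices -> AHP ranking.

A *screen table* records, for each tested alternative of one factor
(temperatures, carbon sources, ion species, ...), four measured indices of
biosurfactant production: biomass (OD600), protein concentration (g/L),
surface tension (mN/m) and clear-zone diameter of the oil-displacement
test (cm).  Surface tension is a cost criterion (lower is better); the
other three are benefits.

The pipeline turns the table into one judgment matrix per criterion (by
quantizing pairwise value ratios onto the Saaty scale), builds the criteria
matrix from stated importance ranks, checks every matrix's consistency
ratio, and synthesizes overall weights; the alternative with the highest
overall weight is the screen's optimum.  :func:`composite_response`
additionally collapses the four indices of a designed-experiment run table
into a single signed, weighted score usable as a response variable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .ahp import (
    CR_THRESHOLD,
    ConsistencyReport,
    HierarchyResult,
    JudgmentMatrix,
    PriorityVector,
    consistency_report,
    geometric_mean_weights,
    synthesize,
)

__all__ = [
    "CriterionSpec",
    "DEFAULT_CRITERIA",
    "SCREEN_COLUMNS",
    "ScreenTable",
    "ScreenResult",
    "QUANTIZERS",
    "rank_to_matrix",
    "values_to_matrix",
    "run_screen",
    "composite_response",
    "AHPScreen",
]


@dataclass(frozen=True)
class CriterionSpec:
    """One evaluation criterion: its table column, direction and rank.

    ``direction`` is +1 for a benefit (higher is better) and -1 for a cost;
    ``rank`` is a positive integer importance score where larger means more
    important (the ranks feed :func:`rank_to_matrix`).
    """

    name: str
    column: str
    direction: int = 1
    rank: int = 1

    def __post_init__(self):
        if self.direction not in (-1, 1):
            raise ValueError(f"direction must be +-1, got {self.direction}")
        if self.rank < 1 or self.rank != int(self.rank):
            raise ValueError(f"rank must be a positive integer, got {self.rank}")


#: Default criteria: biomass < protein < surface tension < clear zone in
#: importance; surface tension is the sole cost criterion.
DEFAULT_CRITERIA: tuple[CriterionSpec, ...] = (
    CriterionSpec("biomass", "biomass", +1, 1),
    CriterionSpec("protein", "protein_g_per_L", +1, 2),
    CriterionSpec("surface_tension", "surface_tension_mN_per_m", -1, 3),
    CriterionSpec("clear_zone", "clear_zone_cm", +1, 4),
)

SCREEN_COLUMNS = [
    "label",
    "biomass",
    "protein_g_per_L",
    "surface_tension_mN_per_m",
    "clear_zone_cm",
]


@dataclass
class ScreenTable:
    """One single-factor screen: alternatives x measured indices."""

    data: pd.DataFrame
    name: str = "screen"
    criteria: tuple[CriterionSpec, ...] = DEFAULT_CRITERIA

    def __post_init__(self):
        df = self.data
        missing = [c for c in SCREEN_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"screen table missing columns {missing}")
        if len(df) < 2:
            raise ValueError("screen table needs at least 2 alternatives")
        if df["label"].duplicated().any():
            dup = df.loc[df["label"].duplicated(), "label"].iloc[0]
            raise ValueError(f"duplicate alternative label {dup!r}")
        vals = df[SCREEN_COLUMNS[1:]].to_numpy(float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite index measurement")
        if np.any(vals < 0):
            raise ValueError("index measurements must be nonnegative")
        st = df["surface_tension_mN_per_m"].to_numpy(float)
        if np.any((st <= 0) | (st > 100)):
            raise ValueError("surface tension must lie in (0, 100] mN/m")
        self.data = df.reset_index(drop=True)

    @property
    def labels(self) -> list[str]:
        return self.data["label"].astype(str).tolist()

    @classmethod
    def from_csv(cls, path, name: str | None = None,
                 criteria: tuple[CriterionSpec, ...] = DEFAULT_CRITERIA) -> "ScreenTable":
        df = pd.read_csv(path)
        return cls(df, name=name or str(path), criteria=criteria)

    def to_csv(self, path) -> None:
        self.data[SCREEN_COLUMNS].to_csv(path, index=False)


@dataclass
class ScreenResult:
    """AHP outcome of one screen, mirroring the layout of the source tables."""

    name: str
    hierarchy: HierarchyResult
    criteria_report: ConsistencyReport
    reports: dict[str, ConsistencyReport]
    consistent: bool
    table: pd.DataFrame = field(repr=False)

    @property
    def best_label(self) -> str:
        return self.hierarchy.best_label

    @property
    def overall(self) -> np.ndarray:
        return self.hierarchy.overall


def _quantize_ceil(r: float) -> int:
    return math.ceil(r)


def _quantize_nearest(r: float) -> int:
    return int(round(r))


def _quantize_log(r: float, r_max: float = 9.0) -> int:
    # logarithmic stretch of [1, r_max] onto the 1..9 scale
    if r <= 1.0:
        return 1
    return int(round(1 + 8 * math.log(r) / math.log(max(r_max, r))))


#: Pluggable ratio -> Saaty-intensity quantizers.  "ceil" is the default:
#: it is the rule that reproduces the published criteria weights
#: (0.10/0.18/0.29/0.43) and criteria CR (0.017) from ranks (1,2,3,4).
QUANTIZERS: dict[str, Callable[[float], int]] = {
    "ceil": _quantize_ceil,
    "nearest": _quantize_nearest,
    "log": _quantize_log,
}


def _resolve_quantizer(q) -> Callable[[float], int]:
    if callable(q):
        return q
    try:
        return QUANTIZERS[q]
    except KeyError:
        raise ValueError(f"unknown quantizer {q!r}; options: {sorted(QUANTIZERS)}")


def rank_to_matrix(ranks: Sequence[int],
                   labels: Sequence[str] | None = None,
                   quantizer="ceil") -> JudgmentMatrix:
    """Judgment matrix from integer importance ranks.

    For ranks s_i >= s_j the comparison is ``quantize(s_i/s_j)`` clipped to
    [1, 9]; reciprocals fill the lower triangle.  Ranks (1, 2, 3, 4) with
    the default ceiling quantizer give the published criteria matrix.
    """
    ranks = np.asarray(list(ranks), dtype=float)
    if ranks.size == 0:
        raise ValueError("empty rank list")
    if np.any(ranks < 1):
        raise ValueError("ranks must be positive integers")
    return values_to_matrix(ranks, direction=+1, labels=labels, quantizer=quantizer)


def values_to_matrix(values: Sequence[float], direction: int = 1,
                     labels: Sequence[str] | None = None,
                     quantizer="ceil") -> JudgmentMatrix:
    """Judgment matrix from measured values of one criterion.

    Effective values are ``v`` for a benefit criterion and ``1/v`` for a
    cost criterion.  For effective values v'_i >= v'_j the comparison is
    ``quantize(v'_i/v'_j)`` clipped to [1, 9].  A zero measurement against a
    positive one is maximal disparity (9); zero against zero is
    indifference (1).
    """
    quant = _resolve_quantizer(quantizer)
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 values")
    if np.any(vals < 0):
        raise ValueError("values must be nonnegative")
    if direction not in (-1, 1):
        raise ValueError(f"direction must be +-1, got {direction}")
    if direction == -1:
        if np.any(vals == 0):
            raise ValueError("cost criterion requires strictly positive values")
        eff = 1.0 / vals
    else:
        if np.all(vals == 0):
            raise ValueError("benefit criterion with all-zero values")
        eff = vals
    n = vals.size
    A = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vi, vj = eff[i], eff[j]
            if vi == 0 and vj == 0:
                a = 1.0
            elif vj == 0:
                a = 9.0
            elif vi == 0:
                a = 1.0 / 9.0
            elif vi >= vj:
                a = float(min(9, max(1, quant(vi / vj))))
            else:
                a = 1.0 / min(9, max(1, quant(vj / vi)))
            A[i, j] = a
            A[j, i] = 1.0 / a
    return JudgmentMatrix(A, labels)


def composite_response(indices, criteria_weights, directions=None,
                       normalization: str = "sum") -> np.ndarray:
    """Collapse per-run index measurements into one weighted signed score.

    ``Y_k = sum_c w_c * sign_c * norm(x)_{c,k}`` where ``norm`` rescales each
    index column across the runs: ``"sum"`` (default) divides by the column
    sum, ``"max"`` by the column maximum, ``"minmax"`` maps onto [0, 1].

    ``indices`` is an (n_runs, n_criteria) array or DataFrame;
    ``directions`` defaults to (+1, +1, -1, +1) for four columns, else all
    benefits.
    """
    X = np.asarray(
        indices.to_numpy() if isinstance(indices, pd.DataFrame) else indices,
        dtype=float,
    )
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D run x criterion array with >= 2 runs")
    w = np.asarray(criteria_weights, dtype=float)
    if w.shape != (X.shape[1],):
        raise ValueError(
            f"{w.size} criteria weights for {X.shape[1]} index columns"
        )
    if directions is None:
        directions = [c.direction for c in DEFAULT_CRITERIA] \
            if X.shape[1] == 4 else [1] * X.shape[1]
    s = np.asarray(directions, dtype=float)
    if normalization == "sum":
        colsum = X.sum(axis=0)
        if np.any(colsum == 0):
            raise ValueError("zero column sum; use max or minmax normalization")
        N = X / colsum
    elif normalization == "max":
        colmax = X.max(axis=0)
        if np.any(colmax == 0):
            raise ValueError("zero column maximum")
        N = X / colmax
    elif normalization == "minmax":
        lo, hi = X.min(axis=0), X.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        N = (X - lo) / span
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return N @ (w * s)


class AHPScreen(BaseEstimator):
    """AHP ranking of the alternatives in a single-factor screen.

    A scikit-learn style estimator: ``fit`` consumes a :class:`ScreenTable`
    (or a DataFrame in the screen-table layout), builds the criteria matrix
    from the configured importance ranks and one judgment matrix per
    criterion from the measured values, runs the consistency diagnostics,
    and synthesizes overall alternative weights.

    Parameters
    ----------
    criteria : sequence of CriterionSpec, optional
        Evaluation criteria; defaults to the four standard indices.
    quantizer : str or callable, default "ceil"
        Ratio quantizer used for all judgment matrices.
    lambda_method : {"row_ratio", "eigen"}, default "row_ratio"
        Maximal-eigenvalue estimator for the consistency chain.
    cr_threshold : float, default 0.1
        Consistency-ratio acceptability threshold.

    Attributes
    ----------
    criteria_weights_ : PriorityVector
        Weights of the criteria toward the goal.
    criteria_report_ : ConsistencyReport
        Consistency of the criteria matrix.
    alternative_weights_ : dict of str -> PriorityVector
        Per-criterion weights of the alternatives.
    reports_ : dict of str -> ConsistencyReport
        Per-criterion consistency diagnostics.
    overall_ : ndarray
        Overall weight of each alternative (sums to 1).
    best_index_, best_label_ : int, str
        The selected optimum.
    consistent_ : bool
        True when every matrix passes CR < ``cr_threshold``.
    result_ : ScreenResult
        Bundled report, including a table mirroring the source layout.
    """

    def __init__(self, criteria=None, quantizer="ceil",
                 lambda_method="row_ratio", cr_threshold=CR_THRESHOLD):
        self.criteria = criteria
        self.quantizer = quantizer
        self.lambda_method = lambda_method
        self.cr_threshold = cr_threshold

    def fit(self, X, y=None):
        table = X if isinstance(X, ScreenTable) else ScreenTable(
            pd.DataFrame(X), criteria=tuple(self.criteria or DEFAULT_CRITERIA))
        criteria = tuple(self.criteria) if self.criteria is not None else table.criteria
        labels = table.labels

        crit_matrix = rank_to_matrix(
            [c.rank for c in criteria], [c.name for c in criteria],
            quantizer=self.quantizer)
        crit_w = geometric_mean_weights(crit_matrix)
        crit_rep = consistency_report(
            crit_matrix, crit_w, method=self.lambda_method,
            threshold=self.cr_threshold)

        alt_w: dict[str, PriorityVector] = {}
        reports: dict[str, ConsistencyReport] = {}
        for c in criteria:
            vals = table.data[c.column].to_numpy(float)
            m = values_to_matrix(vals, c.direction, labels, self.quantizer)
            w = geometric_mean_weights(m)
            alt_w[c.name] = w
            reports[c.name] = consistency_report(
                m, w, method=self.lambda_method, threshold=self.cr_threshold)

        hier = synthesize(crit_w, [alt_w[c.name] for c in criteria])
        consistent = crit_rep.acceptable and all(
            r.acceptable for r in reports.values())
        if not consistent:
            bad = [n for n, r in reports.items() if not r.acceptable]
            if not crit_rep.acceptable:
                bad = ["criteria"] + bad
            warnings.warn(
                f"screen {table.name!r}: CR >= {self.cr_threshold} for {bad}; "
                "ranking reported but flagged inconsistent", stacklevel=2)

        self.criteria_ = criteria
        self.criteria_weights_ = crit_w
        self.criteria_report_ = crit_rep
        self.alternative_weights_ = alt_w
        self.reports_ = reports
        self.overall_ = hier.overall
        self.best_index_ = hier.best_index
        self.best_label_ = labels[hier.best_index]
        self.consistent_ = consistent
        self.result_ = ScreenResult(
            name=table.name, hierarchy=hier, criteria_report=crit_rep,
            reports=reports, consistent=consistent,
            table=self._report_frame(table, criteria, alt_w, reports, hier))
        return self

    def _report_frame(self, table, criteria, alt_w, reports, hier) -> pd.DataFrame:
        # Alternatives block (measurements + overall weight), then the
        # lambda_max / CI / RI / CR diagnostic rows, as in the source tables.
        body = table.data[[c.column for c in criteria]].copy()
        body.columns = [c.name for c in criteria]
        body.insert(0, "label", table.labels)
        body["overall_weight"] = np.round(hier.overall, 4)
        diag = {
            "lambda_max": [reports[c.name].lambda_max for c in criteria],
            "CI": [reports[c.name].ci for c in criteria],
            "RI": [reports[c.name].ri for c in criteria],
            "CR": [reports[c.name].cr for c in criteria],
        }
        rows = []
        for stat, vals in diag.items():
            row = {"label": stat}
            row.update({c.name: round(v, 4) for c, v in zip(criteria, vals)})
            row["overall_weight"] = np.nan
            rows.append(row)
        return pd.concat([body, pd.DataFrame(rows)], ignore_index=True)

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise NotFittedError("AHPScreen is not fitted; call fit first")

    def transform(self, X=None) -> np.ndarray:
        """Overall alternative weights of the fitted screen."""
        self._check_fitted()
        return self.overall_

    def report_frame(self) -> pd.DataFrame:
        self._check_fitted()
        return self.result_.table


def run_screen(table: ScreenTable, **params) -> ScreenResult:
    """Functional wrapper: fit :class:`AHPScreen` and return its result."""
    return AHPScreen(**params).fit(table).result_
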