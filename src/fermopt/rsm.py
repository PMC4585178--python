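"""Central composite designs and quadratic response-surface modelling.

A rotatable central composite design (CCD) for k factors combines 2^k
factorial corners (coded +-1), 2k axial points (+-alpha on one axis) and
replicated center runs.  The response over the design region is modelled by
the full second-order polynomial

    Y = b0 + sum_i b_i x_i + sum_{i<j} b_ij x_i x_j + sum_i b_ii x_i^2

fitted by ordinary least squares.  The module provides the design
generator, a scikit-learn style :class:`ResponseSurfaceRegressor` with the
associated ANOVA (partial sums of squares, lack of fit vs pure error,
R^2 / adjusted R^2 / predicted R^2 via PRESS), and analytic optimum
location on the fitted surface.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize as sciopt
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import NotFittedError

__all__ = [
    "FactorMapping",
    "DEFAULT_FACTORS",
    "CCDDesign",
    "generate_ccd",
    "quadratic_terms",
    "quadratic_design_matrix",
    "QuadraticModel",
    "ResponseSurfaceRegressor",
    "fit_quadratic",
    "anova",
    "stationary_point",
    "constrained_optimum",
    "infer_steps",
    "surface_grid",
]


@dataclass(frozen=True)
class FactorMapping:
    """Linear coded <-> actual-unit mapping for one design factor.

    coded x = (actual - center) / step; ``step`` is the actual-unit width of
    one coded unit and must be positive.
    """

    name: str
    center: float
    step: float

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError(f"step must be positive, got {self.step}")

    def code(self, actual):
        return (np.asarray(actual, float) - self.center) / self.step

    def uncode(self, coded):
        return self.center + self.step * np.asarray(coded, float)


#: Medium composition factors with centers from the response-surface slices
#: (lactose 5, yeast extract 6, NaCl 20 g/L) and steps recovered from the
#: ratio between coded-fit and actual-unit quadratic coefficients.
DEFAULT_FACTORS: tuple[FactorMapping, ...] = (
    FactorMapping("lactose", 5.0, 2.0),
    FactorMapping("yeast_extract", 6.0, 3.0),
    FactorMapping("NaCl", 20.0, 10.0),
)


@dataclass
class CCDDesign:
    """A coded central composite design."""

    k: int
    coded: np.ndarray
    roles: list[str]
    alpha: float
    n_center: int

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coded, columns=[f"x{i+1}" for i in range(self.k)])
        df.insert(0, "run", np.arange(1, self.n_runs + 1))
        df["role"] = self.roles
        return df


def generate_ccd(k: int, alpha: float | None = None, n_center: int = 6,
                 shuffle_seed: int | None = None) -> CCDDesign:
    """Generate a central composite design.

    ``alpha`` defaults to the exact rotatable choice 2^(k/4) (1.68179... for
    k = 3, conventionally printed as 1.682; the published 20-run design has
    6 center replicates).  Runs
    come in canonical order -- factorial block, axial block, centers --
    unless ``shuffle_seed`` requests a seeded random run order.
    """
    if k < 2:
        raise ValueError("need at least 2 factors")
    if n_center < 1:
        raise ValueError("need at least 1 center run")
    if alpha is None:
        alpha = 2 ** (k / 4)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    factorial = np.array(list(itertools.product([-1.0, 1.0], repeat=k)))
    axial = np.zeros((2 * k, k))
    for i in range(k):
        axial[2 * i, i] = -alpha
        axial[2 * i + 1, i] = alpha
    center = np.zeros((n_center, k))
    coded = np.vstack([factorial, axial, center])
    roles = (["factorial"] * len(factorial) + ["axial"] * len(axial)
             + ["center"] * n_center)
    if shuffle_seed is not None:
        order = np.random.default_rng(shuffle_seed).permutation(len(coded))
        coded = coded[order]
        roles = [roles[i] for i in order]
    return CCDDesign(k=k, coded=coded, roles=roles, alpha=float(alpha),
                     n_center=n_center)


def quadratic_terms(k: int) -> list[str]:
    """Term names of the full second-order model, in column order."""
    names = ["intercept"]
    names += [f"x{i+1}" for i in range(k)]
    names += [f"x{i+1}:x{j+1}" for i, j in itertools.combinations(range(k), 2)]
    names += [f"x{i+1}^2" for i in range(k)]
    return names


def quadratic_design_matrix(X) -> np.ndarray:
    """Model matrix [1 | linear | two-way interactions | squares]."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("design must be 2-D (runs x factors)")
    n, k = X.shape
    cols = [np.ones(n)]
    cols += [X[:, i] for i in range(k)]
    cols += [X[:, i] * X[:, j] for i, j in itertools.combinations(range(k), 2)]
    cols += [X[:, i] ** 2 for i in range(k)]
    return np.column_stack(cols)


@dataclass
class QuadraticModel:
    """Second-order polynomial surface in k factors.

    ``coef`` follows the column order of :func:`quadratic_terms`; ``coded``
    flags whether the coefficients act on coded or actual units.
    """

    k: int
    coef: np.ndarray
    coded: bool = True
    factor_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float)
        p = 1 + 2 * self.k + self.k * (self.k - 1) // 2
        if self.coef.shape != (p,):
            raise ValueError(f"expected {p} coefficients for k={self.k}, "
                             f"got {self.coef.shape}")
        if not self.factor_names:
            self.factor_names = [f"x{i+1}" for i in range(self.k)]

    @property
    def terms(self) -> list[str]:
        return quadratic_terms(self.k)

    @property
    def intercept(self) -> float:
        return float(self.coef[0])

    @property
    def linear(self) -> np.ndarray:
        """Gradient at the origin, b."""
        return self.coef[1:1 + self.k]

    @property
    def quadratic(self) -> np.ndarray:
        """Symmetric matrix B with Y = b0 + b'x + x'Bx."""
        k = self.k
        B = np.zeros((k, k))
        pos = 1 + k
        for i, j in itertools.combinations(range(k), 2):
            B[i, j] = B[j, i] = self.coef[pos] / 2.0
            pos += 1
        for i in range(k):
            B[i, i] = self.coef[pos]
            pos += 1
        return B

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.k:
            raise ValueError(f"point dimension {X.shape[1]} != k={self.k}")
        y = quadratic_design_matrix(X) @ self.coef
        return y if y.size > 1 else float(y[0])

    def gradient(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.linear + 2.0 * self.quadratic @ x

    def to_json(self) -> str:
        return json.dumps({
            "k": self.k,
            "terms": self.terms,
            "coef": self.coef.tolist(),
            "coded": self.coded,
            "factor_names": self.factor_names,
        })

    @classmethod
    def from_json(cls, s: str) -> "QuadraticModel":
        d = json.loads(s)
        return cls(k=d["k"], coef=np.asarray(d["coef"]), coded=d["coded"],
                   factor_names=d.get("factor_names") or [])


class ResponseSurfaceRegressor(RegressorMixin, BaseEstimator):
    """Ordinary-least-squares full quadratic response surface.

    ``fit(X, y)`` takes the (runs x factors) design matrix -- coded or
    actual units -- and the response vector, and solves the 10-term (for
    k = 3) second-order model by a QR-based least squares.  The fitted
    estimator exposes the classical designed-experiment diagnostics.

    Attributes
    ----------
    model_ : QuadraticModel
        The fitted surface.
    coef_, intercept_ : ndarray, float
        Model coefficients (scikit-learn convention: ``coef_`` excludes the
        intercept).
    residuals_, hat_diag_ : ndarray
        OLS residuals and leverages h_ii.
    press_ : float
        Leave-one-out prediction error sum of squares,
        sum (e_i / (1 - h_ii))^2.
    r2_, r2_adj_, r2_pred_ : float
        Coefficient of determination, its df-adjusted form, and the
        PRESS-based predicted R^2.
    anova_ : DataFrame
        Partial-SS ANOVA with model, per-term, residual, lack-of-fit,
        pure-error and corrected-total rows (lack of fit only when the
        design contains replicated runs).
    """

    def __init__(self, coded: bool = True):
        self.coded = coded

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D (runs x factors)")
        n, k = X.shape
        if y.shape != (n,):
            raise ValueError(f"{y.size} responses for {n} runs")
        M = quadratic_design_matrix(X)
        p = M.shape[1]
        if n < p + 1:
            raise ValueError(
                f"need more runs than the {p} model terms (got {n})")
        rank = np.linalg.matrix_rank(M)
        if rank < p:
            # name the collinear columns via the QR diagonal
            _, R = np.linalg.qr(M)
            diag = np.abs(np.diag(R))
            bad = [quadratic_terms(k)[i] for i in
                   np.nonzero(diag < 1e-10 * diag.max())[0]]
            raise ValueError(f"rank-deficient design; collinear columns: {bad}")
        coef, *_ = np.linalg.lstsq(M, y, rcond=None)
        fitted = M @ coef
        resid = y - fitted
        # leverages from the thin QR factor
        Q, _ = np.linalg.qr(M)
        h = np.sum(Q * Q, axis=1)

        self.n_features_in_ = k
        self.model_ = QuadraticModel(k=k, coef=coef, coded=self.coded)
        self.intercept_ = float(coef[0])
        self.coef_ = coef[1:]
        self.design_ = X
        self.response_ = y
        self.model_matrix_ = M
        self.fitted_values_ = fitted
        self.residuals_ = resid
        self.hat_diag_ = h
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        self.ss_res_ = ss_res
        self.ss_tot_ = ss_tot
        self.df_res_ = n - p
        one_minus_h = 1.0 - h
        self.press_ = float(((resid / one_minus_h) ** 2).sum())
        self.r2_ = 1.0 - ss_res / ss_tot
        self.r2_adj_ = 1.0 - (ss_res / (n - p)) / (ss_tot / (n - 1))
        self.r2_pred_ = 1.0 - self.press_ / ss_tot
        self.anova_ = self._anova()
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise NotFittedError("ResponseSurfaceRegressor is not fitted")

    def predict(self, X):
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return quadratic_design_matrix(X) @ self.model_.coef

    def _anova(self) -> pd.DataFrame:
        M, y = self.model_matrix_, self.response_
        n, p = M.shape
        k = self.n_features_in_
        terms = quadratic_terms(k)
        ss_res, ss_tot = self.ss_res_, self.ss_tot_
        df_res = self.df_res_
        ms_res = ss_res / df_res
        rows = []
        ss_model = ss_tot - ss_res
        df_model = p - 1

        def fratio(ms):  # an exactly interpolating fit has ms_res == 0
            return ms / ms_res if ms_res > 0 else np.inf

        f_model = fratio(ss_model / df_model)
        rows.append(("model", ss_model, df_model, ss_model / df_model,
                     f_model, stats.f.sf(f_model, df_model, df_res)))
        # partial (drop-one) SS for each non-intercept term
        for j in range(1, p):
            Mj = np.delete(M, j, axis=1)
            cj, *_ = np.linalg.lstsq(Mj, y, rcond=None)
            rj = y - Mj @ cj
            ss_j = float(rj @ rj) - ss_res
            f_j = fratio(ss_j)
            rows.append((terms[j], ss_j, 1, ss_j, f_j,
                         stats.f.sf(f_j, 1, df_res)))
        rows.append(("residual", ss_res, df_res, ms_res, np.nan, np.nan))
        # lack of fit / pure error from exactly-replicated runs
        groups: dict[tuple, list[int]] = {}
        for i, row in enumerate(self.design_):
            groups.setdefault(tuple(row), []).append(i)
        rep_groups = [ix for ix in groups.values() if len(ix) > 1]
        df_pe = sum(len(ix) - 1 for ix in rep_groups)
        if df_pe >= 1:
            ss_pe = sum(
                float(((y[ix] - y[ix].mean()) ** 2).sum()) for ix in rep_groups)
            ss_lof = ss_res - ss_pe
            df_lof = df_res - df_pe
            if df_lof >= 1 and ss_pe > 0:
                ms_lof, ms_pe = ss_lof / df_lof, ss_pe / df_pe
                f_lof = ms_lof / ms_pe
                p_lof = stats.f.sf(f_lof, df_lof, df_pe)
                rows.append(("lack_of_fit", ss_lof, df_lof, ms_lof, f_lof, p_lof))
                rows.append(("pure_error", ss_pe, df_pe, ms_pe, np.nan, np.nan))
            else:
                rows.append(("lack_of_fit", ss_lof, max(df_lof, 0),
                             np.nan, np.nan, np.nan))
                rows.append(("pure_error", ss_pe, df_pe, ss_pe / df_pe,
                             np.nan, np.nan))
        rows.append(("total", ss_tot, n - 1, np.nan, np.nan, np.nan))
        return pd.DataFrame(rows, columns=["source", "SS", "df", "MS", "F", "p"])


def fit_quadratic(design, response, coded: bool = True) -> ResponseSurfaceRegressor:
    """Fit the full second-order model; returns the fitted estimator."""
    return ResponseSurfaceRegressor(coded=coded).fit(design, response)


def anova(fitted: ResponseSurfaceRegressor) -> pd.DataFrame:
    """ANOVA table of a fitted response surface."""
    fitted._check_fitted()
    return fitted.anova_


def _model_of(model) -> QuadraticModel:
    if isinstance(model, ResponseSurfaceRegressor):
        model._check_fitted()
        return model.model_
    return model


def stationary_point(model, frozen: dict[int, float] | None = None):
    """Solve grad Y = 0, optionally with some coordinates frozen.

    Returns ``(point, classification)`` where classification is
    ``"maximum"``, ``"minimum"`` or ``"saddle"`` from the eigenvalue signs
    of the (free-coordinate) Hessian.  A singular Hessian raises, pointing
    to the constrained search instead.
    """
    m = _model_of(model)
    k = m.k
    b, B = m.linear, m.quadratic
    frozen = dict(frozen or {})
    free = [i for i in range(k) if i not in frozen]
    if not free:
        raise ValueError("all coordinates frozen; nothing to solve")
    x = np.zeros(k)
    for i, v in frozen.items():
        x[i] = v
    Bff = B[np.ix_(free, free)]
    cond = np.linalg.cond(Bff)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "singular quadratic part; use constrained_optimum over a bounded "
            "region instead")
    if frozen:
        fz_idx = sorted(frozen)
        fz_val = np.array([frozen[i] for i in fz_idx])
        rhs = -(b[free] + 2.0 * B[np.ix_(free, fz_idx)] @ fz_val)
    else:
        rhs = -b[free]
    x[free] = np.linalg.solve(2.0 * Bff, rhs)
    eig = np.linalg.eigvalsh(Bff)
    if np.all(eig < 0):
        kind = "maximum"
    elif np.all(eig > 0):
        kind = "minimum"
    else:
        kind = "saddle"
    return x, kind


def constrained_optimum(model, bounds=None, grid: int = 101):
    """Maximize the fitted surface over a coded box, deterministically.

    If the unconstrained stationary point is an interior maximum it is
    returned exactly; otherwise a dense ``grid``-per-axis evaluation over
    the box seeds a bounded local polish (L-BFGS-B).  The default box is
    the rotatable design region [-1.682, 1.682]^k.

    Returns ``(point, value)``.
    """
    m = _model_of(model)
    k = m.k
    if bounds is None:
        bounds = [(-1.682, 1.682)] * k
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    if any(hi < lo for lo, hi in bounds):
        raise ValueError("empty bounds")
    try:
        x0, kind = stationary_point(m)
        if kind == "maximum" and all(
                lo <= xi <= hi for xi, (lo, hi) in zip(x0, bounds)):
            return x0, float(m.predict(x0))
    except np.linalg.LinAlgError:
        pass
    axes = [np.linspace(lo, hi, grid) for lo, hi in bounds]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([g.ravel() for g in mesh])
    vals = quadratic_design_matrix(pts) @ m.coef
    best = pts[int(np.argmax(vals))]
    res = sciopt.minimize(
        lambda x: -float(m.predict(x)), best, method="L-BFGS-B",
        bounds=bounds, jac=lambda x: -m.gradient(x))
    x_star = res.x if -res.fun >= vals.max() else best
    return x_star, float(m.predict(x_star))


def infer_steps(coded_model, actual_model) -> np.ndarray:
    """Estimate the per-factor coded-unit step sizes.

    Uses the invariance of the quadratic model space under affine recoding:
    the pure quadratic coefficient in coded units is the actual-unit one
    times step^2, so step_i = sqrt(b_coded_ii / b_actual_ii).
    """
    mc, ma = _model_of(coded_model), _model_of(actual_model)
    if mc.k != ma.k:
        raise ValueError("factor count mismatch")
    qc = np.diag(mc.quadratic)
    qa = np.diag(ma.quadratic)
    if np.any(qa == 0):
        raise ValueError("zero actual-unit quadratic coefficient")
    ratio = qc / qa
    if np.any(ratio <= 0):
        raise ValueError("coded and actual quadratic coefficients disagree in sign")
    return np.sqrt(ratio)


def surface_grid(model, i: int, j: int, frozen: dict[int, float],
                 bounds=(-1.682, 1.682), num: int = 41) -> pd.DataFrame:
    """Long-format prediction grid over factors i, j with the rest frozen."""
    m = _model_of(model)
    ax = np.linspace(bounds[0], bounds[1], num)
    gi, gj = np.meshgrid(ax, ax, indexing="ij")
    pts = np.zeros((gi.size, m.k))
    for d, v in frozen.items():
        pts[:, d] = v
    pts[:, i] = gi.ravel()
    pts[:, j] = gj.ravel()
    z = quadratic_design_matrix(pts) @ m.coef
    return pd.DataFrame({
        f"x{i+1}": gi.ravel(), f"x{j+1}": gj.ravel(), "predicted": z})
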