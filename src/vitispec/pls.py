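"""PLS1 regression (NIPALS) with cross-validated component count and
max-|loading| variable selection.

Partial least squares with a single response builds orthogonal score
vectors t_a = X w_a that maximise covariance with y, deflating X (and y)
after each component.  It handles the p >> n, highly collinear geometry
of hyperspectral data where ordinary least squares breaks down.  The
component count is chosen by v-fold cross-validated RMSE (RMSECV,
global minimum, ties toward fewer components).  Variable selection then
takes, per component in order, the variable with the largest absolute
X-loading (the "factor load"); a variable already taken yields its
runner-up, so selections are unique.

The model API follows the endog/exog convention: ``PLS1(y, X).fit(k)``
returns a :class:`PLS1Results` carrying weights, loadings, scores,
explained variances and prediction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import primary_region

__all__ = [
    "PLS1",
    "PLS1Results",
    "SelectedVariable",
    "SelectionResult",
    "fit_pls1",
    "choose_components",
    "select_variables",
]


class PLS1:
    """Single-response partial least squares model (NIPALS).

    Parameters
    ----------
    endog : array-like, shape (n,)
        Response (already scaled as desired; mean-centering is internal).
    exog : array-like or DataFrame, shape (n, p)
        Predictors.  Column names are kept for selection reports.
    var_names : sequence of str, optional
        Predictor names; defaults to DataFrame columns or ``x0..x{p-1}``.
    """

    def __init__(self, endog, exog, var_names=None):
        if isinstance(exog, pd.DataFrame):
            if var_names is None:
                var_names = [str(c) for c in exog.columns]
            exog = exog.to_numpy(float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        self.endog = np.asarray(endog, dtype=float).ravel()
        n, p = self.exog.shape
        if len(self.endog) != n:
            raise ValueError(f"endog has {len(self.endog)} rows, exog has {n}")
        if np.ptp(self.endog) == 0:
            raise ValueError("zero-variance response")
        self.var_names = (list(var_names) if var_names is not None
                          else [f"x{j}" for j in range(p)])
        if len(self.var_names) != p:
            raise ValueError("var_names length must match predictor count")

    @property
    def max_components(self) -> int:
        n, p = self.exog.shape
        return min(n - 1, p)

    def fit(self, n_components: int) -> "PLS1Results":
        n, p = self.exog.shape
        k = int(n_components)
        if not 1 <= k <= self.max_components:
            raise ValueError(
                f"n_components must be in [1, {self.max_components}], got {k}")
        x_mean = self.exog.mean(axis=0)
        y_mean = self.endog.mean()
        Xc = self.exog - x_mean
        yc = self.endog - y_mean
        ss_x = float((Xc ** 2).sum())
        ss_y = float((yc ** 2).sum())

        W = np.zeros((p, k))
        P = np.zeros((p, k))
        T = np.zeros((n, k))
        q = np.zeros(k)
        x_var = np.zeros(k)
        y_var = np.zeros(k)
        actual_k = k
        for a in range(k):
            w = Xc.T @ yc
            norm_w = np.linalg.norm(w)
            if norm_w < 1e-13:  # response fully deflated; stop early
                actual_k = a
                break
            w /= norm_w
            t = Xc @ w
            tt = float(t @ t)
            if tt < 1e-13:
                actual_k = a
                break
            pa = Xc.T @ t / tt
            qa = float(yc @ t) / tt
            Xc -= np.outer(t, pa)
            yc = yc - qa * t
            W[:, a], P[:, a], T[:, a], q[a] = w, pa, t, qa
            x_var[a] = tt * float(pa @ pa)
            y_var[a] = qa * qa * tt
        if actual_k < k:
            W, P, T, q = W[:, :actual_k], P[:, :actual_k], T[:, :actual_k], q[:actual_k]
            x_var, y_var = x_var[:actual_k], y_var[:actual_k]
        return PLS1Results(self, actual_k, W, P, T, q, x_mean, y_mean,
                           x_var / ss_x * 100 if ss_x else x_var,
                           y_var / ss_y * 100 if ss_y else y_var)


@dataclass
class PLS1Results:
    """Fitted PLS1 model: weights, loadings, scores and derived quantities."""

    model: PLS1
    n_components: int
    weights: np.ndarray      # W, (p, k)
    x_loadings: np.ndarray   # P, (p, k)
    scores: np.ndarray       # T, (n, k)
    y_loadings: np.ndarray   # q, (k,)
    x_mean: np.ndarray
    y_mean: float
    explained_x_variance: np.ndarray  # % per component
    explained_y_variance: np.ndarray  # % per component

    @property
    def coef(self) -> np.ndarray:
        """Regression coefficients on the input scale: b = W (P'W)^-1 q."""
        W, P, q = self.weights, self.x_loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, q)

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coef)

    def predict(self, exog) -> np.ndarray:
        if isinstance(exog, pd.DataFrame):
            exog = exog.to_numpy(float)
        exog = np.atleast_2d(np.asarray(exog, float))
        return exog @ self.coef + self.intercept

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.exog)

    @property
    def cumulative_x_variance(self) -> float:
        return float(self.explained_x_variance.sum())

    @property
    def cumulative_y_variance(self) -> float:
        return float(self.explained_y_variance.sum())

    def summary(self) -> str:
        lines = [
            "PLS1 (NIPALS) results",
            f"  components: {self.n_components}",
            f"  cumulative X variance: {self.cumulative_x_variance:.1f}%",
            f"  cumulative y variance: {self.cumulative_y_variance:.1f}%",
            "  comp  expl.X%  expl.y%  max-|loading| variable",
        ]
        names = self.model.var_names
        for a in range(self.n_components):
            j = int(np.argmax(np.abs(self.x_loadings[:, a])))
            lines.append(
                f"  {a + 1:4d}  {self.explained_x_variance[a]:7.2f}"
                f"  {self.explained_y_variance[a]:7.2f}  {names[j]}"
            )
        return "\n".join(lines)


def fit_pls1(X, y, n_components: int, var_names=None) -> PLS1Results:
    """Functional wrapper: fit PLS1 with a fixed component count."""
    return PLS1(y, X, var_names=var_names).fit(n_components)


def choose_components(X, y, k_max: int = 10, v_folds: int = 10,
                      seed: int = 0) -> int:
    """Component count minimising v-fold RMSECV over 1..k_max.

    Folds are a seeded shuffle; exact RMSECV ties resolve toward the
    smaller count.  Returns the chosen k.
    """
    from sklearn.model_selection import KFold

    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(float)
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n = len(y)
    if v_folds < 2:
        raise ValueError("v_folds must be >= 2")
    if n < v_folds:
        raise ValueError(f"n={n} smaller than v_folds={v_folds}")
    k_cap = min(k_max, min(n - int(np.ceil(n / v_folds)) - 1, X.shape[1]))
    if k_cap < 1:
        raise ValueError("not enough samples for even one component")

    press = np.zeros(k_cap)
    folds = KFold(n_splits=v_folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in folds.split(X):
        model = PLS1(y[train_idx], X[train_idx])
        cap = min(k_cap, model.max_components)
        for k in range(1, cap + 1):
            res = model.fit(k)
            err = y[test_idx] - res.predict(X[test_idx])
            press[k - 1] += float(err @ err)
        # folds too small for the full range contribute their best fit
        for k in range(cap + 1, k_cap + 1):
            res = model.fit(cap)
            err = y[test_idx] - res.predict(X[test_idx])
            press[k - 1] += float(err @ err)
    rmsecv = np.sqrt(press / n)
    return int(np.argmin(rmsecv)) + 1  # argmin takes the first (smallest k) tie


_WAVELENGTH_NAME = re.compile(r"^R?(\d+(?:\.\d+)?)$")


@dataclass(frozen=True)
class SelectedVariable:
    name: str
    component: int       # 1-based
    loading: float       # signed loading (or weight) value
    region: str | None   # primary spectral region for wavelength variables


@dataclass(frozen=True)
class SelectionResult:
    variables: tuple[SelectedVariable, ...]

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(v) for v in self.variables])


def select_variables(results: PLS1Results, dedupe: bool = True,
                     use: str = "loadings") -> SelectionResult:
    """One variable per component: the max-|factor load| variable.

    ``use`` picks the load matrix: "loadings" (X-loadings P, default) or
    "weights" (W).  With ``dedupe`` a variable already selected by an
    earlier component yields the component's next-highest variable.
    Wavelength-named variables (``R809`` or plain numbers) are annotated
    with their primary spectral region.
    """
    if use == "loadings":
        load = results.x_loadings
    elif use == "weights":
        load = results.weights
    else:
        raise ValueError("use must be 'loadings' or 'weights'")
    names = results.model.var_names
    chosen: list[SelectedVariable] = []
    taken: set[int] = set()
    for a in range(results.n_components):
        order = np.argsort(-np.abs(load[:, a]), kind="stable")
        for j in order:
            if dedupe and int(j) in taken:
                continue
            taken.add(int(j))
            name = names[int(j)]
            m = _WAVELENGTH_NAME.match(name)
            region = None
            if m:
                wl = float(m.group(1))
                if 350 <= wl <= 2500:
                    region = primary_region(wl)
            chosen.append(SelectedVariable(name, a + 1,
                                           float(load[int(j), a]), region))
            break
    return SelectionResult(tuple(chosen))
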