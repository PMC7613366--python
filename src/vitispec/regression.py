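"""Forward-selection multiple linear regression with validity gating,
grid-tuned epsilon-SVR, and R2/RMSE evaluation.

The MLR path mirrors the classical chemometrics workflow: starting from
an intercept-only model, at each step the candidate predictor giving the
largest R2 increase is added if its partial-F p-value clears
``alpha_enter`` (default 0.05).  The fitted model is then gated on three
validity conditions -- Durbin-Watson d in [1.5, 2.5] (no residual
autocorrelation), all variance inflation factors below 10 (no serious
multicollinearity) and overall regression significance p < 0.05.
Models failing a gate are reported with flags, never suppressed.

The SVR path ("regression SVM-type 1", i.e. cost-parameterised
epsilon-SVR) tunes kernel and hyperparameters by v-fold cross-validated
RMSE over a declared grid and refits the winner on the full training
set.

Durbin-Watson uses dataset row order as the observation ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ForwardSelectionMLR",
    "MLRResults",
    "ValidityReport",
    "Metrics",
    "SVRGrid",
    "SVRGridSearch",
    "SVRResults",
    "fit_mlr_forward",
    "durbin_watson",
    "vif",
    "validate_mlr",
    "tune_and_fit_svr",
    "evaluate",
]


def durbin_watson(residuals) -> float:
    """d = sum (e_t - e_{t-1})^2 / sum e_t^2, in observation order.

    Ranges over [0, 4]; ~2 under independent residuals.  All-zero
    residuals give nan with a warning (undefined statistic).
    """
    e = np.asarray(residuals, dtype=float).ravel()
    if len(e) < 3:
        raise ValueError("need at least 3 residuals")
    denom = float(e @ e)
    if denom == 0:
        warnings.warn("all-zero residuals: Durbin-Watson undefined", stacklevel=2)
        return float("nan")
    return float(np.sum(np.diff(e) ** 2) / denom)


def vif(X) -> np.ndarray:
    """Variance inflation factors, VIF_j = 1/(1 - R2_j).

    R2_j regresses predictor j on the remaining predictors (with
    intercept).  Exactly collinear predictors are flagged infinite.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least 2 predictors")
    if n <= p:
        raise ValueError(f"VIF needs n > p (got n={n}, p={p})")
    out = np.empty(p)
    for j in range(p):
        yj = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, _, _, _ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        sst = float(np.sum((yj - yj.mean()) ** 2))
        if sst == 0:
            out[j] = np.inf  # constant predictor
            continue
        r2 = 1.0 - float(resid @ resid) / sst
        out[j] = np.inf if r2 >= 1.0 - 1e-10 else 1.0 / (1.0 - r2)
    return out


@dataclass(frozen=True)
class ValidityReport:
    """Gates for an MLR fit; ``valid`` is the conjunction of the three."""

    dw: float
    dw_ok: bool
    vifs: tuple[float, ...]
    vif_ok: bool
    regression_pvalue: float
    significance_ok: bool

    @property
    def valid(self) -> bool:
        return self.dw_ok and self.vif_ok and self.significance_ok


class ForwardSelectionMLR:
    """Forward stepwise multiple linear regression.

    ``ForwardSelectionMLR(y, X).fit()`` greedily adds, from the
    candidate columns of X, the predictor with the largest R2 increase
    whose partial-F p-value is below ``alpha_enter``, then refits by
    least squares.  ``force_all=True`` skips selection and fits every
    candidate (plain OLS).
    """

    def __init__(self, endog, exog, var_names=None):
        if isinstance(exog, pd.DataFrame):
            if var_names is None:
                var_names = [str(c) for c in exog.columns]
            exog = exog.to_numpy(float)
        self.exog = np.atleast_2d(np.asarray(exog, float))
        self.endog = np.asarray(endog, float).ravel()
        if len(self.endog) != self.exog.shape[0]:
            raise ValueError("endog/exog length mismatch")
        p = self.exog.shape[1]
        self.var_names = (list(var_names) if var_names is not None
                          else [f"x{j}" for j in range(p)])

    def fit(self, alpha_enter: float = 0.05, force_all: bool = False
            ) -> "MLRResults":
        if not 0 < alpha_enter < 1:
            raise ValueError("alpha_enter must be in (0, 1)")
        y = self.endog
        n, p = self.exog.shape
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst == 0:
            raise ValueError("zero-variance response")

        if force_all:
            selected = list(range(p))
        else:
            selected: list[int] = []
            sse_current = sst
            while len(selected) < min(p, n - 2):
                best = None  # (sse_new, j)
                for j in range(p):
                    if j in selected:
                        continue
                    cols = selected + [j]
                    A = np.column_stack([np.ones(n), self.exog[:, cols]])
                    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
                    if rank < A.shape[1]:
                        continue  # candidate collinear with current model
                    resid = y - A @ coef
                    sse_new = float(resid @ resid)
                    if best is None or sse_new < best[0] - 1e-12 * sst:
                        best = (sse_new, j)
                if best is None:
                    break
                sse_new, j = best
                df_resid = n - (len(selected) + 2)  # intercept + new predictor
                if df_resid <= 0:
                    break
                num = max(sse_current - sse_new, 0.0)
                if sse_new <= 0:
                    p_enter = 0.0 if num > 0 else 1.0
                else:
                    F = num / (sse_new / df_resid)
                    p_enter = float(stats.f.sf(F, 1, df_resid))
                if p_enter < alpha_enter:
                    selected.append(j)
                    sse_current = sse_new
                else:
                    break
            if not selected:
                warnings.warn(
                    "no candidate met the entry criterion: intercept-only "
                    "model", stacklevel=2)

        A = np.column_stack([np.ones(n)] +
                            ([self.exog[:, selected]] if selected else []))
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        fitted = A @ coef
        resid = y - fitted
        sse = float(resid @ resid)
        k = len(selected)
        if k > 0 and n - k - 1 > 0 and sse > 0:
            F = ((sst - sse) / k) / (sse / (n - k - 1))
            f_pvalue = float(stats.f.sf(F, k, n - k - 1))
        elif k > 0 and sse == 0:
            f_pvalue = 0.0
        else:
            f_pvalue = float("nan")
        return MLRResults(
            model=self,
            selected=tuple(self.var_names[j] for j in selected),
            selected_idx=tuple(selected),
            intercept=float(coef[0]),
            coefs=tuple(float(c) for c in coef[1:]),
            fittedvalues=fitted,
            resid=resid,
            r_squared=1.0 - sse / sst,
            f_pvalue=f_pvalue,
        )


@dataclass
class MLRResults:
    """A fitted forward-selection MLR model with its diagnostics."""

    model: ForwardSelectionMLR
    selected: tuple[str, ...]
    selected_idx: tuple[int, ...]
    intercept: float
    coefs: tuple[float, ...]
    fittedvalues: np.ndarray
    resid: np.ndarray
    r_squared: float
    f_pvalue: float

    def predict(self, exog) -> np.ndarray:
        if isinstance(exog, pd.DataFrame):
            exog = exog.to_numpy(float)
        exog = np.atleast_2d(np.asarray(exog, float))
        if not self.selected_idx:
            return np.full(exog.shape[0], self.intercept)
        return self.intercept + exog[:, list(self.selected_idx)] @ np.asarray(
            self.coefs)

    @property
    def durbin_watson(self) -> float:
        return durbin_watson(self.resid)

    @property
    def vifs(self) -> np.ndarray:
        if len(self.selected_idx) < 2:
            return np.array([])  # multicollinearity needs >= 2 predictors
        return vif(self.model.exog[:, list(self.selected_idx)])

    def validity(self, dw_band=(1.5, 2.5), vif_limit=10.0,
                 alpha=0.05) -> ValidityReport:
        d = self.durbin_watson
        vifs = self.vifs
        return ValidityReport(
            dw=d,
            dw_ok=bool(np.isfinite(d) and dw_band[0] <= d <= dw_band[1]),
            vifs=tuple(float(v) for v in vifs),
            vif_ok=bool(len(vifs) == 0 or np.all(vifs < vif_limit)),
            regression_pvalue=self.f_pvalue,
            significance_ok=bool(np.isfinite(self.f_pvalue)
                                 and self.f_pvalue < alpha),
        )

    def equation(self, response_name: str = "C") -> str:
        terms = [f"{self.intercept:+.4g}".lstrip("+")]
        for name, c in zip(self.selected, self.coefs):
            sign = "+" if c >= 0 else "-"
            terms.append(f" {sign} ({abs(c):.4g}x{name})")
        return f"{response_name} = " + "".join(terms)

    def summary(self) -> str:
        rep = self.validity()
        lines = [
            "Forward-selection MLR results",
            f"  {self.equation()}",
            f"  R2 (train): {self.r_squared:.4f}",
            f"  Sig. of regression (F-test p): {self.f_pvalue:.4g}"
            f"  [{'ok' if rep.significance_ok else 'FAIL'}]",
            f"  Durbin-Watson: {rep.dw:.3f}"
            f"  [{'ok' if rep.dw_ok else 'FAIL'}]",
        ]
        if len(rep.vifs):
            vmax = max(rep.vifs)
            lines.append(f"  VIF max: {vmax:.2f}"
                         f"  [{'ok' if rep.vif_ok else 'FAIL'}]")
        else:
            lines.append("  VIF: n/a (fewer than 2 predictors)")
        lines.append(f"  valid: {rep.valid}")
        return "\n".join(lines)


def fit_mlr_forward(X, y, alpha_enter: float = 0.05,
                    var_names=None) -> MLRResults:
    """Functional wrapper over :class:`ForwardSelectionMLR`."""
    return ForwardSelectionMLR(y, X, var_names=var_names).fit(alpha_enter)


def validate_mlr(results: MLRResults, **kwargs) -> ValidityReport:
    return results.validity(**kwargs)


@dataclass(frozen=True)
class SVRGrid:
    """Hyperparameter grid for epsilon-SVR tuning.

    The defaults cover the four standard kernels with cost/epsilon
    {0.1, 1, 10, 100} x {0.01, 0.1}, gamma up to 1, polynomial degree up
    to 11 and kernel coefficient (coef0) in {0, 1}.
    """

    kernels: tuple[str, ...] = ("linear", "rbf", "poly", "sigmoid")
    cost: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    epsilon: tuple[float, ...] = (0.01, 0.1)
    gamma: tuple[float, ...] = (0.05, 0.1, 0.25, 0.5, 1.0)
    degree: tuple[int, ...] = tuple(range(2, 12))
    coef0: tuple[float, ...] = (0.0, 1.0)

    def configurations(self):
        for kernel in self.kernels:
            if kernel == "linear":
                axes = [self.cost, self.epsilon, [None], [None], [None]]
            elif kernel == "rbf":
                axes = [self.cost, self.epsilon, self.gamma, [None], [None]]
            elif kernel == "sigmoid":
                axes = [self.cost, self.epsilon, self.gamma, [None], self.coef0]
            elif kernel == "poly":
                axes = [self.cost, self.epsilon, self.gamma, self.degree,
                        self.coef0]
            else:
                raise ValueError(f"unknown kernel {kernel!r}")
            for c, eps, g, d, c0 in product(*axes):
                yield {"kernel": kernel, "C": c, "epsilon": eps, "gamma": g,
                       "degree": d, "coef0": c0}


FAST_SVR_GRID = SVRGrid(kernels=("linear", "rbf"), cost=(1.0, 10.0, 100.0),
                        epsilon=(0.01, 0.1), gamma=(0.05, 0.25, 1.0))


class SVRGridSearch:
    """epsilon-SVR with kernel/hyperparameter tuning by v-fold CV RMSE."""

    def __init__(self, endog, exog, grid: SVRGrid | None = None):
        if isinstance(exog, pd.DataFrame):
            exog = exog.to_numpy(float)
        self.exog = np.atleast_2d(np.asarray(exog, float))
        self.endog = np.asarray(endog, float).ravel()
        self.grid = grid or SVRGrid()

    def fit(self, v_folds: int = 10, seed: int = 0) -> "SVRResults":
        from sklearn.model_selection import KFold
        from sklearn.svm import SVR

        configs = list(self.grid.configurations())
        if not configs:
            raise ValueError("empty hyperparameter grid")
        n = len(self.endog)
        v = min(v_folds, n)
        folds = list(KFold(n_splits=v, shuffle=True,
                           random_state=seed).split(self.exog))
        best = None  # (cv_rmse, order, config)
        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning
            warnings.simplefilter("ignore", ConvergenceWarning)
            for order, cfg in enumerate(configs):
                sq_sum = 0.0
                for train_idx, test_idx in folds:
                    est = _make_svr(SVR, cfg)
                    est.fit(self.exog[train_idx], self.endog[train_idx])
                    err = self.endog[test_idx] - est.predict(self.exog[test_idx])
                    sq_sum += float(err @ err)
                cv_rmse = np.sqrt(sq_sum / n)
                if best is None or cv_rmse < best[0]:  # ties keep grid order
                    best = (cv_rmse, order, cfg)
            cv_rmse, _, cfg = best
            final = _make_svr(SVR, cfg)
            final.fit(self.exog, self.endog)
        return SVRResults(self, cfg, float(cv_rmse), final)


def _make_svr(SVR, cfg):
    # libsvm's default max_iter=-1 can stall on ill-conditioned
    # poly/sigmoid configurations; a generous bound keeps the grid search
    # finite without affecting well-behaved fits
    kw = {"kernel": cfg["kernel"], "C": cfg["C"], "epsilon": cfg["epsilon"],
          "max_iter": 200_000}
    if cfg["gamma"] is not None:
        kw["gamma"] = cfg["gamma"]
    if cfg["degree"] is not None:
        kw["degree"] = cfg["degree"]
    if cfg["coef0"] is not None:
        kw["coef0"] = cfg["coef0"]
    return SVR(**kw)


@dataclass
class SVRResults:
    """The winning SVR configuration, refitted on the full training set."""

    model: SVRGridSearch
    config: dict
    cv_rmse: float
    estimator: object

    @property
    def kernel(self) -> str:
        return self.config["kernel"]

    @property
    def n_support(self) -> int:
        return int(np.sum(self.estimator.n_support_)) \
            if hasattr(self.estimator, "n_support_") \
            else len(self.estimator.support_)

    def predict(self, exog) -> np.ndarray:
        if isinstance(exog, pd.DataFrame):
            exog = exog.to_numpy(float)
        return self.estimator.predict(np.atleast_2d(np.asarray(exog, float)))

    def summary(self) -> str:
        c = self.config
        return "\n".join([
            "epsilon-SVR grid-search results",
            f"  kernel: {c['kernel']}  (CV RMSE {self.cv_rmse:.4f})",
            f"  cost C: {c['C']}, epsilon: {c['epsilon']}, "
            f"gamma: {c['gamma']}, degree: {c['degree']}, coef0: {c['coef0']}",
            f"  support vectors: {self.n_support}",
        ])


def tune_and_fit_svr(X_train, y_train, grid: SVRGrid | None = None,
                     v_folds: int = 10, seed: int = 0) -> SVRResults:
    """Functional wrapper over :class:`SVRGridSearch`."""
    return SVRGridSearch(y_train, X_train, grid=grid).fit(v_folds, seed)


@dataclass(frozen=True)
class Metrics:
    """R2 and RMSE on train and test, RMSE in scaled and original units."""

    r2_train: float
    rmse_train: float
    r2_test: float
    rmse_test: float
    rmse_train_original: float | None = None
    rmse_test_original: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in vars(self).items() if v is not None}


def _r2_rmse(y, yhat):
    y = np.asarray(y, float).ravel()
    yhat = np.asarray(yhat, float).ravel()
    resid = y - yhat
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        warnings.warn("zero-variance observations: R2 undefined", stacklevel=3)
        return float("nan"), rmse
    return 1.0 - float(resid @ resid) / sst, rmse


def evaluate(results, X_train, y_train, X_test, y_test,
             y_scaler=None) -> Metrics:
    """R2 and RMSE for a fitted model on train and test sets.

    ``y_scaler`` is the min-max scaler fitted on the (scaled) response;
    when given, RMSE is also reported in original units by inverting the
    scaling (an exact rescale by the fitted range).
    """
    r2_tr, rmse_tr = _r2_rmse(y_train, results.predict(X_train))
    r2_te, rmse_te = _r2_rmse(y_test, results.predict(X_test))
    orig_tr = orig_te = None
    if y_scaler is not None:
        span = float(np.asarray(y_scaler.range_).ravel()[0])
        orig_tr, orig_te = rmse_tr * span, rmse_te * span
    return Metrics(r2_tr, rmse_tr, r2_te, rmse_te, orig_tr, orig_te)
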