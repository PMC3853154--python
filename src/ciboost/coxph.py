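"""Linear Cox proportional-hazards model fitted by Newton-Raphson.

The PH model takes the hazard as ``lambda(t|x) = lambda_0(t) exp(x' theta)``.
Following Cox, ``theta`` is estimated by minimizing the negative log partial
likelihood

    l(theta) = - sum_{i in E} [ theta' x_i - log sum_{j: t_j >= t_i} e^{theta' x_j} ],

which depends only on the ranking structure of the risk sets, never on the
baseline hazard — so no baseline is estimated here.  Tied event times share
the full risk-set denominator (Breslow's approximation).  There is no
intercept: the partial likelihood is invariant to shifting all linear
predictors.

The fitted model doubles as the initializer of the concordance-index booster
and as the linear baseline it is compared against.  Predictions are returned
on the survival-time orientation, ``score = -x' theta`` (the negative log
relative hazard): larger score, longer predicted survival.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator

from .data import SurvivalDataset, _unpack_target

__all__ = ["CoxPH", "fit_coxph", "neg_log_partial_likelihood", "cox_risk_scores"]


def _risk_structure(time):
    """Sort order and tie-group bookkeeping for risk-set sums.

    Returns (order, first_of_group) where ``order`` sorts times ascending and
    ``first_of_group[k]`` is the first sorted position sharing sorted time k —
    the start of subject k's (inclusive, >=) risk set in sorted order.
    """
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    first = np.searchsorted(t_sorted, t_sorted, side="left")
    return order, t_sorted, first


def _objective_parts(theta, time, status, X, want_derivs=True):
    """Negative log partial likelihood, with gradient and Hessian on request."""
    lp = X @ theta
    order, t_sorted, first = _risk_structure(time)
    elp = np.exp(lp[order])
    # reverse cumulative sums: rcum[k] = sum over sorted positions >= k
    rcum = np.cumsum(elp[::-1])[::-1]
    ev = status[order] == 1
    denom = rcum[first][ev]
    if np.any(denom <= 0) or not np.all(np.isfinite(denom)):
        return np.inf, None, None
    f = float(-(np.sum(lp[order][ev]) - np.sum(np.log(denom))))
    if not want_derivs:
        return f, None, None
    Xs = X[order]
    wX = elp[:, None] * Xs
    rcum_x = np.cumsum(wX[::-1], axis=0)[::-1]
    s1 = rcum_x[first][ev] / denom[:, None]  # risk-set weighted mean of x
    grad = -(Xs[ev] - s1).sum(axis=0)
    outer = wX[:, :, None] * Xs[:, None, :]
    rcum_xx = np.cumsum(outer[::-1], axis=0)[::-1]
    s2 = rcum_xx[first][ev] / denom[:, None, None]
    hess = (s2 - s1[:, :, None] * s1[:, None, :]).sum(axis=0)
    return f, grad, hess


def neg_log_partial_likelihood(theta, data) -> float:
    """Negative log Cox partial likelihood at coefficients ``theta``.

    ``data`` is a SurvivalDataset (or an (X, (time, status)) pair is not
    accepted — build the dataset first).  Risk sets are inclusive
    (``t_j >= t_i``); tied event times share the denominator (Breslow).
    """
    if not isinstance(data, SurvivalDataset):
        raise TypeError("data must be a SurvivalDataset")
    if data.n_events == 0:
        raise ValueError("partial likelihood undefined with zero events")
    theta = np.asarray(theta, dtype=float).ravel()
    if theta.shape[0] != data.n_features:
        raise ValueError(f"{theta.shape[0]} coefficients for {data.n_features} covariates")
    f, _, _ = _objective_parts(theta, data.time, data.status, data.X, want_derivs=False)
    return f


class CoxPH(BaseEstimator):
    """Cox proportional-hazards regression (Breslow ties, no regularization).

    Newton-Raphson with step-halving on the negative log partial likelihood;
    accepted iterations never increase the objective.  A non-identifiable fit
    (all-constant covariates, or divergence from quasi-separation) is flagged
    through ``converged_ = False`` rather than raising.

    Attributes
    ----------
    coef_ : ndarray of shape (p,)
    converged_ : bool
    n_iter_ : int
    final_objective_ : float
    objective_path_ : list of float
        Objective at theta = 0 followed by each accepted iterate;
        non-increasing by construction.
    """

    def __init__(self, max_iter: int = 50, tol: float = 1e-8):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        time, status = _unpack_target(y)
        if X.shape[1] < 1:
            raise ValueError("need at least one covariate")
        if status.sum() == 0:
            raise ValueError("cannot fit with zero observed events")
        self.n_features_in_ = X.shape[1]

        informative = np.ptp(X, axis=0) > 0
        if not np.any(informative):
            warnings.warn("all covariates constant: Cox model is non-identifiable")
            self.coef_ = np.zeros(X.shape[1])
            self.converged_ = False
            self.n_iter_ = 0
            self.final_objective_ = _objective_parts(
                self.coef_, time, status, X, want_derivs=False
            )[0]
            self.objective_path_ = [self.final_objective_]
            return self

        theta = np.zeros(X.shape[1])
        f, grad, hess = _objective_parts(theta, time, status, X)
        path = [f]
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(hess, grad, rcond=None)[0]
            if not np.all(np.isfinite(step)):
                break
            # step-halving: accept only a strict decrease
            t, accepted = 1.0, False
            for _ in range(40):
                cand = theta - t * step
                f_new, g_new, h_new = _objective_parts(cand, time, status, X)
                if np.isfinite(f_new) and f_new < f:
                    accepted = True
                    break
                t *= 0.5
            if not accepted:
                converged = bool(np.linalg.norm(grad) < 1e-6)
                break
            delta = f - f_new
            theta, f, grad, hess = cand, f_new, g_new, h_new
            path.append(f)
            if delta < self.tol:
                converged = True
                break
        if not np.all(np.isfinite(theta)) or np.linalg.norm(theta) > 1e6:
            warnings.warn("Cox fit diverged (possible separation); flagged non-converged")
            converged = False
        self.coef_ = theta
        self.converged_ = converged
        self.n_iter_ = it
        self.final_objective_ = f
        self.objective_path_ = path
        return self

    def predict(self, X) -> np.ndarray:
        """Survival-time-oriented scores: the negative linear predictor."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model was fitted with {self.n_features_in_}"
            )
        return -(X @ self.coef_)


def fit_coxph(data: SurvivalDataset, max_iter: int = 50, tol: float = 1e-8) -> CoxPH:
    """Fit the linear PH baseline on a cohort."""
    return CoxPH(max_iter=max_iter, tol=tol).fit(data.X, data.y)


def cox_risk_scores(model: CoxPH, X) -> np.ndarray:
    """Scores ``-x' theta`` of a fitted model (larger = longer survival)."""
    return model.predict(X)
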