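"""Gradient boosting of regression trees for survival ranking.

Two objectives share one stage-wise loop:

* ``objective="sci"`` — concordance-index learning (GBMCI).  The ensemble
  ``F_m = f_0 + nu * sum_{k<=m} rho_k f_k`` is grown to *maximize* the
  smoothed concordance index.  ``f_0`` is the prediction of a linear Cox PH
  model fitted to the training data (negative log relative hazard); each
  stage fits a depth-limited least-squares tree to the exact SCI gradient
  and the stage weight ``rho_m`` is found by bounded line search on
  ``[0, rho_max]``.  Because ``rho = 0`` is always a candidate and the line
  search is evaluated on the full training sample, the full-data training
  SCI never decreases when no subsampling is used; the bounded search range
  also acts as implicit shrinkage, which is why the default learning rate
  is 1.
* ``objective="coxph"`` — boosted Cox partial likelihood (GBMCOX).  Stages
  fit trees to the negative gradient of the negative log partial likelihood,
  each terminal node is refitted with a single Newton step restricted to its
  subjects, the stage weight is fixed to 1, and a small learning rate
  (default 0.002) does the regularizing.

With ``subsample < 1`` each stage's pseudo-responses are computed on (and
the tree is fitted to) a fresh random subset drawn without replacement —
stochastic gradient boosting; the SCI line search still uses the full
sample.  The number of stages actually used at prediction time is selected
by seeded k-fold cross-validation on held-out concordance.

Internally, "sci" models keep scores on the survival-time orientation while
"coxph" models keep the log relative hazard; :meth:`predict` always returns
survival-time-oriented scores (larger = predicted to survive longer).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold

from ._kernels import grid_scan, sci_at
from .concordance import concordance_index, sci_gradient
from .coxph import CoxPH, _risk_structure
from .data import SurvivalDataset, _unpack_target, comparable_pairs
from .tree import RegressionTree

__all__ = [
    "SurvivalGradientBoosting",
    "fit_gbmci",
    "fit_gbmcox",
    "line_search_rho",
    "select_stages_cv",
    "coxph_negative_gradient",
    "predict",
]

_FINAL_FIT_KEY = 0
_CV_FOLD_KEY = 1


# ---------------------------------------------------------------------------
# line search
# ---------------------------------------------------------------------------

def _pair_diffs(values, pairs, alpha):
    return alpha * (values[pairs.j_idx] - values[pairs.i_idx])


def _sci_of_diffs(d):
    return float(np.mean(expit(d)))


def _line_search_diffs(d, e, rho_max, grid_size):
    """Maximize mean(expit(d + rho*e)) over rho in [0, rho_max].

    Coarse uniform grid (0 always included) followed by bounded scalar
    refinement inside the best grid cell.  Returns (rho, value) with
    value >= value at rho = 0 guaranteed.
    """
    if not np.any(e):
        return 0.0, _sci_of_diffs(d)
    grid = np.linspace(0.0, rho_max, grid_size)
    vals = grid_scan(d, e, grid)
    # ties at the max: keep no-move if it ties, else take the largest rho
    # (a saturated, numerically flat objective resolves to the boundary)
    k = grid_size - 1 - int(np.argmax(vals[::-1]))
    if vals[0] == vals[k]:
        k = 0
    best_rho, best_val = float(grid[k]), float(vals[k])
    a, b = grid[max(k - 1, 0)], grid[min(k + 1, grid_size - 1)]
    if b > a:
        res = minimize_scalar(
            lambda r: -sci_at(d, e, r),
            bounds=(a, b),
            method="bounded",
            options={"xatol": 1e-12},
        )
        if np.isfinite(res.x) and -res.fun > best_val:
            best_rho, best_val = float(res.x), float(-res.fun)
    return best_rho, best_val


def line_search_rho(scores, tree_preds, data, alpha: float = 1.0,
                    rho_range=(0.0, 100.0), *, pairs=None, grid_size: int = 201):
    """Stage-weight search: rho maximizing SCI(scores + rho * tree_preds).

    ``rho_range`` must start at 0 so the no-move option is always a
    candidate, making the returned SCI at least the current one.
    Returns ``(rho, sci_at_rho)``.
    """
    lo, hi = rho_range
    if lo != 0.0:
        raise ValueError("rho_range must start at 0")
    if hi <= lo:
        raise ValueError(f"empty rho_range {rho_range}")
    if pairs is None:
        pairs = comparable_pairs(data)
    if pairs.size == 0:
        raise ValueError("no comparable pairs")
    scores = np.asarray(scores, dtype=float).ravel()
    tree_preds = np.asarray(tree_preds, dtype=float).ravel()
    d = _pair_diffs(scores, pairs, alpha)
    e = _pair_diffs(tree_preds, pairs, alpha)
    return _line_search_diffs(d, e, hi, grid_size)


# ---------------------------------------------------------------------------
# boosted-Cox pseudo-responses
# ---------------------------------------------------------------------------

def coxph_negative_gradient(scores, time, status, with_hessian: bool = False):
    """Negative gradient (and diagonal Hessian) of the negative log partial
    likelihood at offset ``scores`` (log relative hazard scale).

    Component i: ``delta_i - e^{F_i} * sum_{k in E: t_k <= t_i} 1 / D_k``
    with ``D_k = sum_{j: t_j >= t_k} e^{F_j}``; the diagonal Hessian entry is
    ``e^{F_i} A_i - e^{2 F_i} B_i`` with ``B`` the matching sum of
    ``1 / D_k^2``.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    time = np.asarray(time, dtype=float).ravel()
    status = np.asarray(status).astype(int).ravel()
    if status.sum() == 0:
        raise ValueError("no observed events: partial-likelihood gradient undefined")
    order, t_sorted, first = _risk_structure(time)
    last = np.searchsorted(t_sorted, t_sorted, side="right") - 1
    elp = np.exp(scores[order])
    rcum = np.cumsum(elp[::-1])[::-1]
    ev = status[order] == 1
    inv = np.zeros_like(elp)
    inv[ev] = 1.0 / rcum[first][ev]
    A = np.cumsum(inv)[last]  # sum of 1/D_k over events with t_k <= t_i
    r_sorted = status[order] - elp * A
    r = np.empty_like(r_sorted)
    r[order] = r_sorted
    if not with_hessian:
        return r
    inv2 = np.zeros_like(elp)
    inv2[ev] = inv[ev] ** 2
    B = np.cumsum(inv2)[last]
    h_sorted = elp * A - elp**2 * B
    h = np.empty_like(h_sorted)
    h[order] = h_sorted
    return r, h


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class SurvivalGradientBoosting(BaseEstimator):
    """Tree-ensemble survival model boosted on concordance or partial likelihood.

    Parameters
    ----------
    objective : {"sci", "coxph"}, default "sci"
        "sci" maximizes the smoothed concordance index (GBMCI); "coxph"
        minimizes the negative log Cox partial likelihood (GBMCOX).
    alpha : float, default 1.0
        Sigmoid steepness of the smoothed concordance index ("sci" only).
        1 balances how closely SCI tracks CI against gradient conditioning.
    n_estimators : int, default 1500
        Maximum number of boosting stages.
    max_depth : int, default 6
        Depth of each regression-tree base learner.
    min_samples_leaf : int, default 10
        Minimum subjects per terminal node.
    learning_rate : float or None, default None
        Shrinkage nu in (0, 1]; None resolves per objective (1.0 for "sci",
        whose bounded line search shrinks implicitly; 0.002 for "coxph").
    subsample : float, default 1.0
        Fraction of subjects drawn (without replacement) to fit each stage.
    rho_max : float, default 100.0
        Upper end of the stage-weight line-search interval [0, rho_max]
        ("sci" only; "coxph" stages use weight 1).
    line_search_grid : int, default 201
        Points of the coarse line-search grid before local refinement.
    cv : int, default 5
        Folds for selecting the number of stages used at prediction time by
        held-out concordance; < 2 disables selection (all stages used).
    random_state : int or None
        Seed for subsampling and fold assignment.

    Attributes
    ----------
    init_model_ : CoxPH or None
        The PH initializer ("sci" objective; None if it was non-identifiable
        or for "coxph", which starts from 0).
    stages_ : list of (rho, RegressionTree)
    selected_stages_ : int
    cv_curve_ : ndarray or None
        Fold-averaged held-out concordance after each stage.
    training_log_ : ndarray
        Full-data training objective after each stage (SCI for "sci",
        negative log partial likelihood for "coxph").
    final_train_scores_ : ndarray
        Training-set scores of the full ensemble, survival-time oriented.
    """

    def __init__(self, objective: str = "sci", alpha: float = 1.0,
                 n_estimators: int = 1500, max_depth: int = 6,
                 min_samples_leaf: int = 10, learning_rate: float = None,
                 subsample: float = 1.0, rho_max: float = 100.0,
                 line_search_grid: int = 201, cv: int = 5,
                 random_state: int = None):
        self.objective = objective
        self.alpha = alpha
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.learning_rate = learning_rate
        self.subsample = subsample
        self.rho_max = rho_max
        self.line_search_grid = line_search_grid
        self.cv = cv
        self.random_state = random_state

    # -- validation ----------------------------------------------------------
    def _validate(self):
        if self.objective not in ("sci", "coxph"):
            raise ValueError(f"objective must be 'sci' or 'coxph', got {self.objective!r}")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.n_estimators < 0:
            raise ValueError("n_estimators must be >= 0")
        if not (0 < self.subsample <= 1):
            raise ValueError("subsample must be in (0, 1]")
        lr = self.learning_rate
        if lr is not None and not (0 < lr <= 1):
            raise ValueError("learning_rate must be in (0, 1]")
        if self.rho_max <= 0:
            raise ValueError("rho_max must be > 0")

    def _resolved_lr(self) -> float:
        if self.learning_rate is not None:
            return float(self.learning_rate)
        return 1.0 if self.objective == "sci" else 0.002

    def _seed(self) -> int:
        if self.random_state is not None:
            return int(self.random_state)
        if not hasattr(self, "_auto_seed"):
            self._auto_seed = int(np.random.SeedSequence().generate_state(1)[0])
        return self._auto_seed

    # -- fitting -------------------------------------------------------------
    def fit(self, X, y):
        """Fit on covariates ``X`` and structured survival target ``y``
        (fields ``time`` and ``status``, as built by
        :func:`ciboost.data.survival_target`)."""
        self._validate()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        time, status = _unpack_target(y)
        data = SurvivalDataset(time, status, X)
        if data.n_events == 0:
            raise ValueError("cannot boost with zero observed events")
        if comparable_pairs(data).size == 0:
            raise ValueError("no comparable pairs in the training data")
        self.n_features_in_ = X.shape[1]
        self.learning_rate_ = self._resolved_lr()
        seed = self._seed()

        cv_curve = None
        if self.cv >= 2 and self.n_estimators >= 1:
            best_m, cv_curve = self._cv_select(data, seed)
        rng = np.random.default_rng(np.random.SeedSequence([seed, _FINAL_FIT_KEY]))
        loop = self._fit_loop(data, rng)
        self.init_model_ = loop["init_model"]
        self.init_scores_ = loop["init_scores"]
        self.stages_ = loop["stages"]
        self.training_log_ = np.asarray(loop["training_log"])
        self.skipped_stages_ = loop["skipped"]
        self.cv_curve_ = cv_curve
        if cv_curve is not None:
            self.selected_stages_ = min(best_m, len(self.stages_))
        else:
            self.selected_stages_ = len(self.stages_)
        internal = loop["scores"]
        self.final_train_scores_ = internal if self.objective == "sci" else -internal
        return self

    def _fit_init(self, data: SurvivalDataset):
        """Initial score vector (internal orientation) and its model."""
        if self.objective == "coxph":
            return None, np.zeros(data.n_subjects)
        try:
            cox = CoxPH().fit(data.X, data.y)
        except ValueError as err:
            warnings.warn(f"PH initialization failed ({err}); starting from 0")
            return None, np.zeros(data.n_subjects)
        if not cox.converged_:
            warnings.warn("PH initialization non-identifiable; starting from 0")
            return None, np.zeros(data.n_subjects)
        return cox, cox.predict(data.X)

    def _fit_loop(self, data: SurvivalDataset, rng, X_val=None, y_val=None):
        """Run the stage-wise loop; optionally track a held-out CI curve."""
        n = data.n_subjects
        lr = self.learning_rate_
        init_model, scores = self._fit_init(data)
        scores = scores.copy()
        stages, training_log, skipped = [], [], []

        track_val = X_val is not None
        if track_val:
            val_time, val_status = _unpack_target(y_val)
            val_pairs = comparable_pairs((val_time, val_status))
            if init_model is not None:
                val_scores = init_model.predict(X_val)
            else:
                val_scores = np.zeros(X_val.shape[0])
            val_curve = []

        sci_mode = self.objective == "sci"
        if sci_mode:
            pairs = comparable_pairs(data)
            d = _pair_diffs(scores, pairs, self.alpha)
        bag_size = int(math.ceil(self.subsample * n))

        for m in range(self.n_estimators):
            fitted = None
            for attempt in range(2):  # one resample allowed on a degenerate bag
                if bag_size >= n:
                    bag = np.arange(n)
                else:
                    bag = np.sort(rng.choice(n, size=bag_size, replace=False))
                fitted = self._fit_stage(data, scores, bag, sci_mode, pairs if sci_mode else None, d if sci_mode else None)
                if fitted is not None:
                    break
            if fitted is None:
                warnings.warn(f"stage {m}: degenerate bag twice; stage skipped")
                skipped.append(m)
                if sci_mode:
                    training_log.append(_sci_of_diffs(d))
                else:
                    training_log.append(self._coxph_objective(scores, data))
                if track_val:
                    val_curve.append(self._val_ci(val_scores, val_time, val_status, val_pairs))
                continue
            rho, tree, f_all = fitted
            scores += lr * rho * f_all
            stages.append((rho, tree))
            if sci_mode:
                d += _pair_diffs(lr * rho * f_all, pairs, self.alpha)
                training_log.append(_sci_of_diffs(d))
            else:
                training_log.append(self._coxph_objective(scores, data))
            if track_val:
                val_scores += lr * rho * tree.predict(X_val)
                val_curve.append(self._val_ci(val_scores, val_time, val_status, val_pairs))

        if self.n_estimators > 0 and not stages:
            raise RuntimeError("every boosting stage was skipped (degenerate bags)")
        out = {
            "init_model": init_model,
            "init_scores": (init_model.predict(data.X) if init_model is not None
                            else np.zeros(n)),
            "scores": scores,
            "stages": stages,
            "training_log": training_log,
            "skipped": skipped,
        }
        if track_val:
            out["val_curve"] = np.asarray(val_curve)
        return out

    def _fit_stage(self, data, scores, bag, sci_mode, pairs, d):
        """Fit one stage on ``bag``; returns (rho, tree, full-sample preds)
        or None if the bag cannot support a gradient."""
        if sci_mode:
            bag_data = (data.time[bag], data.status[bag])
            bag_pairs = comparable_pairs(bag_data)
            if bag_pairs.size == 0:
                return None
            g = sci_gradient(scores[bag], bag_data, self.alpha, pairs=bag_pairs)
            tree = RegressionTree(self.max_depth, self.min_samples_leaf).fit(data.X[bag], g)
            f_all = tree.predict(data.X)
            e = _pair_diffs(f_all, pairs, self.alpha)
            rho, _ = _line_search_diffs(d, e, self.rho_max, self.line_search_grid)
            return rho, tree, f_all
        # coxph stage
        t_bag, s_bag = data.time[bag], data.status[bag]
        if s_bag.sum() == 0:
            return None
        r, h = coxph_negative_gradient(scores[bag], t_bag, s_bag, with_hessian=True)
        tree = RegressionTree(self.max_depth, self.min_samples_leaf).fit(data.X[bag], r)
        leaf_ids = tree.apply(data.X[bag])
        values = {}
        for leaf in np.unique(leaf_ids):
            in_leaf = leaf_ids == leaf
            den = float(h[in_leaf].sum())
            values[int(leaf)] = float(r[in_leaf].sum() / den) if den >= 1e-12 else 0.0
        tree.set_leaf_values(values)
        return 1.0, tree, tree.predict(data.X)

    @staticmethod
    def _coxph_objective(scores, data: SurvivalDataset) -> float:
        """Negative log partial likelihood of raw scores (no covariates)."""
        order, t_sorted, first = _risk_structure(data.time)
        elp = np.exp(scores[order])
        rcum = np.cumsum(elp[::-1])[::-1]
        ev = data.status[order] == 1
        return float(-(np.sum(scores[order][ev]) - np.sum(np.log(rcum[first][ev]))))

    def _val_ci(self, val_scores, val_time, val_status, val_pairs) -> float:
        oriented = val_scores if self.objective == "sci" else -val_scores
        return concordance_index(oriented, (val_time, val_status), pairs=val_pairs)

    def _cv_select(self, data: SurvivalDataset, seed: int):
        """Seeded k-fold selection of the stage count by held-out concordance."""
        kf = KFold(n_splits=self.cv, shuffle=True, random_state=seed % (2**32 - 1))
        curves = []
        for f, (tr, va) in enumerate(kf.split(data.X)):
            fold_data = data.subset(tr)
            if fold_data.n_events == 0 or comparable_pairs(fold_data).size == 0:
                warnings.warn(f"fold {f}: training part has no comparable pairs; dropped")
                continue
            val_pairs = comparable_pairs((data.time[va], data.status[va]))
            if val_pairs.size == 0:
                warnings.warn(f"fold {f}: no comparable validation pairs; dropped")
                continue
            rng = np.random.default_rng(np.random.SeedSequence([seed, _CV_FOLD_KEY, f]))
            loop = self._fit_loop(fold_data, rng, X_val=data.X[va],
                                  y_val=(data.time[va], data.status[va]))
            curves.append(loop["val_curve"])
        if not curves:
            raise RuntimeError("cross-validation failed: every fold was dropped")
        self.cv_fold_curves_ = np.vstack(curves)
        curve = self.cv_fold_curves_.mean(axis=0)
        best_m = int(np.argmax(curve)) + 1  # first max => smallest m on ties
        return best_m, curve

    # -- prediction ----------------------------------------------------------
    def predict(self, X, n_stages: int = None) -> np.ndarray:
        """Survival-time-oriented scores of the (truncated) ensemble.

        ``n_stages`` defaults to the CV-selected stage count; pass an explicit
        value (<= number of fitted stages) to truncate or extend.
        """
        if not hasattr(self, "stages_"):
            raise RuntimeError("model is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model was fitted with {self.n_features_in_}"
            )
        k = self.selected_stages_ if n_stages is None else int(n_stages)
        if not (0 <= k <= len(self.stages_)):
            raise ValueError(f"n_stages must be in [0, {len(self.stages_)}], got {k}")
        if self.init_model_ is not None:
            s = self.init_model_.predict(X)
        else:
            s = np.zeros(X.shape[0])
        for rho, tree in self.stages_[:k]:
            s += self.learning_rate_ * rho * tree.predict(X)
        return s if self.objective == "sci" else -s


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_gbmci(data: SurvivalDataset, **params) -> SurvivalGradientBoosting:
    """Fit the concordance-index booster (GBMCI) on a cohort."""
    if params.setdefault("objective", "sci") != "sci":
        raise ValueError(f"fit_gbmci requires objective='sci', got {params['objective']!r}")
    return SurvivalGradientBoosting(**params).fit(data.X, data.y)


def fit_gbmcox(data: SurvivalDataset, **params) -> SurvivalGradientBoosting:
    """Fit the boosted Cox partial-likelihood model (GBMCOX) on a cohort."""
    if params.setdefault("objective", "coxph") != "coxph":
        raise ValueError(
            f"fit_gbmcox requires objective='coxph', got {params['objective']!r}"
        )
    return SurvivalGradientBoosting(**params).fit(data.X, data.y)


def select_stages_cv(data: SurvivalDataset, **params):
    """Standalone seeded CV curve: returns (best_m, fold-averaged CI curve)."""
    est = SurvivalGradientBoosting(**params)
    est._validate()
    if est.cv < 2:
        raise ValueError("select_stages_cv needs cv >= 2")
    est.learning_rate_ = est._resolved_lr()
    return est._cv_select(data, est._seed())


def predict(model: SurvivalGradientBoosting, X, n_stages: int = None) -> np.ndarray:
    return model.predict(X, n_stages=n_stages)
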