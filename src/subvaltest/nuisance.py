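"""Nuisance-function estimation, frozen per history.

The value-difference scores need, at each step of the sequential test, a set
of *fixed* functions estimated from the historical data only:

* the propensity ``pi(x) = pr(A=1 | X=x)`` (known constant or logistic fit);
* the control conditional mean ``C0(x)`` and the CATE ``tau(x)`` — on the
  outcome scale for uncensored data, on the RMST scale for survival data;
* for survival data additionally the conditional survival curve
  ``S(t | x, a)``, the censoring survival ``Kc(t | x, a)`` with its cumulative
  hazard ``Lambda_c`` (Cox model with Breslow baseline on the censoring
  times), the conditional residual RMST ``m(r | x, a) = E[min(T, L) | T >= r,
  x, a]``, and the censoring-martingale augmentation integral.

Everything here is estimated by off-the-shelf learners (logistic regression,
arm-wise random forests / random survival forests, Cox PH); the default
learners can be swapped for any object honouring the same ``fit`` contract.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LogisticRegression

from .data_model import DataError, SurvivalTrialData, UncensoredTrialData

logger = logging.getLogger(__name__)

#: floors guarding inverse weights in finite samples; truncations are counted
EPS_PI = 0.01
EPS_K = 0.01
EPS_S = 1e-4

__all__ = [
    "EPS_PI", "EPS_K", "EPS_S",
    "NuisanceFit", "SurvivalNuisanceFit", "CensoringModel", "StepCurves",
    "fit_propensity", "fit_outcome_models", "fit_survival_models",
    "fit_censoring_model", "conditional_rmst", "conditional_rmst_after_r",
    "censoring_augmentation",
    "ForestNuisanceLearner", "SurvivalForestNuisanceLearner",
    "get_learner", "register_learner",
]


# ---------------------------------------------------------------------------
# step-function survival curves
# ---------------------------------------------------------------------------

class StepCurves:
    """A bundle of right-continuous step survival curves on a shared grid.

    ``S(t) = 1`` for ``t < times[0]`` and ``S(t) = surv[:, k]`` for
    ``t in [times[k], times[k+1])``.  All RMST-type functionals below use
    this half-open convention.
    """

    def __init__(self, times: np.ndarray, surv: np.ndarray):
        self.times = np.asarray(times, dtype=float)
        self.surv = np.atleast_2d(np.asarray(surv, dtype=float))
        if self.surv.shape[1] != self.times.shape[0]:
            raise ValueError("surv must have one column per grid time")

    @property
    def n(self) -> int:
        return self.surv.shape[0]

    def eval(self, r) -> np.ndarray:
        """S(r) for scalar r (all curves) or one r per curve."""
        r = np.asarray(r, dtype=float)
        idx = np.searchsorted(self.times, r, side="right") - 1
        if r.ndim == 0:
            return np.ones(self.n) if idx < 0 else self.surv[:, idx].copy()
        vals = self.surv[np.arange(self.n), np.clip(idx, 0, None)]
        return np.where(idx < 0, 1.0, vals)

    def _atoms(self, L: float):
        """Jump locations z_k <= L with masses -dS(z_k) per curve."""
        prev = np.concatenate([np.ones((self.n, 1)), self.surv[:, :-1]], axis=1)
        w = self.times[None, :] * (prev - self.surv)
        w[:, self.times > L] = 0.0
        return w

    def rmst(self, L: float) -> np.ndarray:
        """integral_0^L S(t) dt per curve (step integral)."""
        ts = np.concatenate([[0.0], np.clip(self.times, None, L), [L]])
        dt = np.clip(np.diff(ts), 0.0, None)
        vals = np.concatenate([np.ones((self.n, 1)),
                               self.surv], axis=1)
        return vals @ dt

    def conditional_rmst_at(self, r, L: float, eps_s: float = EPS_S) -> np.ndarray:
        """m(r) = E[min(T, L) | T >= r] per curve; r scalar or per-curve."""
        r = np.asarray(r, dtype=float)
        if self.times.size == 0:
            return np.full(self.n, L) if r.ndim == 0 else np.full_like(
                np.broadcast_to(r, (self.n,)), L)
        w = self._atoms(L)
        cw = np.cumsum(w, axis=1)
        total = cw[:, -1]
        SL = self.eval(np.float64(L))
        idx = np.searchsorted(self.times, r, side="right") - 1
        if r.ndim == 0:
            prefix = np.zeros(self.n) if idx < 0 else cw[:, idx]
        else:
            prefix = np.where(idx < 0, 0.0,
                              cw[np.arange(self.n), np.clip(idx, 0, None)])
        Sr = np.maximum(self.eval(r), eps_s)
        m = (total - prefix + L * SL) / Sr
        return np.clip(m, np.broadcast_to(r, m.shape), L)

    def conditional_rmst_grid(self, grid: np.ndarray, L: float,
                              eps_s: float = EPS_S) -> np.ndarray:
        """Matrix m[i, k] = m(grid[k]) for curve i, for grid points <= L."""
        grid = np.asarray(grid, dtype=float)
        w = self._atoms(L)
        cw = np.cumsum(w, axis=1) if w.shape[1] else np.zeros((self.n, 0))
        total = cw[:, -1:] if w.shape[1] else np.zeros((self.n, 1))
        SL = self.eval(np.float64(L))[:, None]
        gidx = np.searchsorted(self.times, grid, side="right") - 1
        prefix = np.where(gidx[None, :] < 0, 0.0,
                          cw[:, np.clip(gidx, 0, None)] if w.shape[1] else 0.0)
        sidx = np.clip(gidx, 0, None)
        Sr = np.where(gidx[None, :] < 0, 1.0,
                      self.surv[:, sidx] if self.surv.shape[1] else 1.0)
        m = (total - prefix + L * SL) / np.maximum(Sr, eps_s)
        return np.clip(m, grid[None, :], L)


def conditional_rmst(times, surv, r, L, eps_s: float = EPS_S) -> float:
    """Residual restricted mean ``E[min(T, L) | T >= r]`` for one step curve.

    Implements ``[sum_{z in (r, L]} z * (-dS(z)) + L * S(L)] / S(r)``; the
    result always lies in ``[r, L]``.
    """
    if not 0 <= r <= L:
        raise ValueError(f"require 0 <= r <= L, got r={r}, L={L}")
    return float(StepCurves(times, np.atleast_2d(surv)).conditional_rmst_at(
        np.float64(r), L, eps_s)[0])


# ---------------------------------------------------------------------------
# censoring model
# ---------------------------------------------------------------------------

@dataclass
class CensoringModel:
    """Conditional censoring distribution ``Kc(t|x,a) = exp(-Lambda_c(t|x,a))``
    in Cox form: a step baseline cumulative hazard (times/increments) scaled
    by ``exp(linear predictor)``.  ``coef`` is on the design ``[X, A]``; a
    ``None`` coef means a covariate-free (Nelson-Aalen-type) model and an
    empty ``times`` means no censoring at all (``Kc === 1``)."""

    times: np.ndarray
    base_dH: np.ndarray
    coef: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.base_dH = np.asarray(self.base_dH, dtype=float)
        if (self.base_dH < 0).any():
            raise ValueError("baseline hazard increments must be nonnegative")
        self._H0 = np.cumsum(self.base_dH)

    def linpred(self, X: np.ndarray, A: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        A = np.asarray(A, dtype=float).reshape(-1)
        if self.coef is None:
            return np.zeros(X.shape[0])
        Z = np.column_stack([X, A])
        return Z @ self.coef

    def cum_hazard(self, t, X, A) -> np.ndarray:
        """Lambda_c(t | x, a); t scalar or one value per row."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        H0 = np.where(idx < 0, 0.0, self._H0[np.clip(idx, 0, None)]) \
            if self.times.size else np.zeros_like(t, dtype=float)
        return np.exp(self.linpred(X, A)) * H0

    def survival(self, t, X, A) -> np.ndarray:
        return np.exp(-self.cum_hazard(t, X, A))


# ---------------------------------------------------------------------------
# nuisance fits
# ---------------------------------------------------------------------------

@dataclass
class NuisanceFit:
    """Frozen nuisance functions for an uncensored outcome.

    All callables are vectorized: they accept an ``(n, p)`` covariate matrix
    and return an ``(n,)`` array.  ``pi_hat`` is clipped to
    ``[EPS_PI, 1 - EPS_PI]`` by construction.
    """

    pi_hat: Callable[[np.ndarray], np.ndarray]
    c0_hat: Callable[[np.ndarray], np.ndarray]
    tau_hat: Callable[[np.ndarray], np.ndarray]
    fitted_on: str = ""


@dataclass
class SurvivalNuisanceFit(NuisanceFit):
    """Frozen nuisances for a censored outcome on the RMST scale.

    ``curves(X, a)`` returns a :class:`StepCurves` bundle of conditional
    survival curves under arm ``a``; ``cens`` is the fitted censoring model.
    """

    curves: Callable[[np.ndarray, int], StepCurves] = None
    cens: CensoringModel = None
    L: float = None

    # -- scalar conveniences mirroring the field notation -------------------
    def surv_hat(self, t, x, a) -> float:
        return float(self.curves(np.atleast_2d(x), int(a)).eval(np.float64(t))[0])

    def kc_hat(self, t, x, a) -> float:
        return float(np.exp(-self.lambda_c_hat(t, x, a)))

    def lambda_c_hat(self, t, x, a) -> float:
        return float(self.cens.cum_hazard(np.float64(t), np.atleast_2d(x),
                                          np.asarray([a]))[0])

    def m_hat(self, r, x, a) -> float:
        if not 0 <= r <= self.L:
            raise ValueError(f"require 0 <= r <= L, got r={r}")
        sc = self.curves(np.atleast_2d(x), int(a))
        return float(sc.conditional_rmst_at(np.float64(r), self.L)[0])


# ---------------------------------------------------------------------------
# fitting operations
# ---------------------------------------------------------------------------

def _clip_pi(p: np.ndarray) -> np.ndarray:
    return np.clip(p, EPS_PI, 1.0 - EPS_PI)


def fit_propensity(history, mode: str = "logistic") -> Callable:
    """Fit the propensity ``pi(x)``.

    ``mode='known'`` returns the constant randomization probability attached
    to the data; ``mode='logistic'`` fits an unpenalized logistic regression
    of ``A`` on ``X``; ``mode='auto'`` (the learner default) uses the known
    probability when the data carry one — the natural choice for randomized
    trials, where it also removes the finite-sample product bias of an
    estimated propensity — and falls back to the logistic fit otherwise.
    Predictions are clipped to ``[EPS_PI, 1 - EPS_PI]``.
    """
    if mode == "auto":
        mode = "known" if history.known_pi is not None else "logistic"
    if mode == "known":
        if history.known_pi is None:
            raise DataError("known-propensity mode requires known_pi on the data")
        const = float(np.clip(history.known_pi, EPS_PI, 1 - EPS_PI))
        return lambda X: np.full(np.atleast_2d(X).shape[0], const)
    if mode != "logistic":
        raise ValueError(f"unknown propensity mode {mode!r}")
    if len(np.unique(history.A)) < 2:
        raise DataError("degenerate-fit: logistic propensity needs both arms in history")
    lr = LogisticRegression(C=np.inf, max_iter=2000)  # unpenalized MLE
    lr.fit(history.X, history.A)
    return lambda X: _clip_pi(lr.predict_proba(np.atleast_2d(X))[:, 1])


def _check_arms(history, min_per_arm: int) -> None:
    for arm in (0, 1):
        n_arm = int((history.A == arm).sum())
        if n_arm < min_per_arm:
            raise DataError(
                f"too few observations in arm {arm}: {n_arm} < {min_per_arm}")


class _OOBForest:
    """Regression forest whose predictions for its own training rows are the
    out-of-bag predictions.

    The history-based conditional-SD estimator evaluates the score function
    at the training subjects themselves; in-sample forest predictions
    partially memorize those outcomes, which would understate the
    out-of-sample score variance and overdisperse the test statistic.  OOB
    predictions restore honesty for training rows while new rows get the
    ordinary ensemble prediction.
    """

    def __init__(self, rf: RandomForestRegressor, X_train: np.ndarray):
        self.rf = rf
        oob = np.asarray(rf.oob_prediction_, dtype=float)
        fallback = rf.predict(X_train)
        oob = np.where(np.isfinite(oob), oob, fallback)
        self._oob = {}
        for i, row in enumerate(np.ascontiguousarray(X_train)):
            self._oob[row.tobytes()] = oob[i]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        pred = self.rf.predict(X)
        for i, row in enumerate(np.ascontiguousarray(X)):
            hit = self._oob.get(row.tobytes())
            if hit is not None:
                pred[i] = hit
        return pred


def fit_outcome_models(
    history: UncensoredTrialData,
    n_estimators: int = 300,
    min_samples_leaf: int = 5,
    min_per_arm: int = 10,
    random_state=None,
    oob_honesty: bool = True,
):
    """Arm-wise regression forests for the conditional outcome.

    Returns ``(c0_hat, tau_hat)`` where ``c0_hat`` predicts ``E[Y | X, A=0]``
    and ``tau_hat`` the CATE (arm-1 minus arm-0 prediction).  With
    ``oob_honesty`` (default) predictions at the training rows themselves are
    out-of-bag, see :class:`_OOBForest`.  Any regressor pair with the same
    contract may replace this default.
    """
    _check_arms(history, min_per_arm)
    rs = np.random.default_rng(random_state).integers(2**31 - 1, size=2)
    models = {}
    for arm in (0, 1):
        mask = history.A == arm
        rf = RandomForestRegressor(
            n_estimators=n_estimators, min_samples_leaf=min_samples_leaf,
            random_state=int(rs[arm]), n_jobs=1, oob_score=oob_honesty)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # few-tree OOB coverage warnings
            rf.fit(history.X[mask], history.Y[mask])
        models[arm] = _OOBForest(rf, history.X[mask]) if oob_honesty else rf
    c0_hat = lambda X: models[0].predict(np.atleast_2d(X))
    tau_hat = lambda X: models[1].predict(np.atleast_2d(X)) - models[0].predict(np.atleast_2d(X))
    return c0_hat, tau_hat


def fit_survival_models(
    history: SurvivalTrialData,
    L: float,
    n_estimators: int = 300,
    min_samples_leaf: int = 15,
    min_per_arm: int = 10,
    random_state=None,
):
    """Arm-wise random survival forests for the conditional event distribution.

    Returns ``(curves, c0_hat, tau_hat)``: ``curves(X, a)`` is a
    :class:`StepCurves` bundle, ``c0_hat(x) = int_0^L S_hat(t|x,0) dt`` (the
    control conditional RMST) and ``tau_hat`` its arm difference.
    """
    from sksurv.ensemble import RandomSurvivalForest
    from sksurv.util import Surv

    _check_arms(history, min_per_arm)
    rs = np.random.default_rng(random_state).integers(2**31 - 1, size=2)
    models = {}
    for arm in (0, 1):
        mask = history.A == arm
        if history.Delta[mask].sum() == 0:
            raise DataError(f"arm {arm} has zero observed events; cannot fit "
                            "a survival model")
        rsf = RandomSurvivalForest(
            n_estimators=n_estimators, min_samples_leaf=min_samples_leaf,
            random_state=int(rs[arm]), n_jobs=1)
        rsf.fit(history.X[mask], Surv.from_arrays(
            history.Delta[mask].astype(bool), history.U[mask]))
        models[arm] = rsf

    def curves(X, a) -> StepCurves:
        rsf = models[int(a)]
        S = rsf.predict_survival_function(np.atleast_2d(X), return_array=True)
        return StepCurves(rsf.unique_times_, S)

    def c0_hat(X):
        return curves(X, 0).rmst(L)

    def tau_hat(X):
        return curves(X, 1).rmst(L) - curves(X, 0).rmst(L)

    return curves, c0_hat, tau_hat


def fit_censoring_model(history: SurvivalTrialData) -> CensoringModel:
    """Cox PH model for the censoring time: observed time ``U``, status
    ``1 - Delta``, design ``[X, A]``, Breslow baseline.

    With no censoring events in the history this degenerates (with a warning)
    to ``Kc === 1``.  If the Cox fit fails to converge, a covariate-free
    Nelson-Aalen estimate of the censoring hazard is used instead.
    """
    from sksurv.linear_model import CoxPHSurvivalAnalysis
    from sksurv.nonparametric import nelson_aalen_estimator
    from sksurv.util import Surv

    cens_event = history.Delta == 0
    if cens_event.sum() == 0:
        warnings.warn("no censoring events in history; using Kc === 1")
        return CensoringModel(np.empty(0), np.empty(0))
    Z = np.column_stack([history.X, history.A])
    y = Surv.from_arrays(cens_event, history.U)
    try:
        cox = CoxPHSurvivalAnalysis().fit(Z, y)
        bh = cox.cum_baseline_hazard_
        dH = np.diff(bh.y, prepend=0.0)
        return CensoringModel(bh.x, dH, coef=cox.coef_.copy())
    except Exception as exc:  # noqa: BLE001 - any numerical failure
        warnings.warn(f"Cox censoring fit failed ({exc}); falling back to a "
                      "covariate-free censoring hazard")
        t, H = nelson_aalen_estimator(cens_event, history.U)
        return CensoringModel(t, np.diff(H, prepend=0.0), coef=None)


def conditional_rmst_after_r(fit: SurvivalNuisanceFit, r, x, a, L=None) -> float:
    """``m_hat(r | x, a)``, see :func:`conditional_rmst`."""
    L = fit.L if L is None else L
    if not 0 <= r <= L:
        raise ValueError(f"require 0 <= r <= L, got r={r}, L={L}")
    return float(fit.curves(np.atleast_2d(x), int(a)).conditional_rmst_at(
        np.float64(r), L)[0])


def censoring_augmentation(o, fit: SurvivalNuisanceFit, L=None) -> float:
    """Censoring-martingale augmentation integral for one observation.

    Evaluates ``int_0^L dMc(r)/Kc(r) * m(r)`` in its two-term form
    ``(1 - DeltaL) * m(UL)/Kc(UL) - sum_{steps t_k <= UL} dLambda_c(t_k)
    / Kc(t_k) * m(t_k)``; under the true censoring law it has mean zero.

    ``o`` is a ``(x, a, UL, DeltaL)`` tuple.
    """
    x, a, UL, DeltaL = o
    L = fit.L if L is None else L
    x2 = np.atleast_2d(x)
    a_arr = np.asarray([a])
    aug = 0.0
    if DeltaL == 0:
        kc_u = max(fit.cens.survival(np.float64(UL), x2, a_arr)[0], EPS_K)
        aug += fit.m_hat(UL, x, a) / kc_u
    cm = fit.cens
    if cm.times.size:
        mask = cm.times <= UL
        if mask.any():
            tk = cm.times[mask]
            lp = float(cm.linpred(x2, a_arr)[0])
            dH = cm.base_dH[mask] * np.exp(lp)
            H = np.cumsum(cm.base_dH)[mask] * np.exp(lp)
            kc = np.maximum(np.exp(-H), EPS_K)
            sc = fit.curves(x2, int(a))
            mvals = sc.conditional_rmst_grid(tk, L)[0]
            aug -= float(np.sum(dH / kc * mvals))
    return float(aug)


# ---------------------------------------------------------------------------
# learners (pluggable nuisance contract)
# ---------------------------------------------------------------------------

@dataclass
class ForestNuisanceLearner:
    """Default nuisance learner for uncensored data: logistic (or known)
    propensity plus arm-wise regression forests."""

    propensity: str = "auto"
    n_estimators: int = 300
    min_samples_leaf: int = 5
    min_per_arm: int = 10
    oob_honesty: bool = True

    def fit(self, history: UncensoredTrialData, rng=None) -> NuisanceFit:
        rng = np.random.default_rng(rng)
        pi_hat = fit_propensity(history, self.propensity)
        c0_hat, tau_hat = fit_outcome_models(
            history, self.n_estimators, self.min_samples_leaf,
            self.min_per_arm, random_state=rng, oob_honesty=self.oob_honesty)
        return NuisanceFit(pi_hat, c0_hat, tau_hat,
                           fitted_on=f"n={history.n}")


@dataclass
class SurvivalForestNuisanceLearner:
    """Default nuisance learner for survival data: logistic (or known)
    propensity, arm-wise random survival forests, Cox censoring model."""

    propensity: str = "auto"
    n_estimators: int = 300
    min_samples_leaf: int = 15
    min_per_arm: int = 10

    def fit(self, history: SurvivalTrialData, rng=None) -> SurvivalNuisanceFit:
        rng = np.random.default_rng(rng)
        pi_hat = fit_propensity(history, self.propensity)
        curves, c0_hat, tau_hat = fit_survival_models(
            history, history.L, self.n_estimators, self.min_samples_leaf,
            self.min_per_arm, random_state=rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cens = fit_censoring_model(history)
        return SurvivalNuisanceFit(
            pi_hat, c0_hat, tau_hat, fitted_on=f"n={history.n}",
            curves=curves, cens=cens, L=history.L)


_LEARNERS: dict[str, Callable] = {
    "forest": ForestNuisanceLearner,
    "survival_forest": SurvivalForestNuisanceLearner,
}


def register_learner(key: str, factory: Callable) -> None:
    """Register a nuisance learner factory under a string key."""
    _LEARNERS[key] = factory


def get_learner(key: str, **kwargs):
    try:
        return _LEARNERS[key](**kwargs)
    except KeyError:
        raise KeyError(f"no nuisance learner registered under {key!r}; "
                       f"known: {sorted(_LEARNERS)}") from None
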