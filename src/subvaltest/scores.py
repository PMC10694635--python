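"""Per-observation value-difference scores.

Each score is an unbiased (given true nuisances) per-subject contribution to
``Psi(d_opt) = V(d_opt) - V(0)``, the value difference between the estimated
optimal rule ``d(x) = 1(tau(x) > 0)`` and the give-everyone-control rule.
The sample mean of a score vector is the corresponding value-difference
estimator.

Uncensored outcome:

* ``ipw``   — AIPW estimator of ``V(d_opt)`` minus an IPW estimator of ``V(0)``;
* ``aipw``  — both parts augmented; degenerates to exactly zero per subject
  whenever ``tau_hat <= 0`` everywhere (the regular-null cancellation).

Censored outcome (RMST scale, IPCW-weighted by ``Kc``):

* ``ipws``  — censored analogue of ``ipw`` with ``zeta === 1``;
* ``aipws`` — adds the control augmentation; a mean-one perturbation
  ``zeta_i`` multiplies the regime-mismatch augmentation term so that chunk
  estimates do not collapse to exactly zero at the exceptional law;
* ``caipws`` — additionally adds the censoring-martingale augmentation
  integrals, which recover information from censored, regime-consistent
  subjects (the locally efficient, doubly robust choice).

Scalar functions (``score_*``) take a single observation tuple and mirror the
printed formulas; the ``score_vectors_*`` functions are the vectorized
equivalents used by the sequential engine.
"""

from __future__ import annotations

import numpy as np

from .data_model import SurvivalTrialData, UncensoredTrialData
from .nuisance import (EPS_K, EPS_PI, NuisanceFit, SurvivalNuisanceFit,
                       censoring_augmentation)

__all__ = [
    "score_ipw", "score_aipw", "score_ipw_surv", "score_aipw_surv",
    "score_caipw_surv", "score_vectors_uncensored", "score_vectors_survival",
    "UNCENSORED_ESTIMATORS", "SURVIVAL_ESTIMATORS",
]

UNCENSORED_ESTIMATORS = ("ipw", "aipw")
SURVIVAL_ESTIMATORS = ("ipws", "aipws", "caipws")


# ---------------------------------------------------------------------------
# scalar forms (one observation)
# ---------------------------------------------------------------------------

def _scalar_uncensored_parts(o, fit: NuisanceFit):
    x, a, y = o
    x2 = np.atleast_2d(x)
    pi = float(np.clip(fit.pi_hat(x2)[0], EPS_PI, 1 - EPS_PI))
    tau = float(fit.tau_hat(x2)[0])
    c0 = float(fit.c0_hat(x2)[0])
    d = 1 if tau > 0 else 0
    pi_a = pi if a == 1 else 1.0 - pi
    match = 1.0 if a == d else 0.0
    return pi, pi_a, tau, c0, d, match, float(y), int(a)


def score_ipw(o, fit: NuisanceFit) -> float:
    """IPW-type value-difference score for one uncensored observation
    ``o = (x, a, y)``."""
    pi, pi_a, tau, c0, d, match, y, a = _scalar_uncensored_parts(o, fit)
    return (match / pi_a * y
            - (match / pi_a - 1.0) * (c0 + tau * d)
            - (a == 0) / (1.0 - pi) * y)


def score_aipw(o, fit: NuisanceFit) -> float:
    """AIPW value-difference score: :func:`score_ipw` plus the control-arm
    augmentation ``(1(a=0)/(1-pi) - 1) * c0``."""
    pi, _, _, c0, _, _, _, a = _scalar_uncensored_parts(o, fit)
    return score_ipw(o, fit) + ((a == 0) / (1.0 - pi) - 1.0) * c0


def _scalar_survival_parts(o, fit: SurvivalNuisanceFit):
    x, a, UL, DeltaL = o
    x2 = np.atleast_2d(x)
    pi = float(np.clip(fit.pi_hat(x2)[0], EPS_PI, 1 - EPS_PI))
    tau = float(fit.tau_hat(x2)[0])
    c0 = float(fit.c0_hat(x2)[0])
    d = 1 if tau > 0 else 0
    pi_a = pi if a == 1 else 1.0 - pi
    match = 1.0 if a == d else 0.0
    kc = max(fit.kc_hat(UL, x, a), EPS_K)
    return pi, pi_a, tau, c0, d, match, kc, float(UL), int(DeltaL), int(a)


def score_ipw_surv(o, fit: SurvivalNuisanceFit, L=None) -> float:
    """IPW-type RMST value-difference score for one censored observation
    ``o = (x, a, UL, DeltaL)`` (``zeta === 1``)."""
    pi, pi_a, tau, c0, d, match, kc, UL, DeltaL, a = _scalar_survival_parts(o, fit)
    return (DeltaL * match / (kc * pi_a) * UL
            - (match / pi_a - 1.0) * (c0 + tau * d)
            - DeltaL * (a == 0) / (kc * (1.0 - pi)) * UL)


def score_aipw_surv(o, fit: SurvivalNuisanceFit, L=None, zeta: float = 1.0) -> float:
    """AIPW RMST score: the ``zeta``-perturbed IPW form plus the control
    augmentation."""
    pi, pi_a, tau, c0, d, match, kc, UL, DeltaL, a = _scalar_survival_parts(o, fit)
    return (DeltaL * match / (kc * pi_a) * UL
            - (match / pi_a - 1.0) * zeta * (c0 + tau * d)
            - DeltaL * (a == 0) / (kc * (1.0 - pi)) * UL
            + ((a == 0) / (1.0 - pi) - 1.0) * c0)


def score_caipw_surv(o, fit: SurvivalNuisanceFit, L=None, zeta: float = 1.0) -> float:
    """CAIPW RMST score: AIPW plus the censoring-martingale augmentation,
    weighted ``1{a = d}/pi_a`` under the optimal rule and ``1(a=0)/(1-pi)``
    under the control rule (the two terms share one integral)."""
    pi, pi_a, tau, c0, d, match, kc, UL, DeltaL, a = _scalar_survival_parts(o, fit)
    aug = censoring_augmentation((o[0], a, UL, DeltaL), fit, L)
    return (score_aipw_surv(o, fit, L, zeta)
            + (match / pi_a - (a == 0) / (1.0 - pi)) * aug)


# ---------------------------------------------------------------------------
# vectorized forms (whole sample against one frozen fit)
# ---------------------------------------------------------------------------

def score_vectors_uncensored(
    data: UncensoredTrialData,
    fit: NuisanceFit,
    estimators=UNCENSORED_ESTIMATORS,
) -> dict[str, np.ndarray]:
    """Evaluate the requested uncensored scores for every subject."""
    X, A, Y = data.X, data.A, data.Y
    pi = np.clip(fit.pi_hat(X), EPS_PI, 1 - EPS_PI)
    tau = fit.tau_hat(X)
    c0 = fit.c0_hat(X)
    d = (tau > 0).astype(float)
    pi_a = np.where(A == 1, pi, 1.0 - pi)
    match = (A == d).astype(float)
    ctrl = (A == 0).astype(float)
    w_d = match / pi_a
    w_0 = ctrl / (1.0 - pi)
    out = {}
    for est in estimators:
        if est == "ipw":
            out[est] = w_d * Y - (w_d - 1.0) * (c0 + tau * d) - w_0 * Y
        elif est == "aipw":
            # grouped so that the all-control-rule cancellation is exact
            # per subject in floating point, not just algebraically
            out[est] = (w_d * (Y - c0 - tau * d) - w_0 * (Y - c0)
                        + tau * d)
        else:
            raise ValueError(f"estimator {est!r} is not an uncensored estimator")
    return out


def _augmentation_vector(data: SurvivalTrialData, fit: SurvivalNuisanceFit):
    """Vectorized two-term censoring augmentation; returns (aug, n_truncated)."""
    n = data.n
    aug = np.zeros(n)
    cm = fit.cens
    n_trunc = 0
    lp = cm.linpred(data.X, data.A)
    H0 = np.cumsum(cm.base_dH) if cm.times.size else np.empty(0)
    # Kc(UL) per subject
    idx_u = np.searchsorted(cm.times, data.UL, side="right") - 1
    H0_u = np.where(idx_u < 0, 0.0, H0[np.clip(idx_u, 0, None)]) \
        if cm.times.size else np.zeros(n)
    kc_ul_raw = np.exp(-np.exp(lp) * H0_u)
    n_trunc += int((kc_ul_raw < EPS_K).sum())
    kc_ul = np.maximum(kc_ul_raw, EPS_K)
    if cm.times.size == 0:
        return aug, kc_ul, n_trunc
    for arm in (0, 1):
        rows = np.flatnonzero(data.A == arm)
        if rows.size == 0:
            continue
        sc = fit.curves(data.X[rows], arm)
        m_ul = sc.conditional_rmst_at(data.UL[rows], fit.L)
        term1 = (1 - data.DeltaL[rows]) * m_ul / kc_ul[rows]
        M = sc.conditional_rmst_grid(cm.times, fit.L)
        e_lp = np.exp(lp[rows])[:, None]
        Kc_grid_raw = np.exp(-e_lp * H0[None, :])
        need = cm.times[None, :] <= data.UL[rows, None]
        n_trunc += int(((Kc_grid_raw < EPS_K) & need).sum())
        Kc_grid = np.maximum(Kc_grid_raw, EPS_K)
        dH = e_lp * cm.base_dH[None, :]
        term2 = np.sum(np.where(need, dH / Kc_grid * M, 0.0), axis=1)
        aug[rows] = term1 - term2
    return aug, kc_ul, n_trunc


def score_vectors_survival(
    data: SurvivalTrialData,
    fit: SurvivalNuisanceFit,
    zeta: np.ndarray | None = None,
    estimators=SURVIVAL_ESTIMATORS,
):
    """Evaluate the requested survival scores for every subject.

    ``zeta`` is the per-subject mean-one perturbation used by the ``aipws``
    and ``caipws`` scores (``ipws`` always uses 1).  Returns
    ``(scores_dict, n_truncated_kc)``.
    """
    X, A, UL, DeltaL = data.X, data.A, data.UL, data.DeltaL.astype(float)
    n = data.n
    zeta = np.ones(n) if zeta is None else np.asarray(zeta, dtype=float)
    pi = np.clip(fit.pi_hat(X), EPS_PI, 1 - EPS_PI)
    tau = fit.tau_hat(X)
    c0 = fit.c0_hat(X)
    d = (tau > 0).astype(float)
    pi_a = np.where(A == 1, pi, 1.0 - pi)
    match = (A == d).astype(float)
    ctrl = (A == 0).astype(float)

    need_aug = "caipws" in estimators
    aug, kc_ul, n_trunc = _augmentation_vector(data, fit) if need_aug else (
        None, None, 0)
    if kc_ul is None:
        cm = fit.cens
        lp = cm.linpred(X, A)
        kc_raw = cm.survival(UL, X, A) if cm.times.size else np.ones(n)
        n_trunc += int((kc_raw < EPS_K).sum())
        kc_ul = np.maximum(kc_raw, EPS_K)

    w_d = match / pi_a
    w_0 = ctrl / (1.0 - pi)
    # grouped so that for tau_hat <= 0 subjects the score is exactly zero
    # in floating point when zeta = 1 (the all-control-rule degeneracy)
    base_delta = DeltaL / kc_ul * UL * (w_d - w_0)
    mid_unit = (w_d - 1.0) * (c0 + tau * d)
    aipw_corr = (w_0 - 1.0) * c0

    out = {}
    for est in estimators:
        if est == "ipws":
            out[est] = base_delta - mid_unit
        elif est == "aipws":
            out[est] = base_delta - zeta * mid_unit + aipw_corr
        elif est == "caipws":
            out[est] = (base_delta - zeta * mid_unit + aipw_corr
                        + (w_d - w_0) * aug)
        else:
            raise ValueError(f"estimator {est!r} is not a survival estimator")
    return out, n_trunc
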