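"""Synthetic trial generators and the Monte Carlo verification harness.

Two families of data-generating processes are provided, matching the designs
used to study the test's operating characteristics:

* **Model 1** (uncensored): ``Y = C0(X) + A*tau(X) + eps`` with
  ``C0(X) = 3.18 + 0.2*X1 + X2 + 0.5*X3``,
  ``tau(X) = c * 1(-0.5*X2^2 + X4 > 0)`` and ``eps ~ N(0, 0.25)`` (variance
  0.25, i.e. SD 0.5).  ``X1..X3`` are iid N(0,1); ``X4, X5`` iid
  Bernoulli(0.5).  Scheme 2 appends 20 further iid N(0,1) noise covariates.
  Analytically, ``pr{tau(X) = 0} = 1 - 0.5*pr(chi^2_1 < 2) ~= 0.579``.

* **AFT models** (censored): ``log T = 1.75 + 0.5*X1 + X1^2 + 0.3*X2
  + 0.2*X3 + 0.3*X4 + 0.6*X5 + c*A*1(X2 + 3*X4 > 0) + e`` with ``e ~
  N(0, 0.25)`` (Model 1, non-PH) or ``e = log Z``, ``Z ~ Exponential(1)``
  (Model 2, PH).  ``pr{tau(X) = 0} = pr(X2 + 3*X4 <= 0) ~= 0.25``.
  Censoring: (a) ``C ~ U(0, 50)``; (b) ``C ~ U(0, 100)``; (c) covariate-
  dependent exponential with rate ``exp(b0 + 0.1*X1 + 0.2*A)``.  The
  intercept ``b0`` of model (c) is a calibration parameter; the default
  (-3.5) is chosen so that (c) censors more heavily by time ``L`` than (b).

Treatment is assigned Bernoulli(pi) (``pi_mode="bernoulli"``), with the
treated count fixed exactly at ``n*pi`` (``pi_mode="exact"``, used with
SAP-match chunking in randomized studies), or by the observational logistic
model ``pi(X) = expit(-0.3 + 0.2*X1 + 0.6*X5)`` (``pi_mode="observational"``,
marginally about 0.5).

Oracle nuisance learners that plug the true functions of these designs into
the testing engine are included for calibration studies.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import chi2, norm

from .data_model import (ConfigError, SurvivalTrialData, UncensoredTrialData)
from .nuisance import CensoringModel, NuisanceFit, StepCurves, SurvivalNuisanceFit
from .onestep import OneStepConfig, run_one_step_tests

__all__ = [
    "SimDesign", "MonteCarloRow", "gen_model1", "gen_aft", "choose_L",
    "zero_effect_fraction", "monte_carlo", "true_value_difference",
    "OracleModel1Learner", "OracleAFTLearner",
    "MODEL1_ZERO_FRACTION",
]

#: analytic pr{tau(X)=0} for Model 1 (schemes 1 and 2): 1 - 0.5*pr(chi2_1 < 2)
MODEL1_ZERO_FRACTION = 1.0 - 0.5 * chi2.cdf(2.0, df=1)

OBS_PROP_COEF = (-0.3, 0.2, 0.6)  # intercept, X1, X5


def _covariates(n: int, rng, extra_noise: int = 0) -> np.ndarray:
    X = np.empty((n, 5 + extra_noise))
    X[:, :3] = rng.normal(size=(n, 3))
    X[:, 3:5] = rng.integers(0, 2, size=(n, 2))
    if extra_noise:
        X[:, 5:] = rng.normal(size=(n, extra_noise))
    return X


def _obs_propensity(X: np.ndarray) -> np.ndarray:
    b0, b1, b5 = OBS_PROP_COEF
    return expit(b0 + b1 * X[:, 0] + b5 * X[:, 4])


def _assign_treatment(X: np.ndarray, pi_mode: str, pi: float, rng) -> np.ndarray:
    n = X.shape[0]
    if pi_mode == "bernoulli":
        return (rng.random(n) < pi).astype(np.int64)
    if pi_mode == "exact":
        A = np.zeros(n, dtype=np.int64)
        k = int(round(n * pi))
        A[rng.permutation(n)[:k]] = 1
        return A
    if pi_mode == "observational":
        return (rng.random(n) < _obs_propensity(X)).astype(np.int64)
    raise ConfigError(f"unknown pi_mode {pi_mode!r}")


def model1_c0(X: np.ndarray) -> np.ndarray:
    return 3.18 + 0.2 * X[:, 0] + X[:, 1] + 0.5 * X[:, 2]


def model1_tau(X: np.ndarray, c: float) -> np.ndarray:
    return c * (-0.5 * X[:, 1] ** 2 + X[:, 3] > 0)


def aft_mu(X: np.ndarray, A: np.ndarray, c: float) -> np.ndarray:
    """Linear predictor of log T under the AFT designs."""
    base = (1.75 + 0.5 * X[:, 0] + X[:, 0] ** 2 + 0.3 * X[:, 1]
            + 0.2 * X[:, 2] + 0.3 * X[:, 3] + 0.6 * X[:, 4])
    return base + c * np.asarray(A) * (X[:, 1] + 3 * X[:, 3] > 0)


def gen_model1(n: int, c: float, scheme: int = 1, pi_mode: str = "bernoulli",
               rng=None, pi: float = 0.5) -> UncensoredTrialData:
    """Generate one uncensored Model 1 dataset (scheme 1 or 2)."""
    if scheme not in (1, 2):
        raise ConfigError(f"scheme must be 1 or 2, got {scheme}")
    rng = np.random.default_rng(rng)
    X = _covariates(n, rng, extra_noise=20 if scheme == 2 else 0)
    A = _assign_treatment(X, pi_mode, pi, rng)
    Y = model1_c0(X) + A * model1_tau(X, c) + rng.normal(0.0, 0.5, size=n)
    known_pi = pi if pi_mode in ("bernoulli", "exact") else None
    return UncensoredTrialData(X, A, Y, known_pi=known_pi)


def choose_L(U: np.ndarray, target_observed_frac: float = 0.85) -> float:
    """Empirical quantile of the observed times: the smallest time by which
    at least the target fraction of subjects is observed (inverted CDF)."""
    if not 0.0 < target_observed_frac < 1.0:
        raise ConfigError("target_observed_frac must lie in (0, 1)")
    U = np.asarray(U, dtype=float)
    if np.ptp(U) == 0:
        warnings.warn("degenerate observed times: all equal")
        return float(U[0])
    return float(np.quantile(U, target_observed_frac, method="inverted_cdf"))


def gen_aft(n: int, c: float, error_model: str = "normal",
            censoring: str = "b", pi_mode: str = "bernoulli", rng=None,
            pi: float = 0.5, L: float | None = None,
            cens_intercept: float = -3.5) -> SurvivalTrialData:
    """Generate one censored AFT dataset.

    ``error_model``: "normal" (AFT Model 1) or "exp_log" (AFT Model 2).
    ``censoring``: "none", "a" (U(0,50)), "b" (U(0,100)) or "c" (exponential
    with rate ``exp(cens_intercept + 0.1*X1 + 0.2*A)``).  ``L`` defaults to
    42 under (b), 33 under (c), otherwise the 0.85 observed quantile.
    """
    rng = np.random.default_rng(rng)
    X = _covariates(n, rng)
    A = _assign_treatment(X, pi_mode, pi, rng)
    if error_model == "normal":
        e = rng.normal(0.0, 0.5, size=n)
    elif error_model == "exp_log":
        e = np.log(rng.exponential(1.0, size=n))
    else:
        raise ConfigError(f"unknown error_model {error_model!r}")
    T = np.exp(aft_mu(X, A, c) + e)
    if censoring == "none":
        C = np.full(n, np.inf)
    elif censoring == "a":
        C = rng.uniform(0.0, 50.0, size=n)
    elif censoring == "b":
        C = rng.uniform(0.0, 100.0, size=n)
    elif censoring == "c":
        rate = np.exp(cens_intercept + 0.1 * X[:, 0] + 0.2 * A)
        C = rng.exponential(1.0 / rate)
    else:
        raise ConfigError(f"unknown censoring model {censoring!r}")
    U = np.minimum(T, C)
    Delta = (T <= C).astype(np.int64)
    if L is None:
        L = {"b": 42.0, "c": 33.0}.get(censoring) or choose_L(U, 0.85)
    known_pi = pi if pi_mode in ("bernoulli", "exact") else None
    return SurvivalTrialData(X, A, U, Delta, L, known_pi=known_pi)


@dataclass
class SimDesign:
    """One simulation condition; ``sample(rng)`` draws a dataset."""

    family: str  # model1_scheme1 | model1_scheme2 | aft_model1 | aft_model2
    c: float
    n: int
    pi_mode: str = "bernoulli"
    pi: float = 0.5
    censoring: str = "none"
    L: float | None = None
    cens_intercept: float = -3.5

    def __post_init__(self) -> None:
        if self.family.startswith("model1") and self.censoring != "none":
            raise ConfigError("uncensored families take censoring='none'")
        if self.family.startswith("aft") and self.censoring == "none" \
                and self.L is None:
            self.L = 42.0

    @property
    def survival(self) -> bool:
        return self.family.startswith("aft")

    def sample(self, rng):
        rng = np.random.default_rng(rng)
        if self.family == "model1_scheme1":
            return gen_model1(self.n, self.c, 1, self.pi_mode, rng, self.pi)
        if self.family == "model1_scheme2":
            return gen_model1(self.n, self.c, 2, self.pi_mode, rng, self.pi)
        if self.family == "aft_model1":
            return gen_aft(self.n, self.c, "normal", self.censoring,
                           self.pi_mode, rng, self.pi, self.L,
                           self.cens_intercept)
        if self.family == "aft_model2":
            return gen_aft(self.n, self.c, "exp_log", self.censoring,
                           self.pi_mode, rng, self.pi, self.L,
                           self.cens_intercept)
        raise ConfigError(f"unknown design family {self.family!r}")


def zero_effect_fraction(design: SimDesign, n_mc: int = 10_000, rng=None) -> float:
    """Monte Carlo estimate of ``pr{tau(X) = 0}`` under the design."""
    if n_mc < 1000:
        raise ConfigError("n_mc must be at least 1000")
    rng = np.random.default_rng(rng)
    X = _covariates(n_mc, rng)
    if design.c == 0:
        return 1.0
    if design.family.startswith("model1"):
        ind = -0.5 * X[:, 1] ** 2 + X[:, 3] > 0
    else:
        ind = X[:, 1] + 3 * X[:, 3] > 0
    return float(np.mean(~ind))


# ---------------------------------------------------------------------------
# oracle nuisances (true functions of the designs)
# ---------------------------------------------------------------------------

def _pi_fns(design: SimDesign):
    if design.pi_mode == "observational":
        return lambda X: _obs_propensity(np.atleast_2d(X))
    pi = design.pi
    return lambda X: np.full(np.atleast_2d(X).shape[0], pi)


@dataclass
class OracleModel1Learner:
    """True nuisance functions of the Model 1 designs (no estimation)."""

    design: SimDesign

    def fit(self, history, rng=None) -> NuisanceFit:
        c = self.design.c
        return NuisanceFit(
            pi_hat=_pi_fns(self.design),
            c0_hat=lambda X: model1_c0(np.atleast_2d(X)),
            tau_hat=lambda X: model1_tau(np.atleast_2d(X), c),
            fitted_on="oracle",
        )


def _aft_surv_matrix(X, a, c, error_model, grid):
    mu = aft_mu(np.atleast_2d(X), np.full(np.atleast_2d(X).shape[0], a), c)
    if error_model == "normal":
        return norm.sf((np.log(grid)[None, :] - mu[:, None]) / 0.5)
    return np.exp(-grid[None, :] * np.exp(-mu)[:, None])


@dataclass
class OracleAFTLearner:
    """True nuisance functions of the AFT designs, discretized on a fine time
    grid (survival curves, RMST-scale C0/tau, censoring model)."""

    design: SimDesign
    L: float
    grid_size: int = 500

    def _grid(self) -> np.ndarray:
        return np.linspace(0.0, self.L, self.grid_size + 1)[1:]

    def _cens_model(self) -> CensoringModel:
        d = self.design
        grid = self._grid()
        if d.censoring == "none":
            return CensoringModel(np.empty(0), np.empty(0))
        if d.censoring in ("a", "b"):
            b = 50.0 if d.censoring == "a" else 100.0
            tgrid = grid[grid < b * (1 - 1e-9)]
            H = -np.log1p(-tgrid / b)
            return CensoringModel(tgrid, np.diff(H, prepend=0.0), coef=None)
        # model (c): exponential, rate exp(b0 + 0.1*X1 + 0.2*A)
        coef = np.zeros(6)
        coef[0], coef[5] = 0.1, 0.2
        dH = np.diff(grid, prepend=0.0) * np.exp(d.cens_intercept)
        return CensoringModel(grid, dH, coef=coef)

    def fit(self, history, rng=None) -> SurvivalNuisanceFit:
        d = self.design
        error_model = "normal" if d.family == "aft_model1" else "exp_log"
        grid = self._grid()
        L = self.L

        def curves(X, a) -> StepCurves:
            return StepCurves(grid, _aft_surv_matrix(X, a, d.c, error_model, grid))

        def c0_hat(X):
            return curves(X, 0).rmst(L)

        def tau_hat(X):
            return curves(X, 1).rmst(L) - curves(X, 0).rmst(L)

        return SurvivalNuisanceFit(
            pi_hat=_pi_fns(d), c0_hat=c0_hat, tau_hat=tau_hat,
            fitted_on="oracle", curves=curves, cens=self._cens_model(), L=L)


def true_value_difference(design: SimDesign, n_mc: int = 100_000, rng=None,
                          grid_size: int = 1000) -> float:
    """Monte Carlo value difference ``Psi(d_opt) = V(d_opt) - V(0)`` under the
    design (analytic conditional means averaged over covariate draws)."""
    rng = np.random.default_rng(rng)
    X = _covariates(n_mc, rng)
    if design.family.startswith("model1"):
        tau = model1_tau(X, design.c)
        return float(np.mean(tau * (tau > 0)))
    error_model = "normal" if design.family == "aft_model1" else "exp_log"
    L = design.L if design.L is not None else 42.0
    grid = np.linspace(0.0, L, grid_size + 1)[1:]
    r1 = StepCurves(grid, _aft_surv_matrix(X, 1, design.c, error_model, grid)).rmst(L)
    r0 = StepCurves(grid, _aft_surv_matrix(X, 0, design.c, error_model, grid)).rmst(L)
    tau = r1 - r0
    return float(np.mean(np.where(tau > 0, tau, 0.0)))


# ---------------------------------------------------------------------------
# Monte Carlo harness
# ---------------------------------------------------------------------------

@dataclass
class MonteCarloRow:
    """Summary of one simulation condition: mean and SD of the statistic and
    the rejection rate, with Monte Carlo standard errors."""

    estimator: str
    chunking: str
    c: float
    n: int
    n_reps: int
    mu: float
    sigma: float
    reject_rate: float
    mc_se_mu: float
    mc_se_sigma: float
    mc_se_reject: float
    n_failed: int = 0
    flagged: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self) | {"schema_version": 1}


def monte_carlo(
    design: SimDesign,
    test_config: OneStepConfig,
    n_reps: int,
    seed: int | None = None,
    estimators: Sequence[str] | None = None,
    learner=None,
    per_rep_path=None,
):
    """Run the one-step test on ``n_reps`` independent datasets.

    Returns one :class:`MonteCarloRow` for ``test_config.estimator``, or a
    dict of rows when ``estimators`` lists several score versions (which then
    share data, partitions, nuisance fits and perturbation draws per rep).

    Per-rep failures are recorded and excluded; a row is flagged when more
    than 1% of reps fail.  ``per_rep_path`` optionally writes a CSV of the
    per-replicate statistics.
    """
    if n_reps < 2:
        raise ConfigError("n_reps must be at least 2")
    single = estimators is None
    est_list = [test_config.estimator] if single else list(estimators)
    ss = np.random.SeedSequence(seed)
    stats: dict[str, list] = {e: [] for e in est_list}
    rejects: dict[str, list] = {e: [] for e in est_list}
    n_failed = 0
    for rep_ss in ss.spawn(n_reps):
        data_ss, test_ss = rep_ss.spawn(2)
        cfg = dataclasses.replace(
            test_config, seed=int(test_ss.generate_state(1)[0] % (2**31 - 1)))
        try:
            data = design.sample(np.random.default_rng(data_ss))
            res = run_one_step_tests(data, cfg, est_list, learner=learner)
        except Exception:  # noqa: BLE001 - per-rep failures are tallied
            n_failed += 1
            continue
        for e in est_list:
            stats[e].append(res[e].T)
            rejects[e].append(res[e].rejected)

    if per_rep_path is not None:
        import pandas as pd
        frame = {}
        for e in est_list:
            frame[f"T_{e}"] = stats[e]
            frame[f"reject_{e}"] = np.asarray(rejects[e], dtype=int)
        pd.DataFrame(frame).to_csv(per_rep_path, index_label="rep")

    rows = {}
    flagged = n_failed > 0.01 * n_reps
    for e in est_list:
        t = np.asarray(stats[e], dtype=float)
        r = np.asarray(rejects[e], dtype=bool)
        R = t.size
        mu = float(t.mean()) if R else float("nan")
        sd = float(t.std(ddof=1)) if R > 1 else float("nan")
        rr = float(r.mean()) if R else float("nan")
        rows[e] = MonteCarloRow(
            estimator=e, chunking=test_config.chunking, c=design.c,
            n=design.n, n_reps=R, mu=mu, sigma=sd, reject_rate=rr,
            mc_se_mu=sd / np.sqrt(R) if R else float("nan"),
            mc_se_sigma=sd / np.sqrt(2 * max(R - 1, 1)) if R > 1 else float("nan"),
            mc_se_reject=float(np.sqrt(rr * (1 - rr) / R)) if R else float("nan"),
            n_failed=n_failed, flagged=flagged,
        )
    return rows[est_list[0]] if single else rows
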