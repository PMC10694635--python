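import numpy as np
import pandas as pd
import pytest

from subvaltest.data_model import SurvivalTrialData, UncensoredTrialData
from subvaltest.nuisance import (CensoringModel, NuisanceFit, StepCurves,
                                 SurvivalNuisanceFit)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_table():
    """Six subjects, two covariates, both arms."""
    return pd.DataFrame({
        "A": [0, 1, 0, 1, 0, 1],
        "Y": [1.0, 2.0, 0.5, 2.5, 1.5, 3.0],
        "X1": [0.1, -0.2, 0.3, 0.0, 1.1, -0.5],
        "X2": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
    })


def linear_fit(pi=0.5, tau_shift=-0.5):
    """A smooth synthetic nuisance fit for score algebra tests."""
    return NuisanceFit(
        pi_hat=lambda X: np.full(np.atleast_2d(X).shape[0], pi),
        c0_hat=lambda X: 1.0 + np.atleast_2d(X)[:, 1],
        tau_hat=lambda X: np.atleast_2d(X)[:, 0] + tau_shift,
        fitted_on="synthetic",
    )


def make_survival_fit(times, surv_fn, cens: CensoringModel, L,
                      pi=0.5, c0_fn=None, tau_fn=None):
    """Assemble a synthetic SurvivalNuisanceFit from a per-arm survival-curve
    function ``surv_fn(X, a) -> (n, len(times))`` matrix."""
    times = np.asarray(times, dtype=float)

    def curves(X, a):
        return StepCurves(times, surv_fn(np.atleast_2d(X), a))

    c0 = c0_fn or (lambda X: curves(X, 0).rmst(L))
    tau = tau_fn or (lambda X: curves(X, 1).rmst(L) - curves(X, 0).rmst(L))
    return SurvivalNuisanceFit(
        pi_hat=lambda X: np.full(np.atleast_2d(X).shape[0], pi),
        c0_hat=c0, tau_hat=tau, fitted_on="synthetic",
        curves=curves, cens=cens, L=L)


@pytest.fixture
def small_survival_data(rng):
    """Fifty subjects with moderate uniform censoring."""
    n = 50
    X = rng.normal(size=(n, 3))
    A = rng.integers(0, 2, n)
    A[:4] = [0, 1, 0, 1]
    T = np.exp(1.0 + 0.4 * X[:, 0] + rng.normal(0, 0.5, n))
    C = rng.uniform(0, 8, n)
    U = np.minimum(T, C)
    Delta = (T <= C).astype(int)
    L = float(np.quantile(U, 0.8))
    return SurvivalTrialData(X, A, U, Delta, L, known_pi=0.5)
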