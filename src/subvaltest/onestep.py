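"""The sequential one-step testing engine.

The data are split into an initial nuisance-fitting chunk ``C0`` of size
``ln`` (plus any remainder) and ``rn = floor((n - ln)/m)`` analysis chunks of
size ``m``.  For chunk ``j`` the nuisances are (re)fit on the historical set
``O*_{j-1} = C0 u C1 u ... u C_{j-1}`` and frozen; the chunk's value
difference ``Psi_hat_j`` is the mean score over its ``m`` subjects, and its
conditional standard deviation ``sigma_hat_j`` is estimated from the
historical subjects only.  The standardized statistic

    ``T = rn^{-1/2} * sum_j Psi_hat_j / sigma_hat_j``

is asymptotically standard normal under the null hypothesis of no benefiting
subgroup — including at the exceptional law where ``pr{tau(X) = 0} > 0`` —
so the one-sided test rejects when ``T > z_{1-alpha}``.

Two chunk-allocation schemes are provided: treatment-blind random allocation
(SBT) with the pooled variance estimator, and propensity-matched allocation
(SAP-match) which fixes each chunk's treated count at ``m * pi`` and uses the
arm-stratified variance estimator; stratification never increases the
conditional variance, which can translate into more power.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm

from .data_model import (ChunkResult, ConfigError, DataError, Partition,
                         SurvivalTrialData, TestResult, UncensoredTrialData)
from .nuisance import get_learner
from .scores import (SURVIVAL_ESTIMATORS, UNCENSORED_ESTIMATORS,
                     score_vectors_survival, score_vectors_uncensored)

__all__ = [
    "OneStepConfig", "partition_sbt", "partition_sap_match",
    "chunk_variance_pooled", "chunk_variance_stratified",
    "assemble_statistic", "run_one_step_test", "run_one_step_tests",
]


def default_q_floor(j: int) -> float:
    """Variance floor q_j = 1e-3 / j: positive, vanishing in j."""
    return 1e-3 / j


@dataclass
class OneStepConfig:
    """Configuration of one test run.

    ``ln`` defaults to ``floor(n/2)``; ``refit_stride`` > 1 refreshes the
    nuisance fits only every that many chunks (the stale fit is still
    measurable with respect to the history, so validity is unaffected).
    """

    estimator: str = "aipw"
    chunking: str = "sbt"  # "sbt" | "sap-match"
    m: int = 10
    ln: int | None = None
    alpha: float = 0.05
    refit_stride: int = 1
    seed: int | None = None
    learner: object | str | None = None
    learner_params: dict = field(default_factory=dict)
    q_floor: Callable[[int], float] | None = None
    max_trunc_frac: float = 0.1

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["learner"] = self.learner if isinstance(self.learner, (str, type(None))) \
            else type(self.learner).__name__
        d["q_floor"] = "1e-3/j" if self.q_floor is None else repr(self.q_floor)
        return d


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

def partition_sbt(n: int, ln: int, m: int, rng) -> Partition:
    """Treatment-blind random partition: a uniform permutation, the first
    ``ln`` plus any remainder going to C0, then blocks of ``m``."""
    if n - ln < m:
        raise ConfigError(f"need n - ln >= m, got n={n}, ln={ln}, m={m}")
    rng = np.random.default_rng(rng)
    perm = rng.permutation(n)
    rn = (n - ln) // m
    n0 = n - rn * m
    chunks = [perm[n0 + j * m: n0 + (j + 1) * m] for j in range(rn)]
    return Partition(perm[:n0], chunks)


def _treated_counts(rn: int, m: int, pi: float) -> np.ndarray:
    """Deterministic largest-remainder allocation of treated slots: chunk j
    gets ``floor(j*m*pi) - floor((j-1)*m*pi)`` so the running average per-chunk
    treated count tracks ``m * pi`` exactly."""
    cum = np.floor(np.arange(rn + 1) * m * pi + 1e-9).astype(int)
    return np.diff(cum)


def partition_sap_match(A: np.ndarray, ln: int, m: int, pi: float, rng) -> Partition:
    """Propensity-matched partition: each analysis chunk holds (about)
    ``m * pi`` treated and the rest control subjects, sampled without
    replacement; all remaining subjects form C0.

    ``pi`` is the known randomization probability, or the sample proportion
    of treated subjects when unknown.
    """
    A = np.asarray(A)
    n = A.shape[0]
    if n - ln < m:
        raise ConfigError(f"need n - ln >= m, got n={n}, ln={ln}, m={m}")
    rng = np.random.default_rng(rng)
    rn = (n - ln) // m
    t_counts = _treated_counts(rn, m, pi)
    c_counts = m - t_counts
    treated = rng.permutation(np.flatnonzero(A == 1))
    control = rng.permutation(np.flatnonzero(A == 0))
    if t_counts.sum() > treated.size:
        raise DataError(f"SAP-match infeasible: need {int(t_counts.sum())} "
                        f"treated subjects, have {treated.size}")
    if c_counts.sum() > control.size:
        raise DataError(f"SAP-match infeasible: need {int(c_counts.sum())} "
                        f"control subjects, have {control.size}")
    chunks = []
    it, ic = 0, 0
    for tj, cj in zip(t_counts, c_counts):
        chunk = np.concatenate([treated[it:it + tj], control[ic:ic + cj]])
        it, ic = it + tj, ic + cj
        chunks.append(rng.permutation(chunk))
    initial = np.concatenate([treated[it:], control[ic:]])
    return Partition(initial, chunks)


# ---------------------------------------------------------------------------
# conditional variance estimators
# ---------------------------------------------------------------------------

def _pop_var(s: np.ndarray) -> float:
    return float(np.mean(s**2) - np.mean(s) ** 2)


def chunk_variance_pooled(historical_scores: np.ndarray, m: int, q_j: float) -> float:
    """Pooled (SBT) estimator: ``sigma_j = sqrt(max(q_j, Var_hat(S)/m))``
    with the population variance over the historical scores."""
    s = np.asarray(historical_scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty history")
    return float(np.sqrt(max(q_j, _pop_var(s) / m)))


def chunk_variance_stratified(scores_a0: np.ndarray, scores_a1: np.ndarray,
                              m: int, pi: float, q_j: float) -> float:
    """Arm-stratified (SAP-match) estimator:
    ``sigma_j = sqrt(max(q_j, [pi*Var_hat(S|A=1) + (1-pi)*Var_hat(S|A=0)]/m))``."""
    s0 = np.asarray(scores_a0, dtype=float)
    s1 = np.asarray(scores_a1, dtype=float)
    if s0.size == 0 or s1.size == 0:
        raise ValueError("both arms must be present in the history")
    v = pi * _pop_var(s1) + (1.0 - pi) * _pop_var(s0)
    return float(np.sqrt(max(q_j, v / m)))


def assemble_statistic(psis: Sequence[float], sigmas: Sequence[float],
                       alpha: float):
    """Combine per-chunk estimates into (T, p, psi_pooled, rejected)."""
    psis = np.asarray(psis, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    rn = psis.size
    w = 1.0 / sigmas
    T = float(np.sum(w * psis) / np.sqrt(rn))
    pooled = float(np.sum(w * psis) / np.sum(w))
    p = float(norm.sf(T))
    rejected = bool(T > norm.ppf(1.0 - alpha))
    return T, p, pooled, rejected


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------

def _resolve_learner(config: OneStepConfig, survival: bool):
    if config.learner is not None and not isinstance(config.learner, str):
        return config.learner
    key = config.learner or ("survival_forest" if survival else "forest")
    return get_learner(key, **config.learner_params)


def run_one_step_tests(
    data,
    config: OneStepConfig,
    estimators: Sequence[str] | None = None,
    partition: Partition | None = None,
    learner=None,
) -> dict[str, TestResult]:
    """Run the sequential test once, evaluating several estimators that share
    the same partition, nuisance fits and perturbation draws.

    Returns a dict mapping estimator key to :class:`TestResult`.
    """
    survival = isinstance(data, SurvivalTrialData)
    if not survival and not isinstance(data, UncensoredTrialData):
        raise TypeError("data must be UncensoredTrialData or SurvivalTrialData")
    valid = SURVIVAL_ESTIMATORS if survival else UNCENSORED_ESTIMATORS
    estimators = list(estimators) if estimators is not None else [config.estimator]
    for est in estimators:
        if est not in valid:
            kind = "survival" if survival else "continuous"
            raise ConfigError(f"estimator {est!r} is incompatible with a "
                              f"{kind} outcome (valid: {valid})")

    n = data.n
    ln = n // 2 if config.ln is None else int(config.ln)
    m = int(config.m)
    if n - ln < m:
        raise ConfigError(f"need n - ln >= m, got n={n}, ln={ln}, m={m}")
    q_floor = config.q_floor or default_q_floor

    ss = np.random.SeedSequence(config.seed)
    part_ss, zeta_ss, fit_ss = ss.spawn(3)

    p_hat = float(np.mean(data.A))
    pi_match = data.known_pi if data.known_pi is not None else p_hat
    if partition is None:
        if config.chunking == "sbt":
            partition = partition_sbt(n, ln, m, np.random.default_rng(part_ss))
        elif config.chunking == "sap-match":
            partition = partition_sap_match(
                data.A, ln, m, pi_match, np.random.default_rng(part_ss))
        else:
            raise ConfigError(f"unknown chunking scheme {config.chunking!r}")
    rn = partition.rn

    # one mean-one Exp(1) draw per subject, fixed for the whole run; used
    # only by the perturbed survival scores
    zeta = np.random.default_rng(zeta_ss).exponential(1.0, size=n) \
        if survival and any(e in ("aipws", "caipws") for e in estimators) else None

    learner = learner if learner is not None else _resolve_learner(config, survival)
    fit_rng = np.random.default_rng(fit_ss)

    hist = list(partition.initial)
    svec: dict[str, np.ndarray] = {}
    n_trunc = 0
    psis = {e: [] for e in estimators}
    sigmas = {e: [] for e in estimators}
    traces = {e: [] for e in estimators}
    fit_errors: list[str] = []

    for j in range(1, rn + 1):
        hist_idx = np.asarray(hist, dtype=np.int64)
        if (j - 1) % config.refit_stride == 0:
            try:
                fit = learner.fit(data.subset(hist_idx), fit_rng)
            except DataError as exc:
                raise DataError(f"nuisance fit failed at chunk {j}: {exc}") from exc
            if survival:
                svec, k = score_vectors_survival(data, fit, zeta, estimators)
                n_trunc += k
            else:
                svec = score_vectors_uncensored(data, fit, estimators)
        chunk = partition.chunks[j - 1]
        q_j = q_floor(j)
        for est in estimators:
            s = svec[est]
            if config.chunking == "sap-match":
                sh0 = s[hist_idx][data.A[hist_idx] == 0]
                sh1 = s[hist_idx][data.A[hist_idx] == 1]
                sig = chunk_variance_stratified(sh0, sh1, m, pi_match, q_j)
            else:
                sig = chunk_variance_pooled(s[hist_idx], m, q_j)
            psi = float(np.mean(s[chunk]))
            psis[est].append(psi)
            sigmas[est].append(sig)
            traces[est].append(ChunkResult(j, psi, sig, hist_idx.size))
        hist.extend(chunk)

    results = {}
    n_evals = n * max(1, -(-rn // config.refit_stride))  # refits * subjects
    for est in estimators:
        T, p, pooled, rejected = assemble_statistic(psis[est], sigmas[est],
                                                    config.alpha)
        warn = []
        if survival and n_trunc / n_evals > config.max_trunc_frac:
            warn.append(
                f"Kc floored at {n_trunc} evaluation point(s) "
                f"({n_trunc / n_evals:.1%} of weight evaluations)")
        results[est] = TestResult(
            T=T, p_value=p, psi_pooled=pooled, chunk_trace=traces[est],
            alpha=config.alpha, rejected=rejected, estimator=est,
            chunking=config.chunking, n_truncated_kc=n_trunc,
            warnings=warn, config=config.echo(),
        )
    return results


def run_one_step_test(data, config: OneStepConfig,
                      partition: Partition | None = None,
                      learner=None) -> TestResult:
    """Run the one-step value-difference test for ``config.estimator``."""
    return run_one_step_tests(data, config, [config.estimator],
                              partition=partition, learner=learner)[config.estimator]
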