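"""Independent, literal evaluators of the value-difference score formulas.

These deliberately re-derive every score from scratch, term by term, with no
shared code with the package: indicator functions are spelled out, the
censoring-martingale integral is evaluated as an explicit Stieltjes sum over
step points, and the two augmentation terms of the censoring-augmented score
are computed separately (not via the shared-integral simplification the
package uses).  Used as oracles in the test suite.
"""

from __future__ import annotations

import numpy as np


def ind(b) -> float:
    return 1.0 if b else 0.0


def pi_a_of(a: int, pi: float) -> float:
    return a * pi + (1 - a) * (1 - pi)


def ipw_score(y, a, pi, c0, tau) -> float:
    """Value-difference score, AIPW-for-optimal-rule minus IPW-for-control."""
    d = ind(tau > 0)
    w = ind(a == d) / pi_a_of(a, pi)
    return w * y - (w - 1.0) * (c0 + tau * d) - ind(a == 0) / (1 - pi) * y


def aipw_score(y, a, pi, c0, tau) -> float:
    return ipw_score(y, a, pi, c0, tau) + (ind(a == 0) / (1 - pi) - 1.0) * c0


def ipws_score(ul, dl, a, pi, c0, tau, kc_ul, zeta=1.0) -> float:
    """Censored-outcome value-difference score on the RMST scale."""
    d = ind(tau > 0)
    w = ind(a == d) / pi_a_of(a, pi)
    return (dl * w / kc_ul * ul
            - (w - 1.0) * zeta * (c0 + tau * d)
            - dl * ind(a == 0) / (kc_ul * (1 - pi)) * ul)


def aipws_score(ul, dl, a, pi, c0, tau, kc_ul, zeta) -> float:
    return (ipws_score(ul, dl, a, pi, c0, tau, kc_ul, zeta)
            + (ind(a == 0) / (1 - pi) - 1.0) * c0)


def martingale_integral(ul, dl, step_times, step_dlam, kc_at, m_at) -> float:
    """Direct Stieltjes evaluation of ``int_0^L dMc(r)/Kc(r) * m(r)``.

    ``dMc(r) = dNc(r) - Y(r) dLambda_c(r)`` where ``Nc`` jumps at the
    observed time when the subject is censored before the truncation time
    (``dl == 0``) and ``Y(r) = 1(U >= r)`` is the at-risk process.
    ``kc_at`` / ``m_at`` are scalar functions of time.
    """
    total = 0.0
    if dl == 0:
        total += m_at(ul) / kc_at(ul)
    for t, dlam in zip(step_times, step_dlam):
        if t <= ul:  # at risk up to and including ul
            total -= dlam / kc_at(t) * m_at(t)
    return total


def caipws_score(ul, dl, a, pi, c0, tau, kc_ul, zeta,
                 step_times, step_dlam, kc_at, m_at) -> float:
    """Censoring-augmented score with the two augmentation terms evaluated
    separately, exactly as printed."""
    d = ind(tau > 0)
    integral = martingale_integral(ul, dl, step_times, step_dlam, kc_at, m_at)
    term_opt = ind(a == d) / pi_a_of(a, pi) * integral
    term_ctrl = ind(a == 0) / (1 - pi) * integral
    return (aipws_score(ul, dl, a, pi, c0, tau, kc_ul, zeta)
            + term_opt - term_ctrl)


def residual_rmst(times, surv, r, L) -> float:
    """Brute-force E[min(T, L) | T >= r] for a discrete step curve: iterate
    over atoms of the distribution."""
    prev = 1.0
    num = 0.0
    for t, s in zip(times, surv):
        if r < t <= L:
            num += t * (prev - s)
        prev = s
    sL = 1.0
    for t, s in zip(times, surv):
        if t <= L:
            sL = s
    sr = 1.0
    for t, s in zip(times, surv):
        if t <= r:
            sr = s
    return (num + L * sL) / sr
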