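"""Univariate Cox proportional-hazards screen for a single binary covariate.

This is the scoring engine behind split selection in the survival-path
tree: at every candidate bifurcation the landmark survival of a node is
regressed on one binarized covariate and the Wald p-value decides
eligibility. The partial likelihood uses Efron's tie correction; the single
parameter is maximized by Newton iterations with step-halving. Monotone
likelihoods (complete separation of events by the covariate) push the
coefficient to infinity — such fits are flagged ineligible instead of
raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CoxScreenResult:
    """Outcome of one univariate screen.

    ``eligible`` is False when the fit is degenerate (single covariate
    level, fewer than two events, or monotone likelihood); degenerate
    screens carry NaN estimates.
    """

    variable: str
    coefficient: float
    hazard_ratio: float
    se: float
    p_value: float
    n_level0: int
    n_level1: int
    n_events: int
    eligible: bool
    reason: str = ""


_MAX_BETA = 15.0
_MAX_ITER = 60
_TOL = 1e-9


def _efron_terms(times: np.ndarray, events: np.ndarray, x: np.ndarray):
    """Per event-time-group at-risk and tied-event counts by covariate level.

    Returns arrays (A, B) with one row per (group, k) pair such that the
    Efron denominator for that pair is ``A + B * exp(beta)``, plus the total
    count of events in level 1.
    """
    order = np.argsort(times, kind="stable")
    t, e, xv = times[order], events[order].astype(bool), x[order].astype(int)
    n = len(t)
    # at-risk counts just before each index position (risk set = T >= t)
    event_times = np.unique(t[e])
    A_list, B_list, d1_total = [], [], 0
    # suffix counts of x==1 and x==0 for T >= s
    for s in event_times:
        at_risk = t >= s
        n1 = int(np.sum(xv[at_risk]))
        n0 = int(np.sum(at_risk)) - n1
        tied = e & (t == s)
        d = int(np.sum(tied))
        d1 = int(np.sum(xv[tied]))
        d0 = d - d1
        d1_total += d1
        k = np.arange(d)
        A_list.append(n0 - (k / d) * d0)
        B_list.append(n1 - (k / d) * d1)
    A = np.concatenate(A_list) if A_list else np.empty(0)
    B = np.concatenate(B_list) if B_list else np.empty(0)
    return A, B, d1_total


def _loglik(beta: float, A: np.ndarray, B: np.ndarray, d1: int) -> float:
    return beta * d1 - np.sum(np.log(A + B * np.exp(beta)))


def cox_screen(
    x: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    variable: str = "",
) -> CoxScreenResult:
    """Fit ``hazard ~ exp(beta * x)`` for binary ``x`` and report the Wald test.

    Parameters
    ----------
    x : 0/1 covariate per subject.
    times : follow-up times from the landmark.
    events : death indicators (1 = death observed).
    """
    x = np.asarray(x, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n1 = int(np.sum(x == 1))
    n0 = int(np.sum(x == 0))
    n_events = int(np.sum(events))

    def degenerate(reason: str) -> CoxScreenResult:
        return CoxScreenResult(variable, np.nan, np.nan, np.nan, np.nan,
                               n0, n1, n_events, False, reason)

    if n0 + n1 != len(x):
        return degenerate("covariate is not 0/1")
    if n0 == 0 or n1 == 0:
        return degenerate("single covariate level")
    if n_events < 2:
        return degenerate("fewer than two events")

    A, B, d1 = _efron_terms(times, events, x)
    beta = 0.0
    ll = _loglik(beta, A, B, d1)
    converged = False
    for _ in range(_MAX_ITER):
        r = np.exp(beta)
        denom = A + B * r
        grad = d1 - float(np.sum(B * r / denom))
        hess = -float(np.sum(A * B * r / denom**2))
        if hess >= -1e-12:
            break  # flat likelihood: no information
        step = -grad / hess
        # step-halving to guarantee ascent
        new_beta = beta + step
        for _ in range(30):
            if abs(new_beta) <= _MAX_BETA and _loglik(new_beta, A, B, d1) >= ll - 1e-12:
                break
            step /= 2.0
            new_beta = beta + step
        new_ll = _loglik(new_beta, A, B, d1)
        if abs(new_beta - beta) < _TOL or abs(new_ll - ll) < _TOL:
            beta, ll = new_beta, new_ll
            converged = True
            break
        beta, ll = new_beta, new_ll
    if not converged or abs(beta) >= _MAX_BETA - 0.01:
        return degenerate("monotone likelihood or non-convergence")

    r = np.exp(beta)
    denom = A + B * r
    info = float(np.sum(A * B * r / denom**2))
    if info <= 0 or not np.isfinite(info):
        return degenerate("singular information")
    se = 1.0 / np.sqrt(info)
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return CoxScreenResult(variable, float(beta), float(np.exp(beta)), float(se),
                           float(p), n0, n1, n_events, True)
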