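"""Survival statistics implemented from first principles.

Kaplan-Meier product-limit curves, the two-group log-rank test with
hypergeometric variance, the maximally selected rank statistic cutpoint for
a continuous marker, and univariate Cox proportional hazards (Breslow tie
handling, Newton-Raphson on the partial likelihood).

The cutpoint scan maximizes the absolute standardized log-rank statistic
over all observed marker values whose induced split leaves at least
``minprop`` of the cohort on each side.  The p-value reported for the
selected split comes from the ordinary chi-square reference and is flagged
``selection_biased``: scanning many candidate splits inflates the statistic,
and no selection correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import ClinicalTable

__all__ = [
    "SurvivalCurve",
    "LogrankResult",
    "CutpointResult",
    "CoxResult",
    "km_curve",
    "logrank_test",
    "optimal_cutpoint",
    "cox_univariate",
]


class SurvivalError(ValueError):
    pass


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate at the distinct observed times."""

    times: np.ndarray  # distinct observed times, ascending
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # S(t) just after each time

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogrankResult:
    chi2: float
    p: float
    observed: tuple[float, float]
    expected: tuple[float, float]


@dataclass
class CutpointResult:
    cutpoint: float
    max_abs_standardized_statistic: float
    candidates: np.ndarray
    statistics: np.ndarray
    minprop: float
    p: float = float("nan")
    p_flag: str = "selection_biased, uncorrected"


@dataclass
class CoxResult:
    beta: float
    hr: float
    se: float
    wald_z: float
    p: float
    ci95: tuple[float, float]
    n_iter: int
    converged: bool
    flags: list[str] = field(default_factory=list)
    tie_method: str = "breslow"


def _extract(clinical: ClinicalTable, mask=None):
    time = clinical.time
    event = clinical.event
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        time, event = time[mask], event[mask]
    return time, event


def km_curve(clinical: ClinicalTable, group_mask=None) -> SurvivalCurve:
    """Kaplan-Meier estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    Censored-only times reduce the risk set but leave S unchanged.
    """
    time, event = _extract(clinical, group_mask)
    if len(time) == 0:
        raise SurvivalError("empty group")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    distinct = np.unique(time)
    n = len(time)
    at_risk = np.empty(len(distinct), dtype=int)
    d = np.empty(len(distinct), dtype=int)
    surv = np.empty(len(distinct))
    s = 1.0
    for i, t in enumerate(distinct):
        at_risk[i] = int(np.sum(time >= t))
        d[i] = int(np.sum((time == t) & (event == 1)))
        if d[i] > 0:
            s *= 1.0 - d[i] / at_risk[i]
        surv[i] = s
    return SurvivalCurve(distinct, at_risk, d, surv)


def _logrank_o_e_v(time, event, group):
    """Observed/expected events in group 1 and hypergeometric variance,
    summed over distinct event times."""
    event_times = np.unique(time[event == 1])
    O1 = E1 = V = 0.0
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        dying = (time == t) & (event == 1)
        d = dying.sum()
        d1 = (dying & group).sum()
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return O1, E1, V, float(event.sum())


def logrank_test(clinical: ClinicalTable, groups) -> LogrankResult:
    """Two-group log-rank: chi2 = (O1 - E1)^2 / V, p from chi-square(1)."""
    time, event = _extract(clinical)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise SurvivalError(f"need two groups, got {len(levels)}")
    g1 = groups == levels[1]
    O1, E1, V, total_events = _logrank_o_e_v(time, event, g1)
    if total_events == 0:
        raise SurvivalError("no events in either group")
    if V == 0:
        chi2 = 0.0
    else:
        chi2 = (O1 - E1) ** 2 / V
    p = float(stats.chi2.sf(chi2, df=1))
    O0 = total_events - O1
    return LogrankResult(float(chi2), p, (O0, float(O1)), (total_events - E1, E1))


def _standardized_logrank(time, event, group) -> float:
    """(O1 - E1) / sqrt(V); 0 when V = 0."""
    O1, E1, V, _ = _logrank_o_e_v(time, event, group)
    return 0.0 if V == 0 else (O1 - E1) / np.sqrt(V)


def optimal_cutpoint(
    values, clinical: ClinicalTable, minprop: float = 0.1
) -> CutpointResult:
    """Maximally selected rank statistic cutpoint.

    Candidates are the observed marker values whose ``value > candidate``
    split leaves at least ``minprop * n`` samples on each side; the returned
    cutpoint maximizes |standardized log-rank statistic|, ties broken toward
    the smaller cutpoint.
    """
    values = np.asarray(values, dtype=float)
    time, event = _extract(clinical)
    if len(values) != len(time):
        raise SurvivalError("marker and clinical table lengths differ")
    if event.sum() < 1:
        raise SurvivalError("need at least one event")
    n = len(values)
    candidates = []
    zs = []
    for v in np.unique(values):
        high = values > v
        n_high = high.sum()
        if n_high < minprop * n or (n - n_high) < minprop * n or n_high == 0:
            continue
        candidates.append(v)
        zs.append(_standardized_logrank(time, event, high))
    if not candidates:
        raise SurvivalError(
            f"no admissible candidate split at minprop={minprop} (n={n})"
        )
    candidates = np.asarray(candidates)
    zs = np.asarray(zs)
    best = int(np.argmax(np.abs(zs)))  # argmax takes the first = smallest value
    chi2 = zs[best] ** 2
    p = float(stats.chi2.sf(chi2, df=1))
    return CutpointResult(
        cutpoint=float(candidates[best]),
        max_abs_standardized_statistic=float(abs(zs[best])),
        candidates=candidates,
        statistics=zs,
        minprop=minprop,
        p=p,
    )


def _cox_loglik_derivs(beta: float, time, event, x):
    """Breslow partial log-likelihood and its first two derivatives.

    Subjects sorted by descending time let risk-set sums accumulate in one
    pass; ties at an event time share the same risk set (Breslow).
    """
    order = np.argsort(-time, kind="stable")
    t, e, xv = time[order], event[order], x[order]
    eta = beta * xv
    w = np.exp(eta)
    ll = 0.0
    d1 = 0.0
    d2 = 0.0
    s0 = s1 = s2 = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            s0 += w[j]
            s1 += w[j] * xv[j]
            s2 += w[j] * xv[j] ** 2
            j += 1
        for k in range(i, j):
            if e[k] == 1:
                ll += eta[k] - np.log(s0)
                mean = s1 / s0
                d1 += xv[k] - mean
                d2 -= s2 / s0 - mean**2
        i = j
    return ll, d1, d2


def cox_univariate(
    covariate, clinical: ClinicalTable, tol: float = 1e-8, max_iter: int = 50
) -> CoxResult:
    """Univariate Cox PH fit by Newton-Raphson (Breslow ties).

    Reports beta, hazard ratio, SE from the observed information, Wald z/p
    and 95% CI.  Non-convergence or a monotone likelihood (perfect
    separation) is flagged on the result, never silently returned.
    """
    x = np.asarray(covariate, dtype=float)
    time, event = _extract(clinical)
    if len(x) != len(time):
        raise SurvivalError("covariate and clinical table lengths differ")
    if event.sum() < 2:
        raise SurvivalError("need >= 2 events for a Cox fit")
    if np.ptp(x) == 0:
        raise SurvivalError("covariate is constant")
    beta = 0.0
    flags: list[str] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ll, d1, d2 = _cox_loglik_derivs(beta, time, event, x)
        if d2 >= 0 or not np.isfinite(d2):
            flags.append("singular_information")
            break
        step = -d1 / d2
        if abs(step) > 5.0:  # damp runaway steps (near-separation)
            step = np.sign(step) * 5.0
        beta += step
        if abs(step) < tol:
            converged = True
            break
        if abs(beta) > 50:
            flags.append("monotone_likelihood")
            break
    if not converged and not flags:
        flags.append("not_converged")
    _, _, d2 = _cox_loglik_derivs(beta, time, event, x)
    se = float(np.sqrt(-1.0 / d2)) if d2 < 0 else float("nan")
    z = beta / se if se > 0 else float("nan")
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else float("nan")
    ci = (float(np.exp(beta - 1.959964 * se)), float(np.exp(beta + 1.959964 * se)))
    return CoxResult(
        beta=float(beta),
        hr=float(np.exp(beta)),
        se=se,
        wald_z=float(z),
        p=p,
        ci95=ci,
        n_iter=n_iter,
        converged=converged,
        flags=flags,
    )


def cox_score_test_at_zero(covariate, clinical: ClinicalTable) -> float:
    """Score test chi2 at beta = 0; for a binary covariate this equals the
    log-rank chi2."""
    x = np.asarray(covariate, dtype=float)
    time, event = _extract(clinical)
    _, d1, d2 = _cox_loglik_derivs(0.0, time, event, x)
    return float(d1**2 / -d2)
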