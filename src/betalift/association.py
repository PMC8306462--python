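"""Frequentist effect estimation for the 2x2 stratum-by-outcome table.

Odds ratio with likelihood-ratio (profile) confidence intervals,
closed-form Wald intervals as a labelled alternative, and univariate
logistic regression whose binary-predictor fit must reproduce the 2x2
closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .cohort import PatientRecord, TwoByTwoTable
from .errors import ConfigError, DataError, SeparationError

__all__ = [
    "ORResult",
    "odds_ratio",
    "or_confint_profile",
    "or_confint_wald",
    "logistic_univariate",
]


@dataclass(frozen=True)
class ORResult:
    """Odds ratio with a confidence interval."""

    odds_ratio: float
    ci_lower: float
    ci_upper: float
    level: float
    method: str  # profile-likelihood | wald

    def __post_init__(self) -> None:
        if self.method not in ("profile-likelihood", "wald"):
            raise ConfigError(f"unknown CI method {self.method!r}")
        if not (self.ci_lower < self.odds_ratio < self.ci_upper):
            raise DataError(
                f"degenerate interval: {self.ci_lower} < {self.odds_ratio} "
                f"< {self.ci_upper} violated"
            )


def odds_ratio(table: TwoByTwoTable, *, haldane: bool = False) -> float:
    """Unadjusted odds ratio (a*d)/(b*c), arm1 exposed, success first.

    ``haldane=True`` adds 0.5 to every cell (Haldane–Anscombe) so
    tables with a zero cell stay computable; off by default, in which
    case a zero cell raises :class:`DataError`.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) <= 0:
        raise DataError(
            "odds ratio undefined with a zero cell; enable the "
            "Haldane–Anscombe correction (haldane=True)"
        )
    return (a * d) / (b * c)


def _loglik_2x2(theta: float, b0: float, table: TwoByTwoTable) -> float:
    """Binomial log-likelihood of the 2x2 model.

    Arm1 success log-odds is ``b0 + theta``; arm2's is ``b0``; ``theta``
    is the log odds ratio.
    """
    eta1, eta2 = b0 + theta, b0
    ll = (table.a * eta1 - (table.a + table.b) * np.logaddexp(0.0, eta1)
          + table.c * eta2 - (table.c + table.d) * np.logaddexp(0.0, eta2))
    return float(ll)


def _profile_loglik(theta: float, table: TwoByTwoTable) -> float:
    # concave in b0; bounded search is robust for extreme tables
    res = optimize.minimize_scalar(
        lambda b0: -_loglik_2x2(theta, b0, table),
        bounds=(-40.0, 40.0),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return -float(res.fun)


def or_confint_profile(table: TwoByTwoTable, level: float = 0.95) -> ORResult:
    """Profile-likelihood (log-likelihood-ratio) CI for the 2x2 odds ratio.

    The bounds are the two roots in log-OR of
    ``2 * (l(theta_hat) - l_profile(theta)) = chi2_1(level)``,
    found by bracketed root-finding; tolerance 1e-8 on the log-OR scale.
    """
    if not (0.0 < level < 1.0):
        raise ConfigError(f"level must be in (0,1), got {level}")
    point = odds_ratio(table)
    theta_hat = math.log(point)
    ll_hat = _loglik_2x2(theta_hat, math.log(table.c / table.d), table)
    target = stats.chi2.ppf(level, df=1)

    def deviance_gap(theta: float) -> float:
        return 2.0 * (ll_hat - _profile_loglik(theta, table)) - target

    bounds = []
    for direction in (-1.0, +1.0):
        step, edge = 0.5, theta_hat
        while deviance_gap(edge + direction * step) < 0:
            step *= 2.0
            if step > 64.0:
                raise DataError(
                    "profile CI bracketing failed (degenerate table); "
                    "consider the Wald interval"
                )
        lo, hi = sorted((edge, edge + direction * step))
        root = optimize.brentq(deviance_gap, lo, hi, xtol=1e-10)
        bounds.append(math.exp(root))
    return ORResult(point, bounds[0], bounds[1], level, "profile-likelihood")


def or_confint_wald(table: TwoByTwoTable, level: float = 0.95) -> ORResult:
    """Closed-form Wald CI: exp(log OR +/- z * sqrt(1/a+1/b+1/c+1/d))."""
    if not (0.0 < level < 1.0):
        raise ConfigError(f"level must be in (0,1), got {level}")
    point = odds_ratio(table)
    se = math.sqrt(1 / table.a + 1 / table.b + 1 / table.c + 1 / table.d)
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    return ORResult(point, point * math.exp(-z * se), point * math.exp(z * se),
                    level, "wald")


def _logistic_nll(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ beta
    return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    res = optimize.minimize(
        _logistic_nll, np.zeros(X.shape[1]), args=(X, y),
        jac=lambda b, X, y: X.T @ (1.0 / (1.0 + np.exp(-(X @ b))) - y),
        method="BFGS", options={"gtol": 1e-10, "maxiter": 500},
    )
    return res.x, -res.fun


def _profile_ci_coef(
    X: np.ndarray, y: np.ndarray, j: int, beta_hat: np.ndarray,
    ll_hat: float, level: float,
) -> tuple[float, float]:
    """Profile-likelihood CI for coefficient ``j`` of a logistic fit."""
    target = stats.chi2.ppf(level, df=1)
    others = [k for k in range(X.shape[1]) if k != j]
    Xo, xj = X[:, others], X[:, j]

    def profile_ll(bj: float) -> float:
        offset = bj * xj
        def nll(bo: np.ndarray) -> float:
            eta = Xo @ bo + offset
            return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)
        res = optimize.minimize(nll, beta_hat[others], method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 500})
        return -res.fun

    def gap(bj: float) -> float:
        return 2.0 * (ll_hat - profile_ll(bj)) - target

    out = []
    for direction in (-1.0, +1.0):
        step = 0.5
        while gap(beta_hat[j] + direction * step) < 0:
            step *= 2.0
            if step > 64.0:
                raise SeparationError(
                    "profile bracketing failed; likelihood is flat in one "
                    "direction (quasi-separation)"
                )
        lo, hi = sorted((beta_hat[j], beta_hat[j] + direction * step))
        out.append(optimize.brentq(gap, lo, hi, xtol=1e-10))
    return out[0], out[1]


def _extract_predictor(records: Sequence[PatientRecord], predictor: str):
    if predictor == "stratum":
        return [r.stratum for r in records], [r.outcome for r in records]
    xs, ys = [], []
    for r in records:
        if predictor in r.covariates:
            xs.append(r.covariates[predictor])
            ys.append(r.outcome)
    if not xs:
        raise DataError(f"no records carry covariate {predictor!r}")
    return xs, ys


def logistic_univariate(
    records: Sequence[PatientRecord],
    predictor: str,
    *,
    reference: str | None = None,
    level: float = 0.95,
) -> dict[str, ORResult]:
    """Univariate logistic regression of the outcome on one predictor.

    ``predictor`` is ``"stratum"`` or a covariate name. Categorical
    predictors are dummy-coded against ``reference`` (default: first
    level in sorted order) and yield one :class:`ORResult` per
    non-reference level; a numeric predictor yields a single per-unit
    OR keyed by the predictor name. CIs are profile-likelihood.

    Raises
    ------
    SeparationError
        If some predictor level has all-identical outcomes (complete
        separation), naming the level.
    """
    xs, ys = _extract_predictor(records, predictor)
    y = np.asarray(ys, dtype=float)
    numeric = all(isinstance(v, (int, float)) and not isinstance(v, bool)
                  for v in xs)
    if numeric:
        x = np.asarray(xs, dtype=float)
        X = np.column_stack([np.ones_like(x), x])
        names = [predictor]
    else:
        levels = sorted({str(v) for v in xs})
        if reference is None:
            reference = levels[0]
        if reference not in levels:
            raise ConfigError(f"reference level {reference!r} not observed")
        non_ref = [lvl for lvl in levels if lvl != reference]
        for lvl in levels:
            sub = y[np.asarray([str(v) == lvl for v in xs])]
            if sub.size and (sub.min() == sub.max()):
                raise SeparationError(
                    f"complete separation: level {lvl!r} of {predictor!r} "
                    f"has uniformly outcome {int(sub[0])}"
                )
        X = np.column_stack(
            [np.ones(len(xs))]
            + [np.asarray([1.0 if str(v) == lvl else 0.0 for v in xs])
               for lvl in non_ref]
        )
        names = non_ref
    beta_hat, ll_hat = _fit_logistic(X, y)
    results: dict[str, ORResult] = {}
    for idx, name in enumerate(names, start=1):
        lo, hi = _profile_ci_coef(X, y, idx, beta_hat, ll_hat, level)
        results[name] = ORResult(
            math.exp(beta_hat[idx]), math.exp(lo), math.exp(hi),
            level, "profile-likelihood",
        )
    return results
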