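"""Conjugate beta-binomial algebra.

Data-only ("likelihood") beta distributions, prior elicitation,
posterior updates, means, quantiles and equal-tailed credible
intervals.

Conventions
-----------
The data-only distribution of a rate given ``s`` successes and ``f``
failures is ``Beta(s, f)`` (not ``Beta(s+1, f+1)``); it therefore
requires at least one event of each kind. Posterior updates add
observed counts to the prior shape parameters and accept zero counts.
Credible intervals are equal-tailed only, from the beta quantile
function.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .cohort import ArmCounts
from .errors import ConfigError, DataError

__all__ = [
    "BetaParams",
    "CredibleInterval",
    "beta_mean",
    "likelihood_beta",
    "posterior_update",
    "beta_quantile",
    "beta_cdf",
    "credible_interval",
]


@dataclass(frozen=True)
class BetaParams:
    """A beta distribution by its two positive shape parameters."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ConfigError(
                f"beta shape parameters must be positive, got "
                f"({self.alpha}, {self.beta})"
            )

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class CredibleInterval:
    """Equal-tailed credible interval at the given level."""

    lower: float
    upper: float
    level: float

    def __post_init__(self) -> None:
        if not (0.0 < self.lower < self.upper < 1.0):
            raise DataError(
                f"interval must satisfy 0 < lower < upper < 1, got "
                f"({self.lower}, {self.upper})"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower


def beta_mean(params: BetaParams) -> float:
    """Mean of a beta distribution: alpha / (alpha + beta)."""
    return params.mean


def likelihood_beta(counts: ArmCounts) -> BetaParams:
    """Data-only beta distribution ``Beta(successes, failures)``.

    Raises
    ------
    DataError
        If either count is zero — the distribution would be improper at
        a boundary under this convention; supply a proper prior and use
        :func:`posterior_update` instead.
    """
    if counts.successes < 1 or counts.failures < 1:
        raise DataError(
            "data-only beta distribution needs at least one success and one "
            "failure; with boundary counts, supply a proper prior and use "
            "posterior_update instead"
        )
    return BetaParams(float(counts.successes), float(counts.failures))


def posterior_update(prior: BetaParams, counts: ArmCounts) -> BetaParams:
    """Conjugate update: ``Beta(prior.alpha + s, prior.beta + f)``."""
    return BetaParams(prior.alpha + counts.successes,
                      prior.beta + counts.failures)


def beta_quantile(params: BetaParams, q: float) -> float:
    """Beta quantile function (inverse regularized incomplete beta)."""
    if not (0.0 < q < 1.0):
        raise ConfigError(f"quantile order must be in (0,1), got {q}")
    return float(stats.beta.ppf(q, params.alpha, params.beta))


def beta_cdf(params: BetaParams, x: float) -> float:
    """Beta CDF (regularized incomplete beta function)."""
    if x <= 0.0:
        return 0.0
    if x >= 1.0:
        return 1.0
    return float(stats.beta.cdf(x, params.alpha, params.beta))


def credible_interval(params: BetaParams, level: float = 0.95) -> CredibleInterval:
    """Equal-tailed interval ``[Q((1-level)/2), Q(1-(1-level)/2)]``."""
    if not (0.0 < level < 1.0):
        raise ConfigError(f"credible level must be in (0,1), got {level}")
    tail = (1.0 - level) / 2.0
    return CredibleInterval(
        lower=beta_quantile(params, tail),
        upper=beta_quantile(params, 1.0 - tail),
        level=level,
    )
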