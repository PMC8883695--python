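"""Bayesian linear regression and Bayes-factor tests of testable implications.

Each testable implication of a DAG states that a partial regression
coefficient beta_{YX|Z} -- the coefficient of X in the regression of Y on
{X} | Z -- either vanishes or does not.  The implication is checked with the
Bayes factor BF01 for H0: beta = 0 against H1: beta != 0 at threshold 1:
BF01 > 1 favors the null, BF01 < 1 the alternative.

The regression model places independent N(0, prior_sd^2) priors on the slope
coefficients and a flat prior on the intercept (handled by mean-centering),
which is the Bayesian counterpart of ridge regression.  The residual variance
is set by an empirical-Bayes plug-in (the OLS residual variance of the full
model), so the slope posterior is Gaussian in closed form and BF01 is the
Savage-Dickey density ratio

    BF01 = p(beta = 0 | data, H1) / p(beta = 0 | H1),

the posterior over prior density of the coefficient of interest at zero.
This equals the marginal-likelihood ratio of the restricted (beta = 0) model
to the full model under the same priors, and is deterministic given the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphs import Node
from .scm import SampleMatrix

__all__ = [
    "RegressionSpec",
    "PosteriorFit",
    "BfResult",
    "SingularDesignError",
    "InsufficientDataError",
    "fit_bayes_linreg",
    "bf01",
    "check_implication",
]


class SingularDesignError(np.linalg.LinAlgError):
    """The design matrix is rank deficient after centering."""


class InsufficientDataError(ValueError):
    """Too few rows for the requested regression."""


@dataclass(frozen=True)
class RegressionSpec:
    """Outcome ~ regressor_of_interest + adjustment (+ intercept)."""

    outcome: Node
    regressor: Node
    adjustment: frozenset[Node] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "adjustment", frozenset(self.adjustment))
        if self.outcome == self.regressor:
            raise ValueError("outcome and regressor must differ")
        if self.outcome in self.adjustment or self.regressor in self.adjustment:
            raise ValueError("adjustment set must exclude outcome and regressor")

    @property
    def regressors(self) -> tuple[Node, ...]:
        """All right-hand-side variables, canonical (sorted) order."""
        return tuple(sorted({self.regressor} | self.adjustment))


@dataclass(frozen=True)
class PosteriorFit:
    """Gaussian slope posterior of one Bayesian ridge regression."""

    outcome: Node
    names: tuple[Node, ...]
    mean: np.ndarray          # posterior means, aligned with names
    cov: np.ndarray           # posterior covariance
    ols: np.ndarray           # least-squares estimates, aligned with names
    sigma2: float             # plug-in residual variance
    prior_sd: float
    n: int

    def coefficient(self, name: Node) -> tuple[float, float]:
        """Posterior (mean, sd) of one slope."""
        j = self.names.index(name)
        return float(self.mean[j]), float(np.sqrt(self.cov[j, j]))


@dataclass(frozen=True)
class BfResult:
    """Savage-Dickey test summary for one coefficient."""

    coefficient_posterior_mean: float
    coefficient_posterior_sd: float
    bf01: float
    null_favored: bool

    def __post_init__(self) -> None:
        if not (np.isfinite(self.bf01) and self.bf01 > 0):
            raise ValueError("bf01 must be finite and positive")
        if self.null_favored != (self.bf01 > 1):
            raise ValueError("null_favored inconsistent with bf01")


def _fit(
    data: SampleMatrix,
    outcome: Node,
    regressors: tuple[Node, ...],
    prior_sd: float,
) -> PosteriorFit:
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    y = data.column(outcome)
    x = np.column_stack([data.column(r) for r in regressors])
    n, p = x.shape
    if n < p + 2:
        raise InsufficientDataError(
            f"need at least {p + 2} rows for {p} regressors plus intercept, got {n}"
        )
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    gram = xc.T @ xc
    xty = xc.T @ yc
    # Rank check on the centered design via the Gram spectrum.
    eig = np.linalg.eigvalsh(gram)
    if eig[0] <= max(n, eig[-1]) * 1e-12:
        raise SingularDesignError("rank-deficient design matrix")
    ols = np.linalg.solve(gram, xty)
    rss = float(yc @ yc - ols @ xty)
    sigma2 = max(rss, 0.0) / (n - p - 1)
    lam = sigma2 / prior_sd**2
    a = gram + lam * np.eye(p)
    mean = np.linalg.solve(a, xty)
    cov = sigma2 * np.linalg.inv(a)
    return PosteriorFit(
        outcome=outcome,
        names=tuple(regressors),
        mean=mean,
        cov=cov,
        ols=ols,
        sigma2=sigma2,
        prior_sd=prior_sd,
        n=n,
    )


def fit_bayes_linreg(
    data: SampleMatrix,
    spec: RegressionSpec,
    prior_sd: float = 1.0,
    cache: dict | None = None,
) -> PosteriorFit:
    """Conjugate Gaussian posterior for all slopes of ``spec``'s regression.

    ``cache`` (optional dict) memoizes fits by (outcome, regressor set,
    prior_sd): specs that share a full model -- e.g. beta_{YX|C} and
    beta_{YC|X} -- are then fit once.
    """
    key = (spec.outcome, spec.regressors, float(prior_sd))
    if cache is not None and key in cache:
        return cache[key]
    fit = _fit(data, spec.outcome, spec.regressors, prior_sd)
    if cache is not None:
        cache[key] = fit
    return fit


def bf01(
    data: SampleMatrix,
    spec: RegressionSpec,
    prior_sd: float = 1.0,
    cache: dict | None = None,
) -> BfResult:
    """Savage-Dickey BF01 for H0: beta = 0 on the coefficient of interest."""
    fit = fit_bayes_linreg(data, spec, prior_sd, cache)
    mean, sd = fit.coefficient(spec.regressor)
    if sd == 0.0:
        # Degenerate (noise-free) posterior: overwhelming evidence one way.
        log_bf = np.inf if mean == 0.0 else -np.inf
    else:
        # log N(0; mean, sd^2) - log N(0; 0, prior_sd^2)
        log_bf = np.log(prior_sd / sd) - 0.5 * (mean / sd) ** 2
    # Clip into the open positive reals so downstream decisions stay defined.
    bf = float(np.exp(np.clip(log_bf, -700.0, 700.0)))
    bf = min(max(bf, np.finfo(float).tiny), np.finfo(float).max)
    return BfResult(
        coefficient_posterior_mean=mean,
        coefficient_posterior_sd=sd,
        bf01=bf,
        null_favored=bf > 1,
    )


def check_implication(
    data: SampleMatrix,
    spec: RegressionSpec,
    expected: str,
    prior_sd: float = 1.0,
    cache: dict | None = None,
) -> tuple[bool, BfResult]:
    """Test one implication; return (violated, BF detail).

    ``expected`` is ``"zero"`` (the DAG entails beta = 0; violated when
    BF01 < 1) or ``"nonzero"`` (violated when BF01 > 1).  BF01 == 1 exactly
    never counts as a violation.
    """
    if expected not in ("zero", "nonzero"):
        raise ValueError("expected must be 'zero' or 'nonzero'")
    result = bf01(data, spec, prior_sd, cache)
    if expected == "zero":
        violated = result.bf01 < 1
    else:
        violated = result.bf01 > 1
    return violated, result
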