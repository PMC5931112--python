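"""A priori power for binary-outcome MR and Bayesian false-null-probability analysis.

Power follows the standard non-centrality argument for an MR estimate of a
binary outcome: with N = cases + controls, case fraction phi, causal log OR
b and instrument PVE rho^2, the Wald statistic is approximately normal with
non-centrality lambda = |b| * sqrt(N * rho^2 * phi * (1 - phi)), giving

    power = Phi(lambda - z_{1-alpha/2}) + Phi(-lambda - z_{1-alpha/2}).

Both rejection tails are included so that power at OR = 1 equals alpha
exactly.

The reliability of a null MR finding is quantified by the Bayesian false null
probability BFNP = 1 - BFDP: the posterior probability that the alternative
is true given the estimate. The Wakefield approximate Bayes factor compares
the marginal likelihood of the estimated log OR under the null, N(0, V), with
a normal prior on the effect under the alternative, theta ~ N(0, W), where W
is calibrated so that a stated "maximum likely OR" is the 97.5th percentile
of the prior:  W = (ln(or_max) / 1.96)^2. Solving BFNP = tau for the prior
probability of association yields the minimum prior that keeps a null finding
believable at level tau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .types import BFNPResult, ValidationError

__all__ = [
    "PowerSpec",
    "power_binary_mr",
    "se_from_ci",
    "wakefield_bf",
    "min_prior_for_bfnp",
    "bfnp",
    "bfnp_analysis",
    "DEFAULT_TAU",
    "DEFAULT_OR_MAX",
]

#: BFNP threshold below which a null finding is considered unreliable.
DEFAULT_TAU = 0.1
#: Maximum likely OR when no observational estimate exists.
DEFAULT_OR_MAX = 2.0


@dataclass(frozen=True)
class PowerSpec:
    """Design of a binary-outcome MR power calculation."""

    n_cases: int
    n_controls: int
    pve: float
    or_alt: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("n_cases and n_controls must be >= 1")
        if not 0 < self.pve < 1:
            raise ValidationError(f"pve must be in (0, 1), got {self.pve}")
        if not self.or_alt > 0:
            raise ValidationError(f"or_alt must be > 0, got {self.or_alt}")
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")


def power_binary_mr(spec: PowerSpec) -> float:
    """Two-sided a priori power of an MR test of a binary outcome."""
    n_total = spec.n_cases + spec.n_controls
    phi = spec.n_cases / n_total
    lam = abs(math.log(spec.or_alt)) * math.sqrt(n_total * spec.pve * phi * (1 - phi))
    z_crit = stats.norm.ppf(1 - spec.alpha / 2)
    return float(stats.norm.cdf(lam - z_crit) + stats.norm.cdf(-lam - z_crit))


def se_from_ci(or_: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Recover (log OR, SE) from an OR with its 95% CI.

    Assumes the CI is symmetric on the log scale with the 1.96 normal
    multiplier; a zero-width CI returns se = 0 (degenerate, flagged by
    downstream checks).
    """
    if not (0 < ci_low <= or_ <= ci_high):
        raise ValidationError(
            f"CI ordering violated: need 0 < {ci_low} <= {or_} <= {ci_high}"
        )
    theta = math.log(or_)
    se = (math.log(ci_high) - math.log(ci_low)) / (2 * 1.96)
    return theta, se


def wakefield_bf(theta_hat: float, se: float, or_max: float) -> float:
    """Approximate Bayes factor of the null against a N(0, W) alternative.

    bf = sqrt((V + W) / V) * exp(-Z^2 W / (2 (V + W))) with V = se^2,
    Z = theta_hat / se and W = (ln(or_max) / 1.96)^2; values above 1 favour
    the null. ``or_max`` is the 97.5th percentile of the prior OR under the
    alternative (protective ORs < 1 enter through |ln|).
    """
    if not se > 0:
        raise ValidationError(f"se must be > 0, got {se}")
    if or_max <= 0 or or_max == 1:
        raise ValidationError(f"or_max must be positive and != 1, got {or_max}")
    v = se * se
    w = (abs(math.log(or_max)) / 1.96) ** 2
    z = theta_hat / se
    return math.sqrt((v + w) / v) * math.exp(-z * z * w / (2 * (v + w)))


def min_prior_for_bfnp(bf: float, tau: float = DEFAULT_TAU) -> float:
    """Smallest prior probability of association for which BFNP exceeds ``tau``.

    Solves 1 / (1 + bf (1 - pi) / pi) = tau:  pi = tau bf / (tau bf + 1 - tau).
    """
    if not bf > 0:
        raise ValidationError(f"bf must be > 0, got {bf}")
    if not 0 < tau < 1:
        raise ValidationError(f"tau must be in (0, 1), got {tau}")
    return tau * bf / (tau * bf + 1 - tau)


def bfnp(bf: float, prior: float) -> float:
    """Bayesian false null probability: posterior probability of association.

    1 - BFDP, i.e. 1 / (1 + bf * (1 - prior) / prior); increasing in the
    prior and decreasing in the Bayes factor.
    """
    if not bf > 0:
        raise ValidationError(f"bf must be > 0, got {bf}")
    if not 0 < prior < 1:
        raise ValidationError(f"prior must be in (0, 1), got {prior}")
    return 1.0 / (1.0 + bf * (1.0 - prior) / prior)


def bfnp_analysis(
    or_: float,
    ci_low: float,
    ci_high: float,
    or_max: float = DEFAULT_OR_MAX,
    tau: float = DEFAULT_TAU,
) -> BFNPResult:
    """Full minimum-prior evaluation of one reported OR (95% CI)."""
    theta, se = se_from_ci(or_, ci_low, ci_high)
    if se == 0:
        raise ValidationError("degenerate CI (zero width): BFNP analysis undefined")
    bf = wakefield_bf(theta, se, or_max)
    return BFNPResult(
        theta_hat=theta,
        v=se * se,
        w=(abs(math.log(or_max)) / 1.96) ** 2,
        z=theta / se,
        bf=bf,
        tau=tau,
        min_prior=min_prior_for_bfnp(bf, tau),
    )
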