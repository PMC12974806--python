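"""Zero-truncated Poisson null model for deficiency-mapped lethal mutations.

A balancer screen observes, per wild chromosome, only whether it is lethal
when homozygous — i.e., whether it carries *at least one* recessive lethal
mutation. If lethal loss-of-function mutations land on chromosomes as a
Poisson process with mean ``lam`` per chromosome, the non-lethal proportion
estimates the Poisson zero class::

    P0 = exp(-lam)            =>   lam = -ln(P0)

and the mean number of lethal mutations on a *lethal* chromosome is the
zero-truncated Poisson mean ``lam / (1 - exp(-lam))``. If every lethal
mutation is single-locus and loss-of-function, crossing ``x1`` lethal
chromosomes to a deficiency panel that interrogates a fraction ``coverage``
of the chromosome should map

    expected = x1 * coverage * lam / (1 - exp(-lam))

mutations. A normal-approximation 95% CI for ``P0`` is propagated through
this transform to bound the expected mapped count. Observing far fewer
mapped mutations than this expectation would indicate that many lethal
chromosomes owe their lethality to unmappable (multigenic or
gain-of-function) effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .frequency_estimation import ProportionEstimate

__all__ = [
    "MappingExpectation",
    "MSBParams",
    "poisson_mean_from_p0",
    "ztp_mean",
    "expected_mapped",
    "expected_mapped_ci",
    "mapping_expectation",
    "msb_equilibrium",
]

#: z quantile used throughout; fixed at 1.96 to match the screen's own
#: normal-approximation interval rather than calling a quantile function.
Z_95 = 1.96


@dataclass(frozen=True)
class MappingExpectation:
    """Full null-model summary for one screen."""

    p0: float
    n: float
    x1: float
    coverage_fraction: float
    lam: float
    ztp_mean: float
    expected_mapped: float
    ci_low: float
    ci_high: float

    def rounded(self) -> tuple[int, int, int]:
        """(expected, ci_low, ci_high) as integers, round-half-to-even."""
        return (
            round(self.expected_mapped),
            round(self.ci_low),
            round(self.ci_high),
        )


@dataclass(frozen=True)
class MSBParams:
    """Mutation-selection balance inputs and equilibrium frequency."""

    mu: float
    s: float
    q_eq: float


def poisson_mean_from_p0(p0: float) -> float:
    """Poisson mean implied by a zero-class proportion: lam = -ln(p0)."""
    if not 0.0 < p0 <= 1.0:
        raise ValueError(f"p0 must be in (0, 1], got {p0!r}")
    return -math.log(p0)


def ztp_mean(lam: float) -> float:
    """Mean of a Poisson(lam) conditioned on being >= 1.

    Continuous at the origin: the limit as lam -> 0 is 1 (a truncated
    Poisson with vanishing rate is a point mass at one).
    """
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam!r}")
    if lam == 0:
        return 1.0
    return lam / (1.0 - math.exp(-lam))


def expected_mapped(x1: float, coverage_fraction: float, lam: float) -> float:
    """Expected number of deficiency-mapped lethal mutations under the null.

    ``x1`` lethal chromosomes, each carrying on average ``ztp_mean(lam)``
    lethal mutations, scanned over ``coverage_fraction`` of the chromosome.
    """
    if not 0.0 <= coverage_fraction <= 1.0:
        raise ValueError(
            f"coverage_fraction must be in [0, 1], got {coverage_fraction!r}"
        )
    if x1 < 0:
        raise ValueError(f"x1 must be >= 0, got {x1!r}")
    return x1 * coverage_fraction * ztp_mean(lam)


def _mapped_at_p0(p0: float, x1: float, coverage_fraction: float) -> float:
    # expected mapped written directly in terms of p0:
    # x1 * coverage * (-ln p0) / (1 - p0); equals expected_mapped because
    # 1 - exp(-lam) = 1 - p0 when lam = -ln(p0).
    return x1 * coverage_fraction * (-math.log(p0)) / (1.0 - p0)


def expected_mapped_ci(
    p0_est: ProportionEstimate, x1: float, coverage_fraction: float
) -> tuple[float, float]:
    """95% CI of the expected mapped count.

    Each endpoint of the normal-approximation CI of the non-lethal
    proportion is pushed through the (monotone decreasing) null-model
    transform; the resulting pair is returned sorted ascending.
    """
    if not 0.0 <= coverage_fraction <= 1.0:
        raise ValueError(
            f"coverage_fraction must be in [0, 1], got {coverage_fraction!r}"
        )
    endpoints = []
    for name, p in (("ci_low", p0_est.ci_low), ("ci_high", p0_est.ci_high)):
        if not 0.0 < p < 1.0:
            raise ValueError(
                f"P0 CI endpoint {name}={p!r} is outside (0, 1); the "
                "normal-approximation transform is undefined there"
            )
        endpoints.append(_mapped_at_p0(p, x1, coverage_fraction))
    lo, hi = sorted(endpoints)
    return lo, hi


def mapped_prediction_interval(
    p0_est: ProportionEstimate, coverage_fraction: float
) -> tuple[float, float]:
    """95% prediction interval for the *realized* mapped count.

    :func:`expected_mapped_ci` propagates only the sampling error of the
    non-lethal proportion and therefore bounds the expectation, not a single
    screen's realized count. Writing the point estimate as
    ``n * coverage * lam_hat`` (the identity ``x1 / (1 - p0) = n``), the
    realized count is approximately Poisson with mean ``n * coverage * lam``
    and is positively correlated with ``lam_hat`` (both are functions of the
    same chromosomes), giving

        Var(realized - predicted) =
            n*c*lam + n*c^2*(1-p0)/p0 - 2*n*lam*c^2.

    The interval is the point estimate +/- 1.96 of that standard deviation;
    a realized screen outcome should land inside it ~95% of the time, which
    is the calibrated form of the consistency check the expectation CI is
    too narrow for.
    """
    if not 0.0 < coverage_fraction <= 1.0:
        raise ValueError(
            f"coverage_fraction must be in (0, 1], got {coverage_fraction!r}"
        )
    p0, n = p0_est.p, p0_est.n
    lam = poisson_mean_from_p0(p0)
    c = coverage_fraction
    centre = n * c * lam
    var = n * c * lam + n * c * c * (1.0 - p0) / p0 - 2.0 * n * lam * c * c
    sd = math.sqrt(max(var, 0.0))
    return centre - Z_95 * sd, centre + Z_95 * sd


def mapping_expectation(
    p0_est: ProportionEstimate, x1: float, coverage_fraction: float
) -> MappingExpectation:
    """Evaluate the whole null model from a non-lethal proportion estimate."""
    lam = poisson_mean_from_p0(p0_est.p)
    mean = ztp_mean(lam)
    point = expected_mapped(x1, coverage_fraction, lam)
    if p0_est.se == 0:
        ci = (point, point)
    else:
        ci = expected_mapped_ci(p0_est, x1, coverage_fraction)
    return MappingExpectation(
        p0=p0_est.p,
        n=p0_est.n,
        x1=x1,
        coverage_fraction=coverage_fraction,
        lam=lam,
        ztp_mean=mean,
        expected_mapped=point,
        ci_low=ci[0],
        ci_high=ci[1],
    )


def msb_equilibrium(mu: float, s: float) -> float:
    """Equilibrium frequency of a recessive deleterious allele.

    Under mutation-selection balance in an infinite population a fully
    recessive allele with mutation rate ``mu`` per locus per generation and
    selection coefficient ``s`` against the homozygote equilibrates at
    q = sqrt(mu / s). For a recessive lethal (s = 1) and a point-mutation
    rate of ~1e-9 this is of order 1e-5 per locus — the yardstick against
    which unusually frequent lethal gene disruptions are judged.
    """
    if s <= 0 or s > 1:
        raise ValueError(f"s must be in (0, 1], got {s!r}")
    if mu < 0:
        raise ValueError(f"mu must be >= 0, got {mu!r}")
    return math.sqrt(mu / s)
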