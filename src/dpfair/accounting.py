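"""Rényi-DP accounting for the sampled Gaussian mechanism (SGM).

One DP-SGD step on a dataset of ``N`` records Poisson-samples each record with
probability ``q``, clips per-sample gradients to ℓ2-norm ``C`` and adds
``Normal(0, σ²C²)`` noise to their sum.  Privacy-wise each step is a sampled
Gaussian mechanism with sampling rate ``q`` and noise multiplier ``σ``.  Its
Rényi divergence at order α composes additively over the ``T`` training steps
and converts to an (ε, δ)-DP statement at the end.

The per-step Rényi bound used here is the standard integer-order expression

    ε_α = 1/(α−1) · ln Σ_{k=0}^{α} C(α,k) (1−q)^{α−k} q^k · exp(k(k−1)/(2σ²)),

which is the exact value of E_{z∼N(0,σ²)}[((1−q) + q·e^{(2z−1)/(2σ²)})^α]
obtained by binomial expansion; everything is evaluated in log-space so that
large orders and small σ do not overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "DEFAULT_ORDERS",
    "MechanismParams",
    "RdpCurve",
    "PrivacySpend",
    "rdp_step",
    "compose",
    "rdp_to_dp",
    "account",
    "calibrate_sigma",
    "CalibrationError",
]

#: Default Rényi order grid: integers 2..64 plus a sparse high-order tail.
DEFAULT_ORDERS: tuple[int, ...] = tuple(range(2, 65)) + (80, 96, 128, 256)

SIGMA_MIN = 1e-2
SIGMA_MAX = 1e4


class CalibrationError(RuntimeError):
    """Raised when no noise multiplier in [SIGMA_MIN, SIGMA_MAX] meets the target."""


@dataclass(frozen=True)
class MechanismParams:
    """Parameters of an iterated sampled Gaussian mechanism.

    Attributes
    ----------
    q : float
        Per-record Poisson sampling probability, in [0, 1].
    sigma : float
        Noise multiplier (noise std over clipping norm), > 0.
    steps : int
        Number of compositions (training steps), >= 0.
    delta : float
        Failure probability δ of the final (ε, δ) guarantee, in (0, 1).
    """

    q: float
    sigma: float
    steps: int
    delta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"sampling rate q must be in [0, 1], got {self.q}")
        if not self.sigma > 0:
            raise ValueError(f"noise multiplier sigma must be > 0, got {self.sigma}")
        if self.steps < 0:
            raise ValueError(f"steps must be >= 0, got {self.steps}")
        if not 0.0 < self.delta < 1.0:
            raise ValueError(f"delta must be in (0, 1), got {self.delta}")


@dataclass(frozen=True)
class RdpCurve:
    """Rényi-DP guarantee as (order, ε_α) pairs with strictly increasing orders."""

    orders: tuple[float, ...]
    epsilons: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.orders) != len(self.epsilons):
            raise ValueError("orders and epsilons must have equal length")
        if len(self.orders) == 0:
            raise ValueError("RdpCurve must contain at least one order")
        if any(b <= a for a, b in zip(self.orders, self.orders[1:])):
            raise ValueError("orders must be strictly increasing")
        if any(e < 0 for e in self.epsilons):
            raise ValueError("RDP epsilons must be non-negative")


@dataclass(frozen=True)
class PrivacySpend:
    """An (ε, δ) guarantee together with the Rényi order that realized it."""

    epsilon: float
    delta: float
    optimal_order: float

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must be in (0, 1)")


def rdp_step(q: float, sigma: float, order: float) -> float:
    """Per-step Rényi-DP ε_α of the sampled Gaussian mechanism.

    Parameters
    ----------
    q : float
        Poisson sampling probability.
    sigma : float
        Noise multiplier.
    order : float
        Rényi order α > 1.  The default grid is integer-valued and the exact
        binomial form below holds for integer α; non-integer orders raise.
    """
    if not order > 1:
        raise ValueError(f"Rényi order must be > 1, got {order}")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0, 1], got {q}")
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if q == 0.0:
        return 0.0
    if q == 1.0:
        # Plain Gaussian mechanism: α / (2σ²).
        return order / (2.0 * sigma**2)
    alpha = int(round(order))
    if abs(order - alpha) > 1e-12:
        raise ValueError(
            f"non-integer Rényi order {order} is not supported; "
            "use an integer order grid"
        )
    k = np.arange(alpha + 1, dtype=float)
    log_binom = gammaln(alpha + 1) - gammaln(k + 1) - gammaln(alpha - k + 1)
    log_terms = (
        log_binom
        + k * math.log(q)
        + (alpha - k) * math.log1p(-q)
        + k * (k - 1.0) / (2.0 * sigma**2)
    )
    log_moment = float(logsumexp(log_terms))
    # The moment is >= 1 by Jensen, so ε_α >= 0; clip tiny negative round-off.
    return max(log_moment / (alpha - 1.0), 0.0)


def compose(curve: RdpCurve, steps: int) -> RdpCurve:
    """Compose an RDP curve over ``steps`` identical mechanism invocations."""
    if steps < 0:
        raise ValueError(f"steps must be >= 0, got {steps}")
    return RdpCurve(curve.orders, tuple(steps * e for e in curve.epsilons))


def rdp_to_dp(curve: RdpCurve, delta: float) -> PrivacySpend:
    """Convert an RDP curve to an (ε, δ) guarantee.

    Uses the classic conversion ε = min_α [ε_α + ln(1/δ)/(α−1)]; the returned
    spend records the minimizing order.
    """
    if not 0.0 < delta < 1.0:
        raise ValueError(f"delta must be in (0, 1), got {delta}")
    orders = np.asarray(curve.orders, dtype=float)
    eps_alpha = np.asarray(curve.epsilons, dtype=float)
    candidates = eps_alpha + math.log(1.0 / delta) / (orders - 1.0)
    best = int(np.argmin(candidates))
    return PrivacySpend(float(candidates[best]), delta, float(orders[best]))


def account(
    params: MechanismParams, order_grid: Sequence[float] = DEFAULT_ORDERS
) -> PrivacySpend:
    """Full accountant: per-step RDP over the grid, compose, convert to (ε, δ)."""
    curve = RdpCurve(
        tuple(float(a) for a in order_grid),
        tuple(rdp_step(params.q, params.sigma, a) for a in order_grid),
    )
    return rdp_to_dp(compose(curve, params.steps), params.delta)


def calibrate_sigma(
    epsilon_target: float,
    delta: float,
    q: float,
    steps: int,
    tolerance: float = 1e-4,
    order_grid: Sequence[float] = DEFAULT_ORDERS,
) -> float:
    """Find the noise multiplier spending exactly the target budget.

    Bisects σ (ε is continuous and non-increasing in σ) inside a bracket found
    by doubling, so that the accounted ε at the returned σ is within
    ``tolerance`` of ``epsilon_target`` and never exceeds it by more than
    ``tolerance``.  This realizes a training schedule whose privacy budget is
    reached on the last training step.
    """
    if not epsilon_target > 0:
        raise ValueError("epsilon_target must be > 0")
    if not tolerance > 0:
        raise ValueError("tolerance must be > 0")

    def eps_at(sigma: float) -> float:
        return account(MechanismParams(q, sigma, steps, delta), order_grid).epsilon

    lo, hi = SIGMA_MIN, SIGMA_MIN
    if eps_at(SIGMA_MIN) < epsilon_target - tolerance:
        raise CalibrationError(
            f"epsilon target {epsilon_target} is unreachable: even sigma="
            f"{SIGMA_MIN} yields a smaller accounted epsilon"
        )
    while eps_at(hi) > epsilon_target:
        lo, hi = hi, 2.0 * hi
        if hi > SIGMA_MAX:
            raise CalibrationError(
                f"epsilon target {epsilon_target} is unreachable within "
                f"sigma <= {SIGMA_MAX}"
            )
    # Invariant: eps(lo) >= target >= eps(hi).
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        e = eps_at(mid)
        if abs(e - epsilon_target) <= tolerance:
            return mid
        if e > epsilon_target:
            lo = mid
        else:
            hi = mid
    # Fall back to the private side of the bracket.
    return hi
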