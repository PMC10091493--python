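"""Diffusion-approximation fixation probabilities and substitution rates.

For drift coefficients ``(s_bar, sigma, Ne)`` the sojourn weight of the
diffusion is

    G(y) = exp(-4*Ne*(s_bar*y - sigma*y*(1-y)))

and the fixation probability of an allele starting at frequency ``p`` is

    U(p) = int_0^p G(y) dy / int_0^1 G(y) dy.

The exponent is quadratic in ``y``, so both integrals reduce to scaled
error-function differences; this closed form is evaluated entirely in log
space (via ``erfcx`` for a concave exponent and ``dawsn`` for a convex
one) so that large ``|Ne*s|`` neither overflows nor cancels.  An adaptive
quadrature of the same integrals serves as an independent evaluation path;
the two must agree and are cross-checked in the test suite.

When ``|4*Ne*sigma|`` falls below :data:`KIMURA_SIGMA_THRESHOLD` the
error-function differences lose all precision and the evaluation switches
to the additive (h = 1/2) limit

    U(p) = (1 - exp(-4*Ne*s_bar*p)) / (1 - exp(-4*Ne*s_bar)),

i.e. Kimura's classical formula, and for vanishing ``s_bar`` to the
neutral identity ``U(p) = p``.

The substitution rate is reported relative to the mutation rate: the
number of new copies entering per generation times ``U(p0)`` equals
``mu * U(p0)/p0`` for every locus class, so the dimensionless quantity
``U(p0)/p0`` is the rate on a scale where neutral = 1.  Its ``p0 -> 0``
limit, ``1 / int_0^1 G(y) dy``, is also available (``first_order=True``);
the two agree to O(p0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special

from .model import (
    DriftCoefficients,
    LocusClass,
    ParameterError,
    PopulationModel,
    SelectionRegime,
    drift_coefficients,
)

__all__ = [
    "KIMURA_SIGMA_THRESHOLD",
    "EvaluationError",
    "QuadratureError",
    "FixationResult",
    "G",
    "log_G",
    "fixation_probability",
    "relative_substitution_rate",
    "kimura_rate",
]

#: Below this value of |4*Ne*sigma| the closed form switches to the
#: additive (Kimura) limit; the erf differences are pure noise there.
KIMURA_SIGMA_THRESHOLD = 1e-8


class EvaluationError(ArithmeticError):
    """A closed-form evaluation produced a non-finite intermediate."""


class QuadratureError(ArithmeticError):
    """Adaptive quadrature failed to reach the requested tolerance."""


@dataclass(frozen=True)
class FixationResult:
    """Fixation probability and mutation-relative substitution rate."""

    u: float
    relative_rate: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.u <= 1.0) or not np.isfinite(self.u):
            raise EvaluationError(f"fixation probability u={self.u} outside [0, 1]")
        if self.relative_rate < 0.0:
            raise EvaluationError(f"negative relative rate {self.relative_rate}")


# ---------------------------------------------------------------------------
# sojourn weight G


def log_G(y, coeffs: DriftCoefficients):
    """Natural log of the sojourn weight G(y); vectorized over ``y``."""
    y = np.asarray(y, dtype=float)
    if np.any((y < 0.0) | (y > 1.0)):
        raise ParameterError("frequency y must lie in [0, 1]")
    return -4.0 * coeffs.Ne * (coeffs.s_bar * y - coeffs.sigma * y * (1.0 - y))


def G(y, coeffs: DriftCoefficients):
    """Sojourn weight G(y) = exp(-4*Ne*(s_bar*y - sigma*y*(1-y)))."""
    return np.exp(log_G(y, coeffs))


# ---------------------------------------------------------------------------
# log-space closed form for  int_a^b exp(alpha*t - beta*t^2) dt


def _log_expm1(x: float) -> float:
    """log(exp(x) - 1) for x > 0, stable for large x."""
    if x > 30.0:
        return x + math.log1p(-math.exp(-x))
    return math.log(math.expm1(x))


def _log_integral_series(alpha: float, beta: float, a: float, b: float) -> float:
    """Taylor evaluation of log int_a^b exp(alpha*t - beta*t^2) dt.

    Used when the exponent varies little over [a, b]: the error-function
    differences cancel catastrophically there, while the exponential
    series converges in a handful of terms at full precision.  Writing
    t = a + u, the exponent is q(a) + c1*u + c2*u^2 with c1 = alpha-2*beta*a
    and c2 = -beta; exp of the polynomial part is accumulated as a power
    series in u and integrated term by term.
    """
    w = b - a
    c_poly = np.array([0.0, alpha - 2.0 * beta * a, -beta])
    term = np.array([1.0])  # p(u)^n / n!, ascending powers of u
    powers = w ** np.arange(1, 2 * 60 + 4) / np.arange(1, 2 * 60 + 4)
    total = w  # n = 0 contribution
    for n in range(1, 61):
        term = np.convolve(term, c_poly) / n
        contrib = float(term @ powers[: term.size])
        total += contrib
        if abs(contrib) < 1e-18 * abs(total):
            break
    qa = alpha * a - beta * a * a
    return qa + math.log(total)


def _log_integral_closed(alpha: float, beta: float, a: float, b: float) -> float:
    """log of int_a^b exp(q(t)) dt with q(t) = alpha*t - beta*t**2, a < b.

    Exponents are combined analytically (``q(b) - q(a)`` is computed in
    factored form) so the result stays accurate when the interval is tiny
    or the quadratic term dominates.
    """
    if not b > a:
        raise ParameterError(f"integration bounds must satisfy a < b (got {a}, {b})")

    def q(t: float) -> float:
        return alpha * t - beta * t * t

    d = (b - a) * (alpha - beta * (a + b))  # q(b) - q(a), no cancellation

    # exponent variation over [a, b] (endpoints and interior extremum)
    q_vals = [0.0, d]
    if beta != 0.0:
        t_star = alpha / (2.0 * beta)
        if a < t_star < b:
            q_vals.append(q(t_star) - q(a))
    if max(q_vals) - min(q_vals) < 0.5:
        return _log_integral_series(alpha, beta, a, b)

    if beta == 0.0:
        if alpha == 0.0:
            return math.log(b - a)
        if alpha > 0.0:
            return alpha * a + _log_expm1(alpha * (b - a)) - math.log(alpha)
        return alpha * b + _log_expm1(-alpha * (b - a)) - math.log(-alpha)

    if beta > 0.0:
        # concave exponent: Gaussian kernel, use erf / erfcx
        m = alpha / (2.0 * beta)
        sq = math.sqrt(beta)
        xa, xb = sq * (a - m), sq * (b - m)
        const = math.log(math.sqrt(math.pi) / 2.0) - 0.5 * math.log(beta)
        if xa >= 0.0:
            diff = special.erfcx(xa) - math.exp(d) * special.erfcx(xb)
            if not diff > 0.0:
                raise EvaluationError(
                    f"erfcx difference underflowed (alpha={alpha}, beta={beta})"
                )
            return const + q(a) + math.log(diff)
        if xb <= 0.0:
            diff = special.erfcx(-xb) - math.exp(-d) * special.erfcx(-xa)
            if not diff > 0.0:
                raise EvaluationError(
                    f"erfcx difference underflowed (alpha={alpha}, beta={beta})"
                )
            return const + q(b) + math.log(diff)
        # maximum interior at t = m; erf terms are O(1)
        return const + 0.5 * alpha * m + math.log(special.erf(xb) + special.erf(-xa))

    # beta < 0: convex exponent, growing Gaussian; use E(x) = exp(x^2)*dawsn(x)
    g = -beta
    sq = math.sqrt(g)
    shift = alpha / (2.0 * g)
    xa, xb = sq * (a + shift), sq * (b + shift)
    base = -0.5 * math.log(g) - alpha * alpha / (4.0 * g)

    def log_dawsn(x: float) -> float:
        v = special.dawsn(x)
        if not v > 0.0:
            raise EvaluationError(f"dawsn underflow at x={x}")
        return math.log(v)

    if xa >= 0.0:
        if xa == 0.0:
            return q(b) - 0.5 * math.log(g) + log_dawsn(xb)
        delta = d + log_dawsn(xb) - log_dawsn(xa)  # d = xb^2 - xa^2 here
        return q(a) - 0.5 * math.log(g) + log_dawsn(xa) + _log_expm1(delta)
    if xb <= 0.0:
        if xb == 0.0:
            return q(a) - 0.5 * math.log(g) + log_dawsn(-xa)
        delta = -d + log_dawsn(-xa) - log_dawsn(-xb)
        return q(b) - 0.5 * math.log(g) + log_dawsn(-xb) + _log_expm1(delta)
    return base + np.logaddexp(
        xb * xb + log_dawsn(xb), xa * xa + log_dawsn(-xa)
    )


# quadrature tolerances on the max-rescaled integrand
_QUAD_EPSABS = 1e-12
_QUAD_EPSREL = 1e-10


def _log_integral_quad(alpha: float, beta: float, a: float, b: float) -> float:
    """Same integral as :func:`_log_integral_closed`, by adaptive quadrature.

    The integrand is rescaled by its maximum over [a, b] before
    integration so that large exponents neither overflow nor underflow.
    """

    def q(t: float) -> float:
        return alpha * t - beta * t * t

    candidates = [a, b]
    interior = None
    if beta > 0.0:
        m = alpha / (2.0 * beta)
        if a < m < b:
            interior = m
            candidates.append(m)
    qmax = max(q(t) for t in candidates)

    def f(t: float) -> float:
        return math.exp(q(t) - qmax)

    points = [interior] if interior is not None else None
    val, err = integrate.quad(
        f, a, b, epsabs=_QUAD_EPSABS, epsrel=_QUAD_EPSREL, limit=200, points=points
    )
    if not (np.isfinite(val) and val > 0.0):
        raise QuadratureError(
            f"quadrature failed on [{a}, {b}] (alpha={alpha}, beta={beta})"
        )
    if err > 10.0 * max(_QUAD_EPSABS, _QUAD_EPSREL * val):
        raise QuadratureError(
            f"quadrature error estimate {err:.3g} exceeds tolerance for value {val:.3g}"
        )
    return qmax + math.log(val)


# ---------------------------------------------------------------------------
# U(p) and rates


def _kimura_u(S: float, p: float) -> float:
    """Additive-limit fixation probability with S = 4*Ne*s_bar."""
    if S == 0.0:
        return p
    if S > 0.0:
        return math.expm1(-S * p) / math.expm1(-S)
    # S < 0: both expm1 arguments positive and possibly huge; work in logs
    return math.exp(_log_expm1(-S * p) - _log_expm1(-S))


def kimura_rate(S: float) -> float:
    """Additive-limit relative substitution rate S / (1 - exp(-S)), S = 4*Ne*s_bar."""
    if S == 0.0:
        return 1.0
    if S > 0.0:
        return S / -math.expm1(-S)
    return math.exp(math.log(-S) - _log_expm1(-S))


def fixation_probability(
    p0: float, coeffs: DriftCoefficients, method: str = "closed_form"
) -> FixationResult:
    """Fixation probability U(p0) of an allele starting at frequency ``p0``.

    ``method`` selects the evaluation path: ``"closed_form"`` (log-space
    error-function evaluation, switching automatically to the Kimura limit
    for vanishing ``sigma``) or ``"quadrature"`` (adaptive numerical
    integration of G).  Both return ``relative_rate = U(p0)/p0``.
    """
    if not 0.0 < p0 < 1.0:
        raise ParameterError(f"initial frequency p0={p0} not in (0, 1)")
    S = 4.0 * coeffs.Ne * coeffs.s_bar
    B = 4.0 * coeffs.Ne * coeffs.sigma
    alpha = B - S

    if method == "closed_form":
        if abs(B) < KIMURA_SIGMA_THRESHOLD:
            u = _kimura_u(S, p0)
            tag = "kimura_limit"
        else:
            log_u = _log_integral_closed(alpha, B, 0.0, p0) - _log_integral_closed(
                alpha, B, 0.0, 1.0
            )
            u = math.exp(log_u)
            tag = "closed_form"
    elif method == "quadrature":
        log_u = _log_integral_quad(alpha, B, 0.0, p0) - _log_integral_quad(
            alpha, B, 0.0, 1.0
        )
        u = math.exp(log_u)
        tag = "quadrature"
    else:
        raise ParameterError(f"unknown method {method!r}")

    if not np.isfinite(u):
        raise EvaluationError(
            f"non-finite U(p0) for Ne*s_bar={coeffs.Ne * coeffs.s_bar}, "
            f"Ne*sigma={coeffs.Ne * coeffs.sigma}"
        )
    u = min(max(u, 0.0), 1.0)
    return FixationResult(u=u, relative_rate=u / p0, method=tag)


def _first_order_rate(coeffs: DriftCoefficients, method: str) -> float:
    """p0 -> 0 limit of U(p0)/p0, i.e. 1 / int_0^1 G(y) dy."""
    S = 4.0 * coeffs.Ne * coeffs.s_bar
    B = 4.0 * coeffs.Ne * coeffs.sigma
    alpha = B - S
    if method == "closed_form":
        if abs(B) < KIMURA_SIGMA_THRESHOLD:
            return kimura_rate(S)
        return math.exp(-_log_integral_closed(alpha, B, 0.0, 1.0))
    if method == "quadrature":
        return math.exp(-_log_integral_quad(alpha, B, 0.0, 1.0))
    raise ParameterError(f"unknown method {method!r}")


def relative_substitution_rate(
    regime: SelectionRegime,
    locus_class: LocusClass | str,
    pop: PopulationModel,
    method: str = "closed_form",
    first_order: bool = False,
    p0: float | None = None,
) -> float:
    """Substitution rate relative to the mutation rate, U(p0)/p0.

    New copies arise at ``(copies) * mu`` per generation and each fixes
    with probability ``U(p0)``; with ``p0 = 1/copies`` the rate is
    ``mu * U(p0)/p0`` for every locus class, so the returned value is
    directly comparable across classes and equals 1 under neutrality.
    With ``first_order=True`` the ``p0 -> 0`` limit ``1/int_0^1 G`` is
    returned instead of the exact ratio.
    """
    coeffs = drift_coefficients(regime, locus_class, pop, p0=p0)
    if first_order:
        return _first_order_rate(coeffs, method)
    return fixation_probability(coeffs.p0, coeffs, method=method).relative_rate
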