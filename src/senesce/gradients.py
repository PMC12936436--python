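"""Selection gradients on the life-history parameters.

The focal quantity is selection on the senescence rate R for a gene that
reshapes mortality from birth (not from some onset age).  Differentiating
the survival function l(x) = exp(-(G/R)(e^{Rx}-1) - Mx) in R gives

    d l(x) / dR = l(x) * G * k(x),
    k(x) = (e^{Rx} - R x e^{Rx} - 1) / R^2,

with k(x) <= 0 and k(x) -> -x^2/2 as R -> 0.  Hence

    dLRS/dR = G * int_{xs} k(x) l(x) m(x) dx                     (LRS estimator)
    dr/dR   = G * int_{xs} k(x) e^{-rx} l m dx
              / int_{xs} x e^{-rx} l m dx                        (Euler–Lotka)

where the denominator of dr/dR is the generation time.  Both are
non-positive: faster senescence never raises fitness.  The classic
onset-age gradient (a permanent additive hazard increment from age ``a``)
is provided for comparison as :func:`hamilton_gradient`.

Gradients with respect to G, M, xs and zeta are computed by central
finite differences with one Richardson extrapolation level; the
negligible-senescence (R = 0) limits of the R-gradients have closed or
semi-closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._quadrature import integrate
from .demography import (
    LifeHistory,
    R_NEGLIGIBLE,
    certain_mortality_age,
    reproduction_rate,
    survival,
)
from .fitness import euler_lotka_r, lrs

__all__ = [
    "SelectionGradient",
    "NegligibleSenescenceError",
    "senescence_kernel",
    "hamilton_gradient",
    "dr_dR",
    "dlrs_dR",
    "gradient_r0_limit",
    "generic_gradient",
    "selection_gradient",
    "finite_difference",
]

ESTIMATORS = ("lrs", "euler_lotka_r")
GRADIENT_PARAMETERS = ("R", "G", "M", "xs", "zeta")


class NegligibleSenescenceError(ValueError):
    """R = 0 requested from a formula that needs R > 0; use gradient_r0_limit."""


@dataclass(frozen=True)
class SelectionGradient:
    """d(fitness)/d(parameter) with the estimator and method recorded."""

    parameter: str
    estimator: str
    value: float
    method: str  # "closed_form" | "finite_difference" | "r0_limit"

    def __float__(self) -> float:
        return self.value


def senescence_kernel(R: float, x):
    """k(x) = (e^{Rx}(1 - Rx) - 1)/R^2, the per-unit-G log-survival sensitivity to R.

    Evaluated by a Taylor branch for |Rx| < 1e-4 (the leading terms are
    -x^2/2 - Rx^3/3 - R^2x^4/8), which is exact in the R -> 0 limit and
    avoids cancellation for small R.
    """
    xa = np.asarray(x, dtype=float)
    u = R * xa
    small = np.abs(u) < 1e-4
    with np.errstate(over="ignore", invalid="ignore"):
        exact = (np.exp(u) * (1.0 - u) - 1.0) / (R * R) if R > 0 else np.zeros_like(xa)
    series = -(xa * xa) * (0.5 + u / 3.0 + u * u / 8.0)
    out = np.where(small, series, exact)
    return out if np.ndim(x) else float(out)


def _check_estimator(estimator: str) -> None:
    if estimator not in ESTIMATORS:
        raise ValueError(f"estimator must be one of {ESTIMATORS}, got {estimator!r}")


def hamilton_gradient(lh: LifeHistory, a: float, change: str = "permanent") -> float:
    """Classic onset-age gradient of r for a hazard change from age ``a``.

    ``change="permanent"`` (default): an additive hazard increment acting
    at every age beyond ``a``,

        dr/d(mu_{a..inf}) = - int_a (x - a) e^{-rx} l m dx
                            / int_0 x e^{-rx} l m dx.

    ``change="instantaneous"``: a pulse of extra mortality at age ``a``
    alone (the numerator weight (x - a) becomes 1); this is the variant
    whose magnitude is exactly constant for a <= xs and shrinks only once
    the onset age passes reproductive maturity.  Both are non-positive
    and vanish once ``a`` reaches the certain-mortality age.
    """
    if a < 0:
        raise ValueError("onset age must be non-negative")
    if change not in ("permanent", "instantaneous"):
        raise ValueError("change must be 'permanent' or 'instantaneous'")
    r = euler_lotka_r(lh).value
    x_trunc = certain_mortality_age(lh.params)

    def w(x):
        return math.exp(-r * x) * survival(lh.params, x) * reproduction_rate(lh, x)

    if change == "permanent":
        num, _ = integrate(lambda x: (x - a) * w(x), max(a, lh.xs), x_trunc)
    else:
        num, _ = integrate(w, max(a, lh.xs), x_trunc)
    den, _ = integrate(lambda x: x * w(x), lh.xs, x_trunc)
    return -num / den


def dlrs_dR(lh: LifeHistory, x_trunc: float | None = None) -> SelectionGradient:
    """Closed-form selection gradient of LRS with respect to R.

    dLRS/dR = G int_{xs} k(x) l(x) m(x) dx, requires R > 0 (the R = 0
    limit lives in :func:`gradient_r0_limit`).  ``x_trunc`` overrides the
    default certain-mortality-age integration window; a fixed window is
    the right object when studying limits in a parameter that moves the
    truncation age (notably G -> 0, where the adaptive window grows like
    ln(1/G)/R and the gradient on it does not vanish).
    """
    R = lh.params.R
    if R < R_NEGLIGIBLE:
        raise NegligibleSenescenceError(
            "R = 0: use gradient_r0_limit for the negligible-senescence gradient"
        )
    if x_trunc is None:
        x_trunc = certain_mortality_age(lh.params)
    val, _ = integrate(
        lambda x: senescence_kernel(R, x) * survival(lh.params, x) * reproduction_rate(lh, x),
        lh.xs,
        x_trunc,
    )
    return SelectionGradient("R", "lrs", lh.params.G * val, "closed_form")


def dr_dR(lh: LifeHistory, x_trunc: float | None = None) -> SelectionGradient:
    """Closed-form selection gradient of the Euler–Lotka r with respect to R."""
    R = lh.params.R
    if R < R_NEGLIGIBLE:
        raise NegligibleSenescenceError(
            "R = 0: use gradient_r0_limit for the negligible-senescence gradient"
        )
    r = euler_lotka_r(lh, x_trunc).value
    if x_trunc is None:
        x_trunc = certain_mortality_age(lh.params)

    def w(x):
        return math.exp(-r * x) * survival(lh.params, x) * reproduction_rate(lh, x)

    num, _ = integrate(lambda x: senescence_kernel(R, x) * w(x), lh.xs, x_trunc)
    den, _ = integrate(lambda x: x * w(x), lh.xs, x_trunc)
    return SelectionGradient("R", "euler_lotka_r", lh.params.G * num / den, "closed_form")


def gradient_r0_limit(
    lh: LifeHistory, estimator: str = "lrs", x_trunc: float | None = None
) -> SelectionGradient:
    """R -> 0 limit of the senescence-rate gradient (negligible senescence).

    The kernel k(x) tends to -x^2/2, so for the LRS estimator with a
    constant rate zeta the limit has the closed form

        -(G zeta / 2) e^{-c xs} (xs^2/c + 2 xs/c^2 + 2/c^3),  c = G + M,

    evaluated with the integral truncated at x_d for consistency with the
    R > 0 formulas (the tail beyond survivorship 1e-4 is negligible).
    For the Euler–Lotka estimator the limit is the same integral
    discounted by e^{-rx} and divided by the generation time.
    """
    _check_estimator(estimator)
    if lh.params.R >= R_NEGLIGIBLE:
        raise ValueError("gradient_r0_limit requires a life history with R = 0")
    G = lh.params.G
    if x_trunc is None:
        x_trunc = certain_mortality_age(lh.params)
    if estimator == "lrs":
        val, _ = integrate(
            lambda x: -0.5 * x * x * survival(lh.params, x) * reproduction_rate(lh, x),
            lh.xs,
            x_trunc,
        )
        return SelectionGradient("R", "lrs", G * val, "r0_limit")
    r = euler_lotka_r(lh, x_trunc).value

    def w(x):
        return math.exp(-r * x) * survival(lh.params, x) * reproduction_rate(lh, x)

    num, _ = integrate(lambda x: -0.5 * x * x * w(x), lh.xs, x_trunc)
    den, _ = integrate(lambda x: x * w(x), lh.xs, x_trunc)
    return SelectionGradient("R", "euler_lotka_r", G * num / den, "r0_limit")


def r0_limit_closed_form(lh: LifeHistory) -> float:
    """Analytic value of the LRS-estimator R->0 gradient for constant zeta.

    -(G zeta/2) e^{-c xs}(xs^2/c + 2xs/c^2 + 2/c^3) with c = G + M; the
    untruncated integral, handy as an independent cross-check.
    """
    if lh.zeta is None:
        raise ValueError("closed form requires a constant reproduction rate")
    c = lh.params.G + lh.params.M
    xs = lh.xs
    tail = math.exp(-c * xs) * (xs * xs / c + 2 * xs / c**2 + 2 / c**3)
    return -0.5 * lh.params.G * lh.zeta * tail


# ---------------------------------------------------------------------------
# Finite differences
# ---------------------------------------------------------------------------


def _evaluate(lh: LifeHistory, estimator: str, x_trunc: float | None = None) -> float:
    if estimator == "lrs":
        return lrs(lh, x_trunc).value
    return euler_lotka_r(lh, x_trunc).value


def _perturb(lh: LifeHistory, parameter: str, value: float) -> LifeHistory:
    if parameter in ("G", "R", "M", "xs", "zeta"):
        return lh.with_params(**{parameter: value})
    raise ValueError(f"unknown parameter {parameter!r}")


def finite_difference(
    lh: LifeHistory,
    parameter: str,
    estimator: str = "lrs",
    step: float | None = None,
    richardson: bool = True,
    fix_truncation: bool = False,
    x_trunc: float | None = None,
) -> float:
    """Central finite difference of the fitness estimator in one parameter.

    Step h = max(1e-6, 1e-4 |p|) unless given; one Richardson level
    (D = (4 D(h/2) - D(h)) / 3) by default.  Steps that would take the
    parameter negative are shrunk to stay in the domain.

    ``fix_truncation=True`` holds the integration window at the base
    point's certain-mortality age for all evaluations, removing the
    moving-boundary term (relative size ~1e-4, the truncation
    survivorship) that otherwise contaminates the difference; use it when
    the FD serves as a high-accuracy oracle for a closed form.
    """
    _check_estimator(estimator)
    if x_trunc is None and fix_truncation:
        x_trunc = certain_mortality_age(lh.params)
    p0 = lh.zeta if parameter == "zeta" else getattr(lh.params, parameter, None)
    if p0 is None:
        p0 = getattr(lh, parameter)
    h = step if step is not None else max(1e-6, 1e-4 * abs(p0))
    if p0 - h < 0 and parameter != "xs":
        h = p0 / 2.0 if p0 > 0 else 1e-8
    if h <= 0:
        raise ValueError(f"finite-difference step underflow at {parameter}={p0}")

    def central(hh: float) -> float:
        up = _evaluate(_perturb(lh, parameter, p0 + hh), estimator, x_trunc)
        dn = _evaluate(_perturb(lh, parameter, p0 - hh), estimator, x_trunc)
        return (up - dn) / (2.0 * hh)

    d1 = central(h)
    if not richardson:
        return d1
    d2 = central(h / 2.0)
    return (4.0 * d2 - d1) / 3.0


def generic_gradient(
    lh: LifeHistory, parameter: str, estimator: str = "lrs"
) -> SelectionGradient:
    """Finite-difference selection gradient for G, M, xs or zeta.

    Sign contract: negative for G, M and xs (selection always favors
    lowering them), positive for zeta.
    """
    if parameter not in ("G", "M", "xs", "zeta"):
        raise ValueError("generic_gradient covers G, M, xs, zeta; use dr_dR/dlrs_dR for R")
    value = finite_difference(lh, parameter, estimator)
    return SelectionGradient(parameter, estimator, value, "finite_difference")


def selection_gradient(
    lh: LifeHistory, parameter: str, estimator: str = "lrs"
) -> SelectionGradient:
    """Dispatch: closed form for R (limit form at R = 0), finite differences otherwise."""
    if parameter == "R":
        if lh.params.R < R_NEGLIGIBLE:
            return gradient_r0_limit(lh, estimator)
        return dlrs_dR(lh) if estimator == "lrs" else dr_dR(lh)
    return generic_gradient(lh, parameter, estimator)
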