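"""Evolutionary feedback on senescence-rate evolution.

Feedback is read off the curvature of fitness in the senescence rate:
a positive second derivative of fitness with respect to R means that a
mutation slowing senescence *strengthens* selection for further slowing
(positive feedback, the route to negligible senescence), while a
negative one means runaway is self-limiting.  Mixed derivatives
d2(fitness)/dR d(other) play the same role for co-evolution of R with
G, M, xs or zeta — e.g. a negative d2LRS/dRdG in the M > G regime
produces a Strehler–Mildvan-like negative association between G and R.

Second derivatives are taken by central differences of the closed-form
first derivative in R; maps over parameter grids mask cells where
survivorship at the reproduction start-age falls below 1e-4 (no one
reproduces: fitness is treated as zero there).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demography import (
    LifeHistory,
    R_NEGLIGIBLE,
    TRUNCATION_SURVIVAL,
    certain_mortality_age,
    survival,
)
from .gradients import dlrs_dR, dr_dR, finite_difference, gradient_r0_limit

__all__ = [
    "FeedbackMap",
    "second_derivative_R",
    "mixed_derivative",
    "feedback_map",
    "approx_positive_feedback_condition",
    "log_modulus",
]

MIXED_PARAMETERS = ("G", "M", "xs", "zeta")


def log_modulus(v):
    """Signed log transform sign(v) * log10(1 + |v|); odd, sign-preserving."""
    va = np.asarray(v, dtype=float)
    out = np.sign(va) * np.log10(1.0 + np.abs(va))
    return out if np.ndim(v) else float(out)


def _first_derivative_R(
    lh: LifeHistory,
    estimator: str,
    equilibrate: bool = True,
    x_trunc: float | None = None,
) -> float:
    """Selection gradient on R at the population's own demographic equilibrium.

    Under reproduction-limited density dependence every point of
    parameter space is a population regulated to LRS = 1, so the
    gradient there is that of the normalized schedule, S'(R)/S(R) for
    constant fecundity (equivalently d ln LRS / dR); because the
    R-gradient is linear in the reproduction rate, normalization is a
    division by LRS.  The Euler–Lotka estimator needs no
    renormalization: regulation through external mortality leaves its
    R-gradient unchanged.

    ``x_trunc`` pins the integration window; the stencils in this module
    evaluate every point on the base point's window so that the moving
    truncation boundary cannot contaminate the differences.
    """
    if estimator != "lrs":
        return dr_dR(lh, x_trunc).value
    if lh.params.R < R_NEGLIGIBLE:
        g = gradient_r0_limit(lh, "lrs", x_trunc=x_trunc).value
    else:
        g = dlrs_dR(lh, x_trunc).value
    if equilibrate:
        from .fitness import lrs

        g /= lrs(lh, x_trunc).value
    return g


def second_derivative_R(
    lh: LifeHistory, estimator: str = "lrs", step: float = 1e-4, equilibrate: bool = True
) -> float:
    """Evolutionary feedback on R: the R-derivative of the selection gradient.

    Central difference, in R, of the closed-form first derivative, each
    evaluation at its own demographic equilibrium (see
    :func:`_first_derivative_R`); for the LRS estimator this is the
    curvature of log fitness, d2(ln LRS)/dR2.  Positive value = positive
    feedback (slowing senescence strengthens selection for slowing it
    further).  At R < step a one-sided (forward) difference keeps R
    non-negative.  ``equilibrate=False`` gives the raw-fitness curvature
    instead.
    """
    R = lh.params.R
    T = certain_mortality_age(lh.params)
    if R >= step:
        up = _first_derivative_R(lh.with_params(R=R + step), estimator, equilibrate, T)
        dn = _first_derivative_R(lh.with_params(R=R - step), estimator, equilibrate, T)
        return (up - dn) / (2.0 * step)
    up = _first_derivative_R(lh.with_params(R=R + step), estimator, equilibrate, T)
    here = _first_derivative_R(lh, estimator, equilibrate, T)
    return (up - here) / step


def mixed_derivative(
    lh: LifeHistory, other: str, estimator: str = "lrs", step: float | None = None,
    equilibrate: bool = True,
) -> float:
    """Co-evolutionary feedback d2(fitness)/dR d(other), other in {G, M, xs, zeta}.

    Central difference, in ``other``, of the closed-form R-gradient, each
    evaluation at its own demographic equilibrium; by continuity the
    result is symmetric in the differentiation order.
    """
    if other not in MIXED_PARAMETERS:
        raise ValueError(f"other must be one of {MIXED_PARAMETERS}, got {other!r}")
    p0 = lh.zeta if other == "zeta" else getattr(lh.params, other, None)
    if p0 is None:
        p0 = getattr(lh, other)
    h = step if step is not None else max(1e-6, 1e-4 * abs(p0))
    if p0 - h < 0:
        h = p0 / 2.0 if p0 > 0 else 1e-8
    T = certain_mortality_age(lh.params)
    up = _first_derivative_R(lh.with_params(**{other: p0 + h}), estimator, equilibrate, T)
    dn = _first_derivative_R(lh.with_params(**{other: p0 - h}), estimator, equilibrate, T)
    return (up - dn) / (2.0 * h)


def mixed_derivative_reversed(
    lh: LifeHistory, other: str, estimator: str = "lrs", step: float = 1e-4,
    equilibrate: bool = True,
) -> float:
    """Same mixed derivative, differentiating the ``other``-gradient in R.

    Finite-difference in R of the finite-difference gradient in ``other``;
    used to check symmetry of the differentiation order.
    """
    R = lh.params.R
    T = certain_mortality_age(lh.params)

    def grad_other(RR: float) -> float:
        point = lh.with_params(R=RR)
        if equilibrate and estimator == "lrs":
            from .fitness import lrs

            point = point.scale_reproduction(1.0 / lrs(point, T).value)
        return finite_difference(point, other, estimator, x_trunc=T)

    if R >= step:
        return (grad_other(R + step) - grad_other(R - step)) / (2.0 * step)
    return (grad_other(R + step) - grad_other(R)) / step


DERIVATIVES = {
    "second_R": lambda lh, est: second_derivative_R(lh, est),
    "mixed_G": lambda lh, est: mixed_derivative(lh, "G", est),
    "mixed_M": lambda lh, est: mixed_derivative(lh, "M", est),
    "mixed_xs": lambda lh, est: mixed_derivative(lh, "xs", est),
    "mixed_zeta": lambda lh, est: mixed_derivative(lh, "zeta", est),
}


@dataclass
class FeedbackMap:
    """A derivative evaluated over a 2-D parameter grid, with viability mask.

    ``values[i, j]`` is the derivative at (y_values[i], x_values[j]);
    masked cells (survivorship at xs <= 1e-4, fitness treated as zero)
    hold NaN.  ``transformed()`` applies the log-modulus transform for
    plotting.
    """

    x_param: str
    x_values: np.ndarray
    y_param: str
    y_values: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    derivative: str
    estimator: str
    transform: str = "raw"

    def transformed(self) -> np.ndarray:
        return log_modulus(self.values)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.values,
            index=pd.Index(self.y_values, name=self.y_param),
            columns=pd.Index(self.x_values, name=self.x_param),
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", na_rep="nan")


def feedback_map(
    base: LifeHistory,
    x_spec: tuple[str, np.ndarray],
    y_spec: tuple[str, np.ndarray],
    derivative: str = "second_R",
    estimator: str = "lrs",
) -> FeedbackMap:
    """Evaluate a second/mixed derivative over a grid in two parameters.

    ``x_spec``/``y_spec`` are (parameter name, strictly increasing grid)
    pairs over any of G, R, M, xs, zeta; remaining parameters are held at
    ``base``'s values.
    """
    if derivative not in DERIVATIVES:
        raise ValueError(f"derivative must be one of {sorted(DERIVATIVES)}")
    x_param, x_values = x_spec
    y_param, y_values = y_spec
    x_values = np.asarray(x_values, dtype=float)
    y_values = np.asarray(y_values, dtype=float)
    for name, grid in ((x_param, x_values), (y_param, y_values)):
        if grid.ndim != 1 or len(grid) < 1 or np.any(np.diff(grid) <= 0):
            raise ValueError(f"grid for {name} must be 1-D and strictly increasing")
        if np.any(grid < 0):
            raise ValueError(f"grid for {name} contains negative values")
    fn = DERIVATIVES[derivative]
    values = np.full((len(y_values), len(x_values)), np.nan)
    mask = np.zeros_like(values, dtype=bool)
    for i, yv in enumerate(y_values):
        for j, xv in enumerate(x_values):
            lh = base.with_params(**{y_param: yv, x_param: xv})
            if survival(lh.params, lh.xs) <= TRUNCATION_SURVIVAL:
                mask[i, j] = True  # fitness-zero convention
                continue
            values[i, j] = fn(lh, estimator)
    return FeedbackMap(
        x_param, x_values, y_param, y_values, values, mask, derivative, estimator
    )


def approx_positive_feedback_condition(
    lh: LifeHistory, g_reading: str = "half"
) -> tuple[bool, bool]:
    """Advisory rules of thumb for positive feedback on R (LRS estimator).

    * near_zero_R: at negligible senescence, positive feedback is expected
      roughly when G > (M/2) e^{-0.12 xs} (``g_reading="half"``; the
      alternative grouping M^2 e^{-0.12 xs} is kept behind
      ``g_reading="squared"``).
    * away_from_zero_R: at substantial R, positive feedback is expected
      while the reproduction start-age stays far from the certain-
      mortality age, operationalized as xs < 0.5 x_d.

    Both flags are heuristics; compute :func:`second_derivative_R` for
    the real thing.
    """
    G, M, xs = lh.params.G, lh.params.M, lh.xs
    decay = np.exp(-0.12 * xs)
    if g_reading == "half":
        near_zero = G > 0.5 * M * decay
    elif g_reading == "squared":
        near_zero = G > M * M * decay
    else:
        raise ValueError("g_reading must be 'half' or 'squared'")
    xd = certain_mortality_age(lh.params)
    away = xs < 0.5 * xd
    return bool(near_zero), bool(away)
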