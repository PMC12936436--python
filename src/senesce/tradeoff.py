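"""Senescence–reproduction trade-off and the ESS senescence rate.

A single allocation variable z in [0, 1] buys reproduction at the cost
of faster senescence:

    R(z)    = (Rmax - Rmin) z^alpha + Rmin
    zeta(z) = (zeta_max - zeta_min) (1 - (1 - z)^beta) + zeta_min

with shape exponents alpha, beta >= 1.  Under density dependence through
reproduction (the LRS estimator) the evolutionarily stable allocation z*
satisfies dLRS/dz = 0 with d2LRS/dz2 < 0.  With a constant reproduction
rate LRS = zeta * S(R) where S(R) = int_{xs}^{xd} l(x) dx, so

    dLRS/dz = zeta(z) S'(R) R'(z) + S(R) zeta'(z),

assembled from the closed-form senescence gradient (S'(R) = dLRS/dR per
unit zeta) by the chain rule.  With zeta_min = 0 the whole expression is
proportional to zeta_max, so the ESS does not depend on zeta_max.

``Rmax`` is pinned by the requirement that reproduction start before
certain death: the R at which survivorship at xs equals 1e-4.  Fitting
the shape exponent alpha so that the ESS reproduces a species' observed
senescence rate, and back-solving the implied zeta_max from the observed
reproduction rate, mirrors the calibration exercise on the four bundled
mammal parameterizations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from ._quadrature import integrate
from .demography import (
    GompertzMakehamParams,
    LifeHistory,
    R_NEGLIGIBLE,
    TRUNCATION_SURVIVAL,
    certain_mortality_age,
    cumulative_hazard,
    survival,
)
from .gradients import dlrs_dR, gradient_r0_limit

__all__ = [
    "TradeoffSpec",
    "ESSResult",
    "tradeoff_map",
    "dlrs_dz",
    "ess_find",
    "rmax_rule",
    "fit_alpha",
    "infer_zeta_max",
]

#: Defaults used throughout the species calibrations.
DEFAULT_BETA = 1.0
DEFAULT_RMIN = 1e-4
DEFAULT_ZETA_MIN = 0.0


@dataclass(frozen=True)
class TradeoffSpec:
    """Shape exponents and bounds of the z -> (R, zeta) trade-off."""

    alpha: float
    Rmax: float
    zeta_max: float
    beta: float = DEFAULT_BETA
    Rmin: float = DEFAULT_RMIN
    zeta_min: float = DEFAULT_ZETA_MIN

    def __post_init__(self) -> None:
        if not (0 <= self.Rmin < self.Rmax):
            raise ValueError(f"need 0 <= Rmin < Rmax, got ({self.Rmin}, {self.Rmax})")
        if not (0 <= self.zeta_min < self.zeta_max):
            raise ValueError(
                f"need 0 <= zeta_min < zeta_max, got ({self.zeta_min}, {self.zeta_max})"
            )
        if self.alpha < 1 or self.beta < 1:
            raise ValueError(f"shape exponents must be >= 1, got alpha={self.alpha}, beta={self.beta}")

    def replace(self, **changes) -> "TradeoffSpec":
        return replace(self, **changes)


def tradeoff_map(spec: TradeoffSpec, z: float) -> tuple[float, float]:
    """Map an allocation z in [0, 1] to its (R, zeta) pair."""
    if not 0.0 <= z <= 1.0:
        raise ValueError(f"allocation z must lie in [0, 1], got {z}")
    R = (spec.Rmax - spec.Rmin) * z**spec.alpha + spec.Rmin
    zeta = (spec.zeta_max - spec.zeta_min) * (1.0 - (1.0 - z) ** spec.beta) + spec.zeta_min
    return R, zeta


@dataclass(frozen=True)
class ESSResult:
    """An interior ESS (or boundary-optimum report when ``is_ess`` is False)."""

    z_star: float
    R_star: float
    zeta_star: float
    gradient_at_root: float
    curvature: float
    is_ess: bool = True
    boundary: str | None = None


def _survivorship_integral(params: GompertzMakehamParams, xs: float) -> float:
    """S(R) = int_{xs}^{xd} l(x) dx — LRS per unit constant reproduction rate."""
    x_trunc = certain_mortality_age(params)
    val, _ = integrate(lambda x: survival(params, x), xs, x_trunc)
    return val


def _s_prime(params: GompertzMakehamParams, xs: float) -> float:
    """S'(R): the senescence gradient of LRS per unit zeta."""
    probe = LifeHistory(params, xs=xs, zeta=1.0)
    if params.R < R_NEGLIGIBLE:
        return gradient_r0_limit(probe, "lrs").value
    return dlrs_dR(probe).value


def dlrs_dz(base: LifeHistory, spec: TradeoffSpec, z: float) -> float:
    """Gradient of LRS along the trade-off at allocation z (chain rule)."""
    R, zeta = tradeoff_map(spec, z)
    params = base.params.replace(R=R)
    dR_dz = spec.alpha * (spec.Rmax - spec.Rmin) * z ** (spec.alpha - 1.0) if z > 0 else (
        spec.alpha * (spec.Rmax - spec.Rmin) if spec.alpha == 1.0 else 0.0
    )
    dzeta_dz = spec.beta * (spec.zeta_max - spec.zeta_min) * (1.0 - z) ** (spec.beta - 1.0)
    return zeta * _s_prime(params, base.xs) * dR_dz + _survivorship_integral(params, base.xs) * dzeta_dz


def ess_find(
    base: LifeHistory,
    spec: TradeoffSpec,
    n_scan: int = 201,
    z_tol: float = 1e-8,
    curvature_step: float = 1e-4,
) -> ESSResult:
    """Locate the ESS allocation: interior root of dLRS/dz with negative curvature.

    The gradient is sign-scanned on an even z grid, each sign change is
    refined by Brent's method to ``z_tol``, and the curvature d2LRS/dz2
    is read from a central difference of the gradient.  If no interior
    root with negative curvature exists, the better boundary (z = 0 or
    z = 1) is reported with ``is_ess=False``.
    """
    zs = np.linspace(0.0, 1.0, n_scan)
    gs = np.array([dlrs_dz(base, spec, z) for z in zs])
    candidates: list[tuple[float, float, float]] = []
    for k in range(n_scan - 1):
        a, b = zs[k], zs[k + 1]
        ga, gb = gs[k], gs[k + 1]
        if ga == 0.0:
            root = a
        elif ga * gb < 0.0:
            root = float(brentq(lambda z: dlrs_dz(base, spec, z), a, b, xtol=z_tol))
        else:
            continue
        h = curvature_step
        lo, hi = max(root - h, 0.0), min(root + h, 1.0)
        curv = (dlrs_dz(base, spec, hi) - dlrs_dz(base, spec, lo)) / (hi - lo)
        candidates.append((root, dlrs_dz(base, spec, root), curv))
    stable = [c for c in candidates if c[2] < 0.0]
    if stable:
        root, grad, curv = min(stable, key=lambda c: abs(c[1]))
        R_star, zeta_star = tradeoff_map(spec, root)
        return ESSResult(root, R_star, zeta_star, grad, curv, is_ess=True)
    # boundary optimum: pick the end the gradient points toward
    z_b = 1.0 if gs.mean() > 0 else 0.0
    R_b, zeta_b = tradeoff_map(spec, z_b)
    return ESSResult(
        z_b, R_b, zeta_b, float(gs[-1] if z_b == 1.0 else gs[0]), math.nan,
        is_ess=False, boundary=f"z={z_b:g}",
    )


def rmax_rule(base: LifeHistory, threshold: float = TRUNCATION_SURVIVAL) -> float:
    """Largest viable senescence rate: R at which survivorship at xs hits the threshold.

    Encodes "reproduction start-age must precede death" under the global
    truncation convention: solve l(xs; G, R, M) = threshold for R.
    """
    if base.xs <= 0:
        raise ValueError("Rmax is unbounded when reproduction starts at age 0")
    G, M, xs = base.params.G, base.params.M, base.xs
    target = -math.log(threshold)

    def f(R: float) -> float:
        return cumulative_hazard(GompertzMakehamParams(G, R, M), xs) - target

    if f(0.0) >= 0.0:
        raise ValueError(
            "survivorship at xs is below the threshold even without senescence"
        )
    hi = 1.0
    for _ in range(60):
        if f(hi) > 0.0:
            break
        hi *= 2.0
    else:
        raise ValueError("could not bracket Rmax")
    return float(brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-14, maxiter=200))


def _spec_for_fit(base: LifeHistory, alpha: float, beta: float, Rmin: float) -> TradeoffSpec:
    # zeta_max is a placeholder: with zeta_min = 0 the ESS allocation is
    # invariant to it (the gradient scales linearly), so fitting alpha and
    # inferring zeta_max decouple.
    return TradeoffSpec(alpha=alpha, Rmax=rmax_rule(base), zeta_max=1.0, beta=beta, Rmin=Rmin)


def fit_alpha(
    base: LifeHistory,
    beta: float = DEFAULT_BETA,
    Rmin: float = DEFAULT_RMIN,
    coarse_step: float = 0.01,
    fine_step: float = 0.001,
    alpha_range: tuple[float, float] = (1.0, 3.0),
    n_scan: int = 41,
) -> float:
    """Brute-force fit of the trade-off shape exponent alpha.

    Searches alpha on a grid over ``alpha_range`` (coarse step 0.01,
    refined to 0.001 around the best point) minimizing the distance
    between the ESS senescence rate and the observed rate ``base.params.R``.
    Raises if no alpha in range yields an interior ESS.
    """
    R_obs = base.params.R
    if not Rmin < R_obs:
        raise ValueError(f"observed R={R_obs} must exceed Rmin={Rmin}")
    Rmax = rmax_rule(base)
    if not R_obs < Rmax:
        raise ValueError(f"observed R={R_obs} must lie below Rmax={Rmax:.4g}")

    def objective(alpha: float) -> float:
        spec = _spec_for_fit(base, alpha, beta, Rmin)
        res = ess_find(base, spec, n_scan=n_scan)
        return abs(res.R_star - R_obs) if res.is_ess else math.inf

    lo, hi = alpha_range
    coarse = np.arange(lo, hi + coarse_step / 2, coarse_step)
    errs = np.array([objective(a) for a in coarse])
    if not np.any(np.isfinite(errs)):
        raise ValueError("no alpha in range yields an interior ESS")
    best = coarse[int(np.argmin(errs))]
    fine = np.arange(max(lo, best - coarse_step), min(hi, best + coarse_step) + fine_step / 2, fine_step)
    fine_errs = np.array([objective(a) for a in fine])
    return float(fine[int(np.argmin(fine_errs))])


def infer_zeta_max(
    base: LifeHistory,
    alpha: float,
    beta: float = DEFAULT_BETA,
    Rmin: float = DEFAULT_RMIN,
    zeta_min: float = DEFAULT_ZETA_MIN,
) -> float:
    """Reproduction-rate ceiling implied by the trade-off passing through the data.

    Inverts R(z) at the observed senescence rate to get z_obs, then scales
    the reproduction branch so zeta(z_obs) equals the observed rate:
    zeta_max = zeta_min + (zeta_obs - zeta_min) / (1 - (1 - z_obs)^beta).
    """
    if base.zeta is None:
        raise ValueError("inference requires a constant observed reproduction rate")
    Rmax = rmax_rule(base)
    R_obs = base.params.R
    z_obs = ((R_obs - Rmin) / (Rmax - Rmin)) ** (1.0 / alpha)
    if not 0.0 < z_obs <= 1.0:
        raise ValueError(f"observed R maps to allocation z={z_obs:.4g} outside (0, 1]")
    denom = 1.0 - (1.0 - z_obs) ** beta
    return zeta_min + (base.zeta - zeta_min) / denom
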