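"""Gompertz–Makeham demography.

The mortality hazard at age ``x`` is

    mu(x) = G * exp(R * x) + M

where ``G`` is the potential mortality risk from internal damage (the
hazard contributed by damage accumulation at age 0), ``R`` is the
senescence rate (the exponential rate at which that internal risk grows
with age) and ``M`` is the external, age-independent mortality risk.
``R = 0`` encodes negligible senescence: a constant hazard ``G + M``.

Ages are continuous and measured in years throughout the package (the
bundled species parameterizations are annual rates).  All improper age
integrals elsewhere in the package are truncated at the age where only a
fraction ``TRUNCATION_SURVIVAL`` (1e-4) of a cohort is still alive; that
age doubles as the "age of certain mortality" x_d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import yaml
from scipy.optimize import brentq

__all__ = [
    "GompertzMakehamParams",
    "LifeHistory",
    "UnboundedLifespanError",
    "hazard",
    "cumulative_hazard",
    "survival",
    "certain_mortality_age",
    "reproduction_rate",
    "SPECIES",
    "get_species",
    "load_life_history",
    "save_life_history",
    "R_NEGLIGIBLE",
    "TRUNCATION_SURVIVAL",
]

#: Below this value the senescence rate is treated as exactly zero and the
#: analytic R -> 0 limits are used (avoids catastrophic cancellation in
#: (G/R)(e^{Rx}-1) without changing any value beyond 1e-10 relative).
R_NEGLIGIBLE = 1e-10

#: Survivorship below which a cohort is considered extinct; defines the
#: truncation age for all improper integrals and the age of certain
#: mortality x_d.
TRUNCATION_SURVIVAL = 1e-4


class UnboundedLifespanError(ValueError):
    """Raised when the hazard integrates to a finite value (G = M = 0)."""


@dataclass(frozen=True)
class GompertzMakehamParams:
    """The Gompertz–Makeham hazard triple (G, R, M), all per year.

    ``G`` and ``M`` must be non-negative; ``R`` must be non-negative, with
    ``R = 0`` meaning the organism does not senesce.  ``G = M = 0`` is
    representable (a zero hazard) but has no finite lifespan; operations
    that need a proper lifespan distribution raise
    :class:`UnboundedLifespanError`.
    """

    G: float
    R: float
    M: float

    def __post_init__(self) -> None:
        if self.G < 0:
            raise ValueError(f"internal-damage risk G must be >= 0, got {self.G}")
        if self.R < 0:
            raise ValueError(f"senescence rate R must be >= 0, got {self.R}")
        if self.M < 0:
            raise ValueError(f"external mortality M must be >= 0, got {self.M}")

    def replace(self, **changes: float) -> "GompertzMakehamParams":
        return replace(self, **changes)


def _check_age(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("age must be non-negative")
    return x


def hazard(params: GompertzMakehamParams, x):
    """Instantaneous mortality rate mu(x) = G e^{Rx} + M at age(s) ``x``."""
    xa = _check_age(x)
    with np.errstate(over="ignore"):
        mu = params.G * np.exp(params.R * xa) + params.M
    return mu if np.ndim(x) else float(mu)


def cumulative_hazard(params: GompertzMakehamParams, x):
    """Integrated hazard H(x) = int_0^x mu(t) dt.

    Closed form (G/R)(e^{Rx} - 1) + Mx, evaluated as (G/R)expm1(Rx) for
    accuracy; the R -> 0 limit (G + M)x is used below ``R_NEGLIGIBLE``.
    """
    xa = _check_age(x)
    G, R, M = params.G, params.R, params.M
    if R < R_NEGLIGIBLE:
        H = (G + M) * xa
    else:
        with np.errstate(over="ignore"):
            H = (G / R) * np.expm1(R * xa) + M * xa
    return H if np.ndim(x) else float(H)


def survival(params: GompertzMakehamParams, x):
    """Probability l(x) of surviving from birth to age(s) ``x``.

    l(x) = exp(-H(x)); continuous at R = 0 where it reduces to the
    constant-hazard exponential exp(-(G + M)x).
    """
    H = cumulative_hazard(params, x)
    with np.errstate(over="ignore"):
        lx = np.exp(-np.asarray(H))
    return lx if np.ndim(x) else float(lx)


def certain_mortality_age(
    params: GompertzMakehamParams, threshold: float = TRUNCATION_SURVIVAL
) -> float:
    """Age x_d at which survivorship first reaches ``threshold``.

    Solves l(x) = threshold by bracketed root search on the cumulative
    hazard.  Because H(x) >= (G + M)x, the root always lies in
    [0, -ln(threshold)/(G + M)], giving a guaranteed bracket.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    G, R, M = params.G, params.R, params.M
    if G + M <= 0.0:
        raise UnboundedLifespanError(
            "G = M = 0: the hazard never accumulates, no finite age reaches "
            f"survivorship {threshold}"
        )
    target = -math.log(threshold)
    if R < R_NEGLIGIBLE:
        return target / (G + M)
    hi = target / (G + M)

    def f(x: float) -> float:
        # cap: far beyond the root the hazard integral overflows to inf,
        # which Brent's interpolation cannot digest; the sign is all that
        # matters out there
        return min(cumulative_hazard(params, x), 1e6) - target

    return float(brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-14, maxiter=200))


@dataclass(frozen=True)
class LifeHistory:
    """A Gompertz–Makeham hazard plus a reproduction schedule.

    Reproduction starts at age ``xs`` (sexual maturity) and proceeds either
    at a constant rate ``zeta`` (offspring per year) or according to a
    user-supplied rate function ``mx`` of age; ``mx`` is implicitly zero
    below ``xs``.
    """

    params: GompertzMakehamParams
    xs: float
    zeta: float | None = None
    mx: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.xs < 0:
            raise ValueError(f"reproduction start-age xs must be >= 0, got {self.xs}")
        if (self.zeta is None) == (self.mx is None):
            raise ValueError("provide exactly one of a constant rate zeta or a rate function mx")
        if self.zeta is not None and self.zeta < 0:
            raise ValueError(f"reproduction rate zeta must be >= 0, got {self.zeta}")

    # -- convenience delegations ------------------------------------------
    def hazard(self, x):
        return hazard(self.params, x)

    def survival(self, x):
        return survival(self.params, x)

    def certain_mortality_age(self, threshold: float = TRUNCATION_SURVIVAL) -> float:
        return certain_mortality_age(self.params, threshold)

    def reproduction_rate(self, x):
        return reproduction_rate(self, x)

    def lrs(self) -> float:
        from .fitness import lrs

        return lrs(self).value

    def growth_rate(self) -> float:
        from .fitness import euler_lotka_r

        return euler_lotka_r(self).value

    def with_params(self, **changes: float) -> "LifeHistory":
        """Copy with some of G, R, M, xs, zeta replaced."""
        param_changes = {k: v for k, v in changes.items() if k in ("G", "R", "M")}
        other = {k: v for k, v in changes.items() if k not in ("G", "R", "M")}
        lh = self
        if param_changes:
            lh = replace(lh, params=self.params.replace(**param_changes))
        if other:
            lh = replace(lh, **other)
        return lh

    def scale_reproduction(self, factor: float) -> "LifeHistory":
        if self.zeta is not None:
            return replace(self, zeta=self.zeta * factor)
        mx = self.mx
        return replace(self, mx=lambda x, _mx=mx, _f=factor: _f * np.asarray(_mx(x)))


def reproduction_rate(lh: LifeHistory, x):
    """Fecundity rate m(x): zero before ``xs``, the schedule value after."""
    xa = np.asarray(x, dtype=float)
    if lh.zeta is not None:
        out = np.where(xa >= lh.xs, lh.zeta, 0.0)
    else:
        out = np.where(xa >= lh.xs, np.asarray(lh.mx(xa), dtype=float), 0.0)
    return out if np.ndim(x) else float(out)


# ---------------------------------------------------------------------------
# Bundled species parameterizations (annual rates, estimated from wild
# populations; see README).
# ---------------------------------------------------------------------------

SPECIES: dict[str, LifeHistory] = {
    "human": LifeHistory(GompertzMakehamParams(G=0.00041, R=0.071, M=0.00001), xs=13.0, zeta=0.036),
    "killer_whale": LifeHistory(GompertzMakehamParams(G=0.00094, R=0.048, M=0.00001), xs=11.0, zeta=0.051),
    "yellow_baboon": LifeHistory(GompertzMakehamParams(G=0.003, R=0.208, M=0.05), xs=5.0, zeta=0.182),
    "lion": LifeHistory(GompertzMakehamParams(G=0.0025, R=0.325, M=0.0522), xs=2.0, zeta=0.2),
}

_ALIASES = {"whale": "killer_whale", "baboon": "yellow_baboon"}


def get_species(name: str) -> LifeHistory:
    """Look up a bundled species parameterization by name (aliases: whale, baboon)."""
    key = _ALIASES.get(name.lower(), name.lower())
    try:
        return SPECIES[key]
    except KeyError:
        raise KeyError(f"unknown species {name!r}; available: {sorted(SPECIES)}") from None


def load_life_history(path) -> LifeHistory:
    """Read a life history from a flat key-value (YAML) file with keys G, R, M, xs, zeta."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    missing = {"G", "R", "M", "xs", "zeta"} - set(raw)
    if missing:
        raise ValueError(f"life-history file {path} missing keys: {sorted(missing)}")
    return LifeHistory(
        GompertzMakehamParams(G=float(raw["G"]), R=float(raw["R"]), M=float(raw["M"])),
        xs=float(raw["xs"]),
        zeta=float(raw["zeta"]),
    )


def save_life_history(lh: LifeHistory, path) -> None:
    if lh.zeta is None:
        raise ValueError("only constant-rate life histories can be serialized")
    data = {"G": lh.params.G, "R": lh.params.R, "M": lh.params.M, "xs": lh.xs, "zeta": lh.zeta}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
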