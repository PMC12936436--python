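"""Shared adaptive-quadrature convention for age integrals."""

from __future__ import annotations

from typing import Callable

from scipy.integrate import quad

#: Absolute tolerance for every age integral in the package.
QUAD_ABS_TOL = 1e-10
QUAD_REL_TOL = 1e-10
QUAD_LIMIT = 300


def integrate(f: Callable, a: float, b: float) -> tuple[float, float]:
    """Adaptive quadrature of ``f`` on [a, b]; returns (value, error estimate)."""
    if b <= a:
        return 0.0, 0.0
    value, err = quad(f, a, b, epsabs=QUAD_ABS_TOL, epsrel=QUAD_REL_TOL, limit=QUAD_LIMIT)
    return value, err
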