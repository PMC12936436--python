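"""Shared fixtures: bundled species and randomized viable life histories."""

from __future__ import annotations

import numpy as np
import pytest

from senesce.demography import (
    SPECIES,
    GompertzMakehamParams,
    LifeHistory,
    survival,
)
from senesce.fitness import lrs

SPECIES_NAMES = tuple(SPECIES)


@pytest.fixture(scope="session")
def species() -> dict[str, LifeHistory]:
    return dict(SPECIES)


def sample_life_histories(n: int, seed: int) -> list[LifeHistory]:
    """Randomized viable parameter sets (log-uniform rates, realistic ranges).

    Viability: survivorship at maturity above 1% and LRS above 0.05, so
    Euler–Lotka roots and gradients are well-conditioned.
    """
    rng = np.random.default_rng(seed)
    out: list[LifeHistory] = []
    while len(out) < n:
        params = GompertzMakehamParams(
            G=10 ** rng.uniform(-5, -2),
            R=10 ** rng.uniform(np.log10(0.01), np.log10(0.5)),
            M=10 ** rng.uniform(-5, -1),
        )
        xs = rng.uniform(1.0, 15.0)
        zeta = 10 ** rng.uniform(np.log10(0.02), 0.0)
        if survival(params, xs) <= 0.01:
            continue
        lh = LifeHistory(params, xs=xs, zeta=zeta)
        if lrs(lh).value < 0.05:
            continue
        out.append(lh)
    return out


@pytest.fixture(scope="session")
def random_life_histories() -> list[LifeHistory]:
    return sample_life_histories(20, seed=1234)
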