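"""Life-table calibration and synthetic life-table generation.

`GompertzMakehamModel` fits the hazard triple (G, R, M) to an observed
survivorship schedule by nonlinear least squares on the survival curve
conditional on reaching the reproduction start-age (juvenile mortality is
excluded from the hazard fit and folded into the effective reproduction
rate instead).  `simulate_life_table` produces life tables from known
parameters — exactly (closed-form survivorship) or as a finite binomial
cohort — so every calibration path can be tested against known truth.

A life table is the standard (age, lx, mx) schedule: ``survivorship``
lx is the fraction of a birth cohort alive at each age (excluding
juvenile mortality below xs when the ``lx_star`` column carries the
schedule that includes it) and ``fecundity`` mx is the per-capita
offspring rate at that age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .demography import (
    GompertzMakehamParams,
    LifeHistory,
    certain_mortality_age,
    cumulative_hazard,
    reproduction_rate,
    survival,
)

__all__ = [
    "LifeTable",
    "GompertzMakehamModel",
    "GompertzMakehamResults",
    "effective_reproduction_rate",
    "simulate_life_table",
    "DEFAULT_STARTS",
]

#: Multi-start grid of initial values for the least-squares fit.
DEFAULT_STARTS = {
    "G": (1e-4, 1e-3, 1e-2),
    "R": (0.01, 0.1, 0.5),
    "M": (1e-5, 1e-2, 0.1),
}


@dataclass
class LifeTable:
    """Tabulated ages, survivorship and fecundity (ages are interval left endpoints)."""

    ages: np.ndarray
    survivorship: np.ndarray
    fecundity: np.ndarray
    survivorship_with_juvenile: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.survivorship = np.asarray(self.survivorship, dtype=float)
        self.fecundity = np.asarray(self.fecundity, dtype=float)
        if self.survivorship_with_juvenile is not None:
            self.survivorship_with_juvenile = np.asarray(
                self.survivorship_with_juvenile, dtype=float
            )
        n = len(self.ages)
        for name in ("survivorship", "fecundity", "survivorship_with_juvenile"):
            col = getattr(self, name)
            if col is not None and len(col) != n:
                raise ValueError(f"column {name} has length {len(col)}, expected {n}")
        if n and np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if n and (self.survivorship[0] > 1.0 + 1e-12 or np.any(self.survivorship < 0)):
            raise ValueError("survivorship must start at <= 1 and be non-negative")
        if n and np.any(np.diff(self.survivorship) > 1e-12):
            bad = np.nonzero(np.diff(self.survivorship) > 1e-12)[0]
            raise ValueError(f"survivorship must be non-increasing (violations after rows {bad.tolist()})")
        if n and np.any(self.fecundity < 0):
            raise ValueError("fecundity must be non-negative")

    def __len__(self) -> int:
        return len(self.ages)

    def to_dataframe(self) -> pd.DataFrame:
        data = {"age": self.ages, "lx": self.survivorship, "mx": self.fecundity}
        if self.survivorship_with_juvenile is not None:
            data["lx_star"] = self.survivorship_with_juvenile
        return pd.DataFrame(data)

    def to_csv(self, path, sep: str = ",") -> None:
        self.to_dataframe().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LifeTable":
        missing = {"age", "lx", "mx"} - set(df.columns)
        if missing:
            raise ValueError(f"life table needs columns age, lx, mx; missing {sorted(missing)}")
        return cls(
            df["age"].to_numpy(),
            df["lx"].to_numpy(),
            df["mx"].to_numpy(),
            df["lx_star"].to_numpy() if "lx_star" in df.columns else None,
        )

    @classmethod
    def from_csv(cls, path, sep: str | None = None) -> "LifeTable":
        df = pd.read_csv(path, sep=sep, engine="python")
        return cls.from_dataframe(df)


def _interp_survivorship(table: LifeTable, x: float, column: np.ndarray) -> float:
    return float(np.interp(x, table.ages, column))


@dataclass
class GompertzMakehamResults:
    """Fitted hazard parameters with goodness-of-fit diagnostics."""

    params: GompertzMakehamParams
    zeta: float
    xs: float
    sse: float
    converged: bool
    n_obs: int
    anchor_age: float
    identifiable: bool = True

    def life_history(self) -> LifeHistory:
        return LifeHistory(self.params, xs=self.xs, zeta=self.zeta)

    def summary(self) -> str:
        lines = [
            "Gompertz-Makeham survival fit",
            "=" * 46,
            f"{'observations (age >= xs)':<34}{self.n_obs:>12d}",
            f"{'reproduction start-age xs':<34}{self.xs:>12.4g}",
            f"{'anchor age (lx renormalized to 1)':<34}{self.anchor_age:>12.4g}",
            "-" * 46,
            f"{'G  (internal-damage risk /yr)':<34}{self.params.G:>12.6g}",
            f"{'R  (senescence rate /yr)':<34}{self.params.R:>12.6g}",
            f"{'M  (external mortality /yr)':<34}{self.params.M:>12.6g}",
            f"{'zeta (effective reproduction /yr)':<34}{self.zeta:>12.6g}",
            "-" * 46,
            f"{'sum of squared residuals':<34}{self.sse:>12.6g}",
            f"{'converged':<34}{str(self.converged):>12}",
            f"{'identifiable':<34}{str(self.identifiable):>12}",
        ]
        return "\n".join(lines)


class GompertzMakehamModel:
    """Least-squares calibration of (G, R, M) from a life table.

    The observed survivorship at ages >= xs is renormalized to 1 at the
    first tabulated age at or above xs, and compared with the model
    survival conditional on reaching that age,
    l(x)/l(x0) = exp(-(H(x) - H(x0))).  The squared-error loss is
    minimized over (G, R, M) >= 0 from a multi-start grid of initial
    values (nonlinear least squares is prone to local minima here because
    G and M trade off against each other at low R).
    """

    def __init__(self, table: LifeTable, xs: float):
        if xs < 0:
            raise ValueError("xs must be non-negative")
        self.table = table
        self.xs = float(xs)
        keep = (table.ages >= self.xs) & (table.survivorship > 0)
        self.fit_ages = table.ages[keep]
        if len(self.fit_ages) < 4:
            raise ValueError(
                f"need at least 4 ages at or above xs={xs} with positive survivorship, "
                f"got {len(self.fit_ages)}"
            )
        self.anchor_age = float(self.fit_ages[0])
        lx = table.survivorship[keep]
        self.observed = lx / lx[0]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, xs: float) -> "GompertzMakehamModel":
        return cls(LifeTable.from_dataframe(df), xs)

    def _model_curve(self, G: float, R: float, M: float) -> np.ndarray:
        p = GompertzMakehamParams(G=max(G, 0.0), R=max(R, 0.0), M=max(M, 0.0))
        H = cumulative_hazard(p, self.fit_ages) - cumulative_hazard(p, self.anchor_age)
        return np.exp(-np.asarray(H))

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        return self._model_curve(*theta) - self.observed

    def fit(self, starts: dict | None = None) -> GompertzMakehamResults:
        """Run the multi-start bounded least-squares fit and keep the best SSE."""
        if np.ptp(self.observed) < 1e-12:
            warnings.warn(
                "constant survivorship: (G, R) are not identifiable; "
                "returning an external-mortality-only fit",
                stacklevel=2,
            )
            M = self._fit_m_only()
            zeta = effective_reproduction_rate(self.table, self.xs)
            sse = float(np.sum(self._residuals(np.array([0.0, 0.0, M])) ** 2))
            return GompertzMakehamResults(
                GompertzMakehamParams(0.0, 0.0, M), zeta, self.xs, sse,
                converged=True, n_obs=len(self.fit_ages), anchor_age=self.anchor_age,
                identifiable=False,
            )
        grid = starts or DEFAULT_STARTS
        best = None
        for G0 in grid["G"]:
            for R0 in grid["R"]:
                for M0 in grid["M"]:
                    try:
                        sol = least_squares(
                            self._residuals,
                            x0=np.array([G0, R0, M0]),
                            bounds=(np.zeros(3), np.full(3, np.inf)),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14,
                        )
                    except Exception:
                        continue
                    sse = float(np.sum(sol.fun**2))
                    if best is None or sse < best[0]:
                        best = (sse, sol)
        if best is None:
            raise RuntimeError("all least-squares starts failed")
        sse, sol = best
        G, R, M = (max(v, 0.0) for v in sol.x)
        zeta = effective_reproduction_rate(self.table, self.xs)
        return GompertzMakehamResults(
            GompertzMakehamParams(G, R, M), zeta, self.xs, sse,
            converged=bool(sol.success), n_obs=len(self.fit_ages),
            anchor_age=self.anchor_age,
        )

    def _fit_m_only(self) -> float:
        dx = self.fit_ages - self.anchor_age
        # 1-D least squares for exp(-M dx); a coarse scan plus golden refine
        from scipy.optimize import minimize_scalar

        def sse(M: float) -> float:
            return float(np.sum((np.exp(-M * dx) - self.observed) ** 2))

        res = minimize_scalar(sse, bounds=(0.0, 10.0), method="bounded", options={"xatol": 1e-10})
        return float(res.x)


def effective_reproduction_rate(
    table: LifeTable, xs: float, reading: str = "additive"
) -> float:
    """Mean observed fecundity, discounted for juvenile mortality.

    With l(xs) the adult-model survivorship and l*(xs) the survivorship
    including juvenile deaths, the default ("additive") reading is

        zeta = (1 - l(xs) + l*(xs)) * mean(mx at ages >= xs),

    which reduces to the plain mean when no separate juvenile schedule is
    present (l* = l).  ``reading="ratio"`` uses zeta = (l*/l) * mean(mx)
    instead.
    """
    at_or_above = table.ages >= xs
    if not np.any(at_or_above) or not np.any(table.fecundity[at_or_above] > 0):
        raise ValueError(f"no positive fecundity at or above xs={xs}")
    m_bar = float(np.mean(table.fecundity[at_or_above]))
    l_xs = _interp_survivorship(table, xs, table.survivorship)
    if table.survivorship_with_juvenile is None:
        l_star = l_xs
    else:
        l_star = _interp_survivorship(table, xs, table.survivorship_with_juvenile)
    if reading == "additive":
        return (1.0 - l_xs + l_star) * m_bar
    if reading == "ratio":
        if l_xs <= 0:
            raise ValueError("ratio reading undefined at zero adult survivorship")
        return (l_star / l_xs) * m_bar
    raise ValueError("reading must be 'additive' or 'ratio'")


def simulate_life_table(
    truth: LifeHistory,
    age_step: float = 1.0,
    n_individuals: int | None = None,
    juvenile_hazard: float | None = None,
    seed: int | None = None,
) -> LifeTable:
    """Generate a life table from known Gompertz–Makeham truth.

    Deterministic mode (``n_individuals=None``) tabulates the closed-form
    survivorship and the constant post-maturity fecundity on an even age
    grid reaching the certain-mortality age.  Stochastic mode follows a
    birth cohort of ``n_individuals``: interval deaths are binomial with
    the exact conditional death probability 1 - l(x+d)/l(x), and observed
    fecundity is Poisson around the true rate among survivors.  An
    optional constant ``juvenile_hazard`` acting below xs yields the
    additional ``survivorship_with_juvenile`` column (an independent
    cohort draw in stochastic mode).  A fixed seed gives identical
    output.
    """
    if age_step <= 0:
        raise ValueError("age_step must be positive")
    if n_individuals is not None and n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if juvenile_hazard is not None and juvenile_hazard < 0:
        raise ValueError("juvenile_hazard must be >= 0")
    x_max = certain_mortality_age(truth.params)
    ages = np.arange(0.0, x_max + age_step, age_step)
    lx_true = survival(truth.params, ages)
    mx_true = reproduction_rate(truth, ages)
    juvenile_factor = (
        np.exp(-juvenile_hazard * np.minimum(ages, truth.xs))
        if juvenile_hazard is not None
        else None
    )

    if n_individuals is None:
        return LifeTable(
            ages, lx_true, mx_true,
            lx_true * juvenile_factor if juvenile_factor is not None else None,
        )

    rng = np.random.default_rng(seed)

    def cohort(lx_curve: np.ndarray) -> np.ndarray:
        alive = np.empty(len(ages), dtype=int)
        alive[0] = n_individuals
        for i in range(len(ages) - 1):
            if alive[i] == 0:
                alive[i + 1] = 0
                continue
            p_death = 1.0 - lx_curve[i + 1] / lx_curve[i]
            alive[i + 1] = alive[i] - rng.binomial(alive[i], min(max(p_death, 0.0), 1.0))
        return alive

    alive = cohort(lx_true)
    lx_obs = alive / n_individuals
    mx_obs = np.zeros(len(ages))
    adult = ages >= truth.xs
    exposure = alive * age_step
    births = np.zeros(len(ages))
    births[adult] = rng.poisson(np.maximum(exposure[adult] * mx_true[adult], 0.0))
    nz = adult & (alive > 0)
    mx_obs[nz] = births[nz] / exposure[nz]

    lx_star_obs = None
    if juvenile_factor is not None:
        lx_star_obs = cohort(lx_true * juvenile_factor) / n_individuals
    return LifeTable(ages, lx_obs, mx_obs, lx_star_obs)
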