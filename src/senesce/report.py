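"""Pipeline runners: gradient profiles and one-shot species reports."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demography import (
    LifeHistory,
    TRUNCATION_SURVIVAL,
    certain_mortality_age,
    get_species,
    survival,
)
from .feedback import approx_positive_feedback_condition, second_derivative_R
from .fitness import DemographicScenario, apply_density_dependence, euler_lotka_r, lrs
from .gradients import selection_gradient
from .tradeoff import TradeoffSpec, ess_find

__all__ = ["RunConfig", "run_gradient_profile", "run_full_species_report", "render_report"]

logger = logging.getLogger("senesce")

#: Estimator conventionally paired with each density-dependence regime.
REGIME_ESTIMATOR = {
    "none": "euler_lotka_r",
    "dd_reproduction": "lrs",
    "dd_external": "euler_lotka_r",
    "growing": "euler_lotka_r",
    "declining": "euler_lotka_r",
}


@dataclass
class RunConfig:
    """Configuration for the pipeline runners.

    Exactly one of ``species`` (a bundled name) or ``life_history`` must
    be given.  ``estimator=None`` picks the estimator conventional for
    the scenario's regime (LRS under reproduction-limited density
    dependence, Euler–Lotka otherwise).
    """

    species: str | None = None
    life_history: LifeHistory | None = None
    scenario: DemographicScenario = field(default_factory=DemographicScenario)
    estimator: str | None = None
    r_grid: np.ndarray | None = None
    tradeoff: TradeoffSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.species is None) == (self.life_history is None):
            raise ValueError("provide exactly one of species or life_history")

    def resolve(self) -> tuple[LifeHistory, str]:
        lh = self.life_history if self.life_history is not None else get_species(self.species)
        estimator = self.estimator or REGIME_ESTIMATOR[self.scenario.regime]
        return lh, estimator


def run_gradient_profile(config: RunConfig) -> pd.DataFrame:
    """Sweep the senescence rate and tabulate the selection gradient on it.

    Holds every other parameter at the configured values, applies the
    density-dependence regime at each grid point, and returns a DataFrame
    with columns (R, gradient, estimator, method, viable).  Non-viable
    grid points (survivorship at xs below 1e-4) carry NaN gradients.
    """
    lh, estimator = config.resolve()
    grid = config.r_grid
    if grid is None:
        grid = np.linspace(0.0, 0.5, 51)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("senescence-rate grid must be non-negative")
    rows = []
    for R in grid:
        point = lh.with_params(R=float(R))
        if survival(point.params, point.xs) <= TRUNCATION_SURVIVAL:
            logger.warning("viability mask triggered at R=%.4g", R)
            rows.append({"R": R, "gradient": np.nan, "estimator": estimator,
                         "method": "masked", "viable": False})
            continue
        regulated = apply_density_dependence(point, config.scenario)
        g = selection_gradient(regulated, "R", estimator)
        rows.append({"R": R, "gradient": g.value, "estimator": estimator,
                     "method": g.method, "viable": True})
    return pd.DataFrame(rows)


def _section(report: dict, name: str, fn) -> None:
    try:
        report[name] = fn()
    except Exception as exc:  # partial failures reported per section
        logger.warning("report section %r failed: %s", name, exc)
        report[name] = {"error": str(exc)}


def run_full_species_report(config: RunConfig) -> dict:
    """One-shot structured report: fitness, gradients, feedback flags, ESS."""
    lh, _ = config.resolve()
    logger.info("report for %s: G=%g R=%g M=%g xs=%g zeta=%s",
                config.species or "<custom>", lh.params.G, lh.params.R,
                lh.params.M, lh.xs, lh.zeta)
    report: dict = {
        "species": config.species,
        "parameters": {"G": lh.params.G, "R": lh.params.R, "M": lh.params.M,
                       "xs": lh.xs, "zeta": lh.zeta},
        "certain_mortality_age": certain_mortality_age(lh.params),
        "seed": config.seed,
    }

    def fitness_all() -> dict:
        out = {"lrs": lrs(lh).value, "euler_lotka_r": euler_lotka_r(lh).value}
        for regime in ("dd_reproduction", "dd_external", "growing", "declining"):
            scen = DemographicScenario(regime)
            regulated = apply_density_dependence(lh, scen)
            est = REGIME_ESTIMATOR[regime]
            value = lrs(regulated).value if est == "lrs" else euler_lotka_r(regulated).value
            out[regime] = {"estimator": est, "value": value}
        return out

    def gradients_all() -> dict:
        return {
            p: selection_gradient(lh, p, "lrs").value
            for p in ("R", "G", "M", "xs", "zeta")
        }

    def feedback_flags() -> dict:
        near, away = approx_positive_feedback_condition(lh)
        return {
            "second_derivative_R": second_derivative_R(lh, "lrs"),
            "near_zero_R_condition": near,
            "away_from_zero_R_condition": away,
        }

    _section(report, "fitness", fitness_all)
    _section(report, "gradients", gradients_all)
    _section(report, "feedback", feedback_flags)
    if config.tradeoff is not None:
        def ess_section() -> dict:
            res = ess_find(lh, config.tradeoff)
            return {"z_star": res.z_star, "R_star": res.R_star,
                    "zeta_star": res.zeta_star, "is_ess": res.is_ess,
                    "curvature": res.curvature, "boundary": res.boundary}
        _section(report, "ess", ess_section)
    return report


def render_report(report: dict) -> str:
    """Human-readable rendering of a species report."""
    lines = [f"Species report: {report.get('species') or 'custom parameters'}"]
    p = report["parameters"]
    lines.append(
        f"  G={p['G']:g}  R={p['R']:g}  M={p['M']:g}  xs={p['xs']:g}  zeta={p['zeta']}"
    )
    lines.append(f"  certain-mortality age x_d = {report['certain_mortality_age']:.2f} yr")
    for name in ("fitness", "gradients", "feedback", "ess"):
        if name not in report:
            continue
        lines.append(f"  [{name}]")
        section = report[name]
        for key, val in section.items():
            if isinstance(val, dict):
                inner = ", ".join(f"{k}={_fmt(v)}" for k, v in val.items())
                lines.append(f"    {key}: {inner}")
            else:
                lines.append(f"    {key}: {_fmt(val)}")
    return "\n".join(lines)


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)
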