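"""Analysis drivers: OAT sensitivity grid, breakeven scan, horizon sweep.

Every cell of every sweep is an independent, fresh simulation of a
modified copy of the base scenario; nothing is shared or accumulated
between cells, so cell values do not depend on evaluation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .diffusion import informed_trajectories, simulate
from .economics import irr_grid, summarize
from .scenario import ScenarioConfig

__all__ = [
    "SENSITIVITY_QUANTITIES",
    "SENSITIVITY_FACTORS",
    "SweepResult",
    "sensitivity_grid",
    "breakeven_population",
    "max_irr",
    "horizon_sweep",
]

CSV_FLOAT_FORMAT = "%.6f"

#: Inputs and parameters varied one-at-a-time in the sensitivity grid.
SENSITIVITY_QUANTITIES = (
    "production_cost",
    "campaign_spend",
    "cost_per_informed",
    "adoption_cost",
    "sharing_rate",
    "adoption_rate",
    "annual_income",
    "income_gain",
)

#: Default OAT scale multipliers.
SENSITIVITY_FACTORS = (0.25, 0.5, 1.0, 2.0, 4.0)


def _scaled_config(base: ScenarioConfig, quantity: str, factor: float) -> ScenarioConfig:
    """One-at-a-time scaling of a single quantity by ``factor``.

    ``cost_per_informed`` scales 1/b (factor 4 means a 4x more expensive,
    i.e. 4x less efficient, campaign: b/4); ``campaign_spend`` scales every
    entry of the schedule.
    """
    if factor <= 0:
        raise ValueError(f"scale factor must be > 0, got {factor}")
    if quantity == "production_cost":
        return base.replace(production_cost=base.production_cost * factor)
    if quantity == "campaign_spend":
        return base.replace(
            campaign_schedule=tuple(m * factor for m in base.campaign_schedule)
        )
    if quantity == "cost_per_informed":
        return base.replace(spend_efficiency=base.spend_efficiency / factor)
    if quantity == "adoption_cost":
        return base.replace(
            adoption_cost_per_adopter_year=base.adoption_cost_per_adopter_year * factor
        )
    if quantity == "sharing_rate":
        return base.replace(sharing_rate=base.sharing_rate * factor)
    if quantity == "adoption_rate":
        return base.replace(adoption_rate=base.adoption_rate * factor)
    if quantity == "annual_income":
        return base.replace(annual_income=base.annual_income * factor)
    if quantity == "income_gain":
        return base.replace(income_gain=base.income_gain * factor)
    raise ValueError(
        f"unknown sensitivity quantity {quantity!r}; "
        f"expected one of {SENSITIVITY_QUANTITIES}"
    )


def sensitivity_grid(
    base: ScenarioConfig,
    factors: Sequence[float] = SENSITIVITY_FACTORS,
    quantities: Sequence[str] = SENSITIVITY_QUANTITIES,
) -> pd.DataFrame:
    """One-at-a-time sensitivity table.

    For each (quantity, factor) pair, exactly one quantity of ``base`` is
    scaled and the full model re-run; the row records IRR, total cost,
    total revenue, time to inform 10% and final adopters.  Factor-1 rows
    reproduce the unmodified base summary exactly.
    """
    rows = []
    for quantity in quantities:
        for factor in factors:
            config = _scaled_config(base, quantity, factor)
            summary = summarize(simulate(config))
            rows.append(
                {
                    "quantity": quantity,
                    "factor": float(factor),
                    "irr": np.nan if summary.irr is None else summary.irr,
                    "total_cost": summary.total_cost,
                    "total_revenue": summary.total_revenue,
                    "time_to_10pct": (
                        np.nan if summary.time_to_10pct is None else summary.time_to_10pct
                    ),
                    "adopters": summary.final_adopters,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SweepResult:
    """Population-size scan: per-point IRR plus breakeven and peak IRR.

    ``irr`` is NaN where no IRR is defined.  ``breakeven_population`` is
    the first scanned population whose initiative clears the 0% IRR
    threshold (None when none does); ``refined_breakeven`` optionally
    sharpens it between the bracketing grid points, but the grid answer
    is canonical.
    """

    populations: np.ndarray
    irr: np.ndarray
    breakeven_population: Optional[int]
    max_irr: Optional[float]
    refined_breakeven: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"population": self.populations, "irr": self.irr})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)

    def summary_dict(self) -> dict:
        return {
            "breakeven_population": self.breakeven_population,
            "max_irr": self.max_irr,
            "refined_breakeven": self.refined_breakeven,
        }

    def save_summary(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary_dict(), indent=2) + "\n")


def _cashflow_matrix(populations: np.ndarray, config: ScenarioConfig) -> np.ndarray:
    """Yearly cashflows, one row per population size."""
    informed = informed_trajectories(populations, config)
    T = config.horizon_years
    rev_factor = config.adoption_rate * config.annual_income * config.income_gain
    cost_factor = config.adoption_rate * config.adoption_cost_per_adopter_year
    spending = np.concatenate([np.asarray(config.campaign_schedule, float), [0.0]])
    flows = np.empty_like(informed)
    flows[:, 0] = -(config.production_cost + spending[0])
    flows[:, 1:] = informed[:, 1:] * (rev_factor - cost_factor) - spending[1:]
    return flows


def _meets_breakeven(flows: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """0%-IRR threshold test per row.

    A defined IRR must be >= 0.  Rows without a defined IRR fail, except
    the degenerate all-nonnegative ledgers with positive total (nothing
    invested, something earned), which clear the threshold trivially.
    """
    defined = ~np.isnan(rates)
    costless = (flows >= 0).all(axis=1) & (flows > 0).any(axis=1)
    return (defined & (rates >= 0)) | costless


def breakeven_population(
    base: ScenarioConfig,
    min_pop: int = 1,
    max_pop: int = 10_000_000,
    step: int = 100,
    *,
    refine: bool = False,
) -> SweepResult:
    """Scan population sizes for the smallest with IRR >= 0.

    Simulates every population on the arithmetic grid ``min_pop,
    min_pop+step, ...`` with all other configuration unchanged (initial
    informed stays at the configured *fraction* of each population; the
    campaign budget is exogenous and fixed).  Also reports the maximum
    defined IRR over the grid.
    """
    if min_pop < 1:
        raise ValueError(f"min_pop must be >= 1, got {min_pop}")
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    populations = np.arange(min_pop, max_pop + 1, step, dtype=float)
    if populations.size == 0:
        raise ValueError(f"empty population grid: [{min_pop}, {max_pop}] step {step}")
    flows = _cashflow_matrix(populations, base)
    rates = irr_grid(flows)
    meets = _meets_breakeven(flows, rates)
    hits = np.nonzero(meets)[0]
    breakeven = int(populations[hits[0]]) if hits.size else None
    peak = float(np.nanmax(rates)) if np.any(~np.isnan(rates)) else None

    refined = None
    if refine and breakeven is not None and hits[0] > 0:
        lo = float(populations[hits[0] - 1])
        hi = float(breakeven)
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            f = _cashflow_matrix(np.array([mid]), base)
            if _meets_breakeven(f, irr_grid(f))[0]:
                hi = mid
            else:
                lo = mid
        refined = hi
    elif refine and breakeven is not None:
        refined = float(breakeven)
    return SweepResult(
        populations=populations,
        irr=rates,
        breakeven_population=breakeven,
        max_irr=peak,
        refined_breakeven=refined,
    )


def max_irr(
    base: ScenarioConfig,
    max_pop: int = 10_000_000,
    min_pop: int = 1,
    step: int = 100,
) -> Optional[float]:
    """Maximum defined IRR over the population grid (None if all undefined)."""
    return breakeven_population(base, min_pop, max_pop, step).max_irr


def horizon_sweep(
    base: ScenarioConfig,
    horizons: Iterable[int] = (3, 5, 10, 15, 30),
    min_pop: int = 1,
    max_pop: int = 10_000_000,
    step: int = 100,
) -> pd.DataFrame:
    """Breakeven population and peak IRR per impact period.

    Each horizon re-runs the full population scan with revenue and
    adoption costs accruing through that horizon; the campaign schedule
    keeps its configured spending years and is padded with zeros beyond
    them.
    """
    rows = []
    for horizon in horizons:
        config = base.replace(horizon_years=int(horizon))
        result = breakeven_population(config, min_pop, max_pop, step)
        rows.append(
            {
                "horizon_years": int(horizon),
                "breakeven_population": (
                    np.nan
                    if result.breakeven_population is None
                    else result.breakeven_population
                ),
                "max_irr": np.nan if result.max_irr is None else result.max_irr,
            }
        )
    return pd.DataFrame(rows)
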