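"""Adoption, revenue, cashflow ledger and internal rate of return.

Each year the informed stock converts into adopters (``I * adoption
rate``) who realise a proportional income gain; the initiative pays a
one-time production cost at year 0, the campaign budget in the year it is
spent, and a recurring per-adopter cost.  Returns are summarised by the
internal rate of return (IRR): the discount rate at which the net present
value (NPV) of the yearly cashflows is zero, located here by bracketing
and bisection on the package's own NPV function.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Optional, Union

import numpy as np
import pandas as pd

from .scenario import ScenarioConfig

if TYPE_CHECKING:  # pragma: no cover
    from .diffusion import Trajectory

__all__ = [
    "CashflowLedger",
    "ReturnsSummary",
    "LedgerConsistencyError",
    "MultipleIRRWarning",
    "adopters",
    "revenue",
    "build_ledger",
    "npv",
    "irr",
    "irr_grid",
    "summarize",
]

CSV_FLOAT_FORMAT = "%.6f"

#: IRR search domain, expressed as u = 1 + r (per-year gross rate).
_U_MIN, _U_MAX = 1e-6, 1e9


class LedgerConsistencyError(ValueError):
    """Trajectory and config passed to the ledger builder disagree."""


class MultipleIRRWarning(UserWarning):
    """The cashflow sign pattern admits more than one IRR root."""


def adopters(informed, adoption_rate: float):
    """Adopting-farmer count, ``I * adoption_rate`` (real-valued).

    Reporting layers round to whole farmers; the dynamics never do.
    Accepts scalars or arrays.
    """
    if not 0.0 <= adoption_rate <= 1.0:
        raise ValueError(f"adoption_rate must be in [0, 1], got {adoption_rate}")
    if np.any(np.asarray(informed) < 0):
        raise ValueError("informed count must be >= 0")
    return informed * adoption_rate


def revenue(informed, adoption_rate: float, annual_income: float, income_gain: float):
    """Yearly income uplift, ``I * adoption_rate * annual_income * income_gain``.

    Accepts scalars or arrays.
    """
    if annual_income < 0 or income_gain < 0:
        raise ValueError("annual_income and income_gain must be >= 0")
    return adopters(informed, adoption_rate) * annual_income * income_gain


@dataclass(frozen=True)
class CashflowLedger:
    """Per-year cash in, cash out and net cashflow (USD) for years 0..T."""

    years: np.ndarray
    cash_in: np.ndarray
    cash_out: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.years) == len(self.cash_in) == len(self.cash_out)):
            raise ValueError("years, cash_in and cash_out must have equal length")

    @property
    def cashflow(self) -> np.ndarray:
        return self.cash_in - self.cash_out

    @property
    def total_revenue(self) -> float:
        return float(self.cash_in.sum())

    @property
    def total_cost(self) -> float:
        return float(self.cash_out.sum())

    def __len__(self) -> int:
        return len(self.years)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "cash_in": self.cash_in,
                "cash_out": self.cash_out,
                "cashflow": self.cashflow,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def build_ledger(
    trajectory: "Trajectory", config: Optional[ScenarioConfig] = None
) -> CashflowLedger:
    """Assemble the cashflow ledger for a simulated trajectory.

    Cash out at year 0 is the one-time production cost plus the first
    year's campaign spending; in later years it is that year's campaign
    spending (zero beyond the schedule) plus the per-adopter cost on the
    current adopting stock.  Cash in is the yearly revenue, recognised
    from year 1 on the end-of-year informed count.
    """
    if config is None:
        config = trajectory.config
    elif config != trajectory.config:
        raise LedgerConsistencyError(
            "trajectory was simulated under a different configuration"
        )
    T = config.horizon_years
    spending = np.concatenate([np.asarray(config.campaign_schedule, float), [0.0]])
    cash_in = np.concatenate([[0.0], np.asarray(trajectory.revenue, float)])
    adoption_costs = config.adoption_cost_per_adopter_year * np.asarray(
        trajectory.adopters, float
    )
    cash_out = spending.copy()
    cash_out[0] += config.production_cost
    cash_out[1:] += adoption_costs
    return CashflowLedger(years=np.arange(T + 1), cash_in=cash_in, cash_out=cash_out)


def _as_flows(ledger) -> np.ndarray:
    if isinstance(ledger, CashflowLedger):
        return np.asarray(ledger.cashflow, dtype=float)
    return np.asarray(ledger, dtype=float)


def npv(rate: float, ledger) -> float:
    """Net present value ``sum_t cashflow(t) / (1 + rate)^t``.

    ``ledger`` may be a :class:`CashflowLedger` or a plain sequence of
    yearly cashflows starting at year 0.
    """
    if rate <= -1.0:
        raise ValueError(f"rate must be > -1, got {rate}")
    flows = _as_flows(ledger)
    t = np.arange(flows.size, dtype=float)
    return float(np.sum(flows * (1.0 + rate) ** (-t)))


def _sign_changes(flows: np.ndarray) -> int:
    nonzero = flows[flows != 0]
    if nonzero.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(np.sign(nonzero))))


def irr(ledger, *, rtol: float = 1e-10) -> Optional[float]:
    """Internal rate of return: smallest root of ``npv(r) = 0``, ``r > -1``.

    The root is bracketed by a sign scan of NPV over a logarithmic grid of
    gross rates ``1 + r`` spanning ``(1e-6, 1e9)`` and then refined by
    bisection to relative tolerance ``rtol``.  Returns ``None`` when the
    cashflows show no sign change (all-nonnegative or all-nonpositive
    flows admit no IRR).  A :class:`MultipleIRRWarning` is attached when
    the sign pattern admits several roots; the smallest is returned.
    """
    flows = _as_flows(ledger)
    if flows.size < 2:
        raise ValueError("IRR requires at least two cashflow periods")
    if not ((flows > 0).any() and (flows < 0).any()):
        return None
    if _sign_changes(flows) > 1:
        warnings.warn(
            "cashflow sign pattern admits multiple IRR roots; "
            "returning the smallest",
            MultipleIRRWarning,
            stacklevel=2,
        )
    t = np.arange(flows.size, dtype=float)
    grid = np.logspace(np.log10(_U_MIN), np.log10(_U_MAX), 601)
    vals = (grid[:, None] ** (-t)) @ flows
    signs = np.sign(vals)
    crossing = np.nonzero(signs[:-1] * signs[1:] <= 0)[0]
    # Exact zero at a grid point counts as the root itself.
    zeros = np.nonzero(signs == 0)[0]
    if zeros.size and (crossing.size == 0 or zeros[0] <= crossing[0]):
        return float(grid[zeros[0]] - 1.0)
    if crossing.size == 0:
        return None
    k = int(crossing[0])
    lo, hi = math.log(grid[k]), math.log(grid[k + 1])
    f_lo = vals[k]
    while hi - lo > rtol:
        mid = 0.5 * (lo + hi)
        f_mid = float(np.sum(flows * math.exp(mid) ** (-t)))
        if f_mid == 0.0:
            lo = hi = mid
            break
        if (f_mid > 0) == (f_lo > 0):
            lo = mid
        else:
            hi = mid
    return float(math.exp(0.5 * (lo + hi)) - 1.0)


def irr_grid(cashflows: np.ndarray, *, rtol: float = 1e-10) -> np.ndarray:
    """Row-wise IRR of a matrix of cashflow series (NaN where undefined).

    Vectorised counterpart of :func:`irr` for parameter sweeps: the same
    bracketing grid and bisection are applied to every row at once.
    """
    flows = np.asarray(cashflows, dtype=float)
    if flows.ndim != 2 or flows.shape[1] < 2:
        raise ValueError("cashflows must be (n, >=2)")
    n = flows.shape[0]
    t = np.arange(flows.shape[1], dtype=float)
    defined = (flows > 0).any(axis=1) & (flows < 0).any(axis=1)
    out = np.full(n, np.nan)

    grid = np.logspace(np.log10(_U_MIN), np.log10(_U_MAX), 151)
    lo = np.full(n, np.nan)
    hi = np.full(n, np.nan)
    v_lo = np.empty(n)
    prev = flows @ (grid[0] ** (-t))
    u_prev = grid[0]
    for u in grid[1:]:
        cur = flows @ (u ** (-t))
        fresh = defined & np.isnan(lo) & (np.sign(prev) * np.sign(cur) <= 0)
        if fresh.any():
            lo[fresh] = u_prev
            hi[fresh] = u
            v_lo[fresh] = prev[fresh]
        prev = cur
        u_prev = u

    bracketed = ~np.isnan(lo)
    if not bracketed.any():
        return out
    llo = np.log(lo[bracketed])
    lhi = np.log(hi[bracketed])
    sub = flows[bracketed]
    s_lo = np.sign(v_lo[bracketed])
    for _ in range(80):
        mid = 0.5 * (llo + lhi)
        v = (sub * np.exp(mid)[:, None] ** (-t)).sum(axis=1)
        same = np.sign(v) == s_lo
        llo = np.where(same, mid, llo)
        lhi = np.where(same, lhi, mid)
        if np.max(lhi - llo) <= rtol:
            break
    out[bracketed] = np.exp(0.5 * (llo + lhi)) - 1.0
    return out


@dataclass(frozen=True)
class ReturnsSummary:
    """Headline economics of one simulated initiative.

    ``irr`` and ``time_to_10pct`` are ``None`` when undefined / not
    reached; adopter counts are rounded to whole farmers.
    """

    irr: Optional[float]
    total_revenue: float
    total_cost: float
    time_to_10pct: Optional[float]
    adopters_at_10pct: Optional[int]
    final_adopters: int

    def to_dict(self) -> dict:
        return {
            "irr": self.irr,
            "total_revenue": self.total_revenue,
            "total_cost": self.total_cost,
            "time_to_10pct": self.time_to_10pct,
            "adopters_at_10pct": self.adopters_at_10pct,
            "final_adopters": self.final_adopters,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def summarize(
    trajectory: "Trajectory",
    ledger: Optional[CashflowLedger] = None,
    config: Optional[ScenarioConfig] = None,
    *,
    fraction: float = 0.10,
) -> ReturnsSummary:
    """Compute the returns summary for a trajectory (building the ledger
    if one is not supplied).  ``fraction`` sets the reach milestone used
    for the time-to-informed and adopters-at-milestone fields."""
    from .diffusion import time_to_informed_fraction

    if config is None:
        config = trajectory.config
    if ledger is None:
        ledger = build_ledger(trajectory, config)
    t_reach = time_to_informed_fraction(trajectory, fraction)
    if t_reach is None:
        adopters_at = None
    else:
        adopters_at = int(
            round(adopters(fraction * config.population_size, config.adoption_rate))
        )
    return ReturnsSummary(
        irr=irr(ledger),
        total_revenue=ledger.total_revenue,
        total_cost=ledger.total_cost,
        time_to_10pct=t_reach,
        adopters_at_10pct=adopters_at,
        final_adopters=int(
            round(adopters(float(trajectory.informed[-1]), config.adoption_rate))
        ),
    )
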