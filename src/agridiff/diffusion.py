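"""Discrete-time susceptible-informed (SI) information diffusion.

The population is split into susceptible farmers ``S(t)`` (would want the
information but do not have it) and informed farmers ``I(t)``.  Knowledge
moves one way, S -> I, through two channels each year:

* peer sharing, ``a * S(t) * I(t) / P`` under frequency-dependent mixing
  (default) or the raw product ``a * S(t) * I(t)`` under mass action;
* campaign spending, ``b * M(t)``, where ``M(t)`` USD spent in year ``t``
  informs farmers counted at year ``t + 1``.

There is no recovery, forgetting or demography, so ``S(t) + I(t) = P`` at
every step and ``I`` is nondecreasing.  The joint yearly increment is
capped at ``S(t)`` so the susceptible pool never goes negative.  Counts
are real-valued throughout; rounding to whole farmers happens only in the
reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import economics
from .scenario import FREQUENCY, MASS_ACTION, MIXING_MODES, ScenarioConfig

__all__ = [
    "PopulationState",
    "Trajectory",
    "SequencingError",
    "sharing_increment",
    "spending_increment",
    "step",
    "simulate",
    "informed_trajectories",
    "time_to_informed_fraction",
]

CSV_FLOAT_FORMAT = "%.6f"


class SequencingError(RuntimeError):
    """Raised when a step is requested beyond the configured horizon."""


@dataclass(frozen=True)
class PopulationState:
    """Compartment counts at one annual time point.

    Attributes
    ----------
    year
        Simulation year, 0-based.
    susceptible
        ``S(t)``, real-valued count of not-yet-informed farmers.
    informed
        ``I(t)``, real-valued count of informed farmers.
    """

    year: int
    susceptible: float
    informed: float

    def __post_init__(self) -> None:
        if self.year < 0:
            raise ValueError(f"year must be >= 0, got {self.year}")
        if self.susceptible < 0 or self.informed < 0:
            raise ValueError(
                f"compartment counts must be >= 0, got S={self.susceptible}, "
                f"I={self.informed}"
            )

    @property
    def population(self) -> float:
        return self.susceptible + self.informed


def sharing_increment(
    susceptible: float,
    informed: float,
    sharing_rate: float,
    mixing_mode: str = FREQUENCY,
    population_size: Optional[float] = None,
) -> float:
    """Newly informed farmers from peer sharing in one year.

    Returns ``a*S*I/P`` under frequency mixing and ``a*S*I`` under mass
    action.  The value is *not* clamped to the susceptible pool; clamping
    is the responsibility of :func:`step`, which caps the joint sharing +
    spending increment.
    """
    if susceptible < 0 or informed < 0:
        raise ValueError(
            f"counts must be >= 0, got S={susceptible}, I={informed}"
        )
    if sharing_rate < 0:
        raise ValueError(f"sharing_rate must be >= 0, got {sharing_rate}")
    if mixing_mode not in MIXING_MODES:
        raise ValueError(f"mixing_mode must be one of {MIXING_MODES}")
    product = sharing_rate * susceptible * informed
    if mixing_mode == MASS_ACTION:
        return product
    if population_size is None:
        population_size = susceptible + informed
    if population_size <= 0:
        return 0.0
    return product / population_size


def spending_increment(money_prev_year: float, spend_efficiency: float) -> float:
    """Newly informed farmers purchased by ``M`` USD of campaign spending.

    The linear reach model ``b * M``: each dollar informs ``b`` farmers,
    equivalently one new informed farmer costs ``1/b`` dollars.  Unclamped.
    """
    if money_prev_year < 0:
        raise ValueError(f"spending must be >= 0, got {money_prev_year}")
    if spend_efficiency < 0:
        raise ValueError(
            f"spend_efficiency must be >= 0, got {spend_efficiency}"
        )
    return spend_efficiency * money_prev_year


def step(state: PopulationState, config: ScenarioConfig) -> PopulationState:
    """Advance the population one year.

    The joint increment ``min(S(t), sharing + spending)`` moves from S to
    I, so conservation ``S + I = P`` holds exactly under any parameters.
    Spending uses ``campaign_schedule[t]``: money spent in year ``t``
    produces informed farmers counted at year ``t + 1``.
    """
    t = state.year
    if t >= config.horizon_years:
        raise SequencingError(
            f"cannot step from year {t}: horizon is {config.horizon_years} years"
        )
    shared = sharing_increment(
        state.susceptible,
        state.informed,
        config.sharing_rate,
        config.mixing_mode,
        config.population_size,
    )
    bought = spending_increment(config.campaign_schedule[t], config.spend_efficiency)
    increment = min(state.susceptible, shared + bought)
    return PopulationState(
        year=t + 1,
        susceptible=state.susceptible - increment,
        informed=state.informed + increment,
    )


@dataclass(frozen=True)
class Trajectory:
    """A simulated diffusion path with its derived economic series.

    ``susceptible``/``informed`` hold ``S(t)``, ``I(t)`` for years
    ``0..T``; ``adopters`` and ``revenue`` hold the derived per-year series
    for years ``1..T`` (revenue recognition starts at year 1).
    """

    config: ScenarioConfig
    years: np.ndarray
    susceptible: np.ndarray
    informed: np.ndarray
    adopters: np.ndarray
    revenue: np.ndarray

    @property
    def population_size(self) -> float:
        return self.config.population_size

    @property
    def states(self) -> list[PopulationState]:
        return [
            PopulationState(int(t), float(s), float(i))
            for t, s, i in zip(self.years, self.susceptible, self.informed)
        ]

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-year table (derived series are 0 at year 0)."""
        T = self.config.horizon_years
        return pd.DataFrame(
            {
                "year": self.years,
                "susceptible": self.susceptible,
                "informed": self.informed,
                "adopters": np.concatenate([[0.0], self.adopters]),
                "revenue": np.concatenate([[0.0], self.revenue]),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def simulate(config: ScenarioConfig) -> Trajectory:
    """Run the annual SI recurrence for the configured horizon.

    Returns the ``T + 1`` states together with the per-year adopter and
    revenue series.  The model is fully deterministic.
    """
    errors = config.validation_errors()
    if errors:
        from .scenario import ScenarioError

        raise ScenarioError(errors)
    T = config.horizon_years
    states = [
        PopulationState(0, config.initial_susceptible, config.initial_informed)
    ]
    for _ in range(T):
        states.append(step(states[-1], config))
    informed = np.array([s.informed for s in states])
    susceptible = np.array([s.susceptible for s in states])
    adopters = economics.adopters(informed[1:], config.adoption_rate)
    revenue = economics.revenue(
        informed[1:],
        config.adoption_rate,
        config.annual_income,
        config.income_gain,
    )
    return Trajectory(
        config=config,
        years=np.arange(T + 1),
        susceptible=susceptible,
        informed=informed,
        adopters=np.asarray(adopters, dtype=float),
        revenue=np.asarray(revenue, dtype=float),
    )


def informed_trajectories(
    population_sizes: np.ndarray, config: ScenarioConfig
) -> np.ndarray:
    """Vectorised ``I(t)`` paths across many population sizes.

    Runs the same recurrence as :func:`simulate` for every entry of
    ``population_sizes`` simultaneously, keeping the initial informed
    fraction, campaign schedule and all rates fixed.  Returns an array of
    shape ``(len(population_sizes), horizon_years + 1)``.
    """
    P = np.asarray(population_sizes, dtype=float)
    if P.ndim != 1 or P.size == 0:
        raise ValueError("population_sizes must be a non-empty 1-D array")
    if np.any(P <= 0):
        raise ValueError("population sizes must be > 0")
    T = config.horizon_years
    a = config.sharing_rate
    b = config.spend_efficiency
    informed = np.empty((P.size, T + 1), dtype=float)
    I = config.initial_informed_fraction * P
    S = P - I
    informed[:, 0] = I
    for t in range(T):
        shared = a * S * I
        if config.mixing_mode == FREQUENCY:
            shared = shared / P
        inc = np.minimum(S, shared + b * config.campaign_schedule[t])
        I = I + inc
        S = S - inc
        informed[:, t + 1] = I
    return informed


def time_to_informed_fraction(
    trajectory: Trajectory, fraction: float
) -> Optional[float]:
    """Years until ``I(t)`` first reaches ``fraction`` of the population.

    Linear interpolation between the two annual states bracketing the
    first crossing gives a fractional year; 0.0 when the threshold is
    already met at year 0; ``None`` when it is never reached within the
    horizon.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    target = fraction * trajectory.population_size
    informed = trajectory.informed
    if informed[0] >= target:
        return 0.0
    above = np.nonzero(informed >= target)[0]
    if above.size == 0:
        return None
    t = int(above[0])
    lo, hi = informed[t - 1], informed[t]
    return float(t - 1 + (target - lo) / (hi - lo))
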