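"""Daily Wisconsin energy-balance model.

Growth is the residual of the whole-fish daily energy budget

    G = C - (R + SDA + E + U)        [J/day]

with consumption and respiration modelled as power functions of mass times
temperature-dependence functions: an exponential for respiration and the
Thornton-Lessem unimodal curve for consumption (peaking at the laboratory
preferendum CTO, reaching zero at the feeding ceiling CTM). Egestion and
excretion are fixed proportions of consumption, specific dynamic action a
fixed proportion of respiration. Mass is stepped daily by G converted to
wet mass through the predator energy density.

All kernels accept scalars or numpy arrays and broadcast, which is what
makes whole-ensemble, whole-network projection cheap: a year is 365 vector
operations regardless of how many (reach, parameter-set) pairs are stepped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import PhysiologyParams, SimulationSettings

__all__ = [
    "DailyBudget",
    "GrowthTrajectory",
    "consumption_temp_factor",
    "respiration_temp_factor",
    "daily_energy_budget",
    "simulate_trajectory",
    "simulate_batch",
    "growing_season_metrics",
    "longest_positive_run",
    "last_positive_day",
    "mass_to_length",
    "length_to_mass",
    "trajectory_frame",
]


@dataclass(frozen=True)
class DailyBudget:
    """One day's energy budget (all energy terms in J/day)."""

    day: int
    temperature: float
    C: float
    R: float
    SDA: float
    E: float
    U: float
    G: float
    mass_start: float
    mass_end: float


@dataclass(frozen=True)
class GrowthTrajectory:
    """A full simulated year of daily budgets plus phenology summaries."""

    budgets: tuple[DailyBudget, ...]
    end_of_year_mass: float
    growing_season_days: int
    end_of_growing_season_day: int | None
    end_of_growing_season_length: float | None
    clamped: bool = False


def _tl_params(params: PhysiologyParams) -> tuple[float, float]:
    """Thornton-Lessem shape constants (X and the CTM-CTO window)."""
    if not params.CTM > params.CTO:
        raise ValueError("degenerate temperature window: CTM must exceed CTO")
    if not params.CQ > 1:
        raise ValueError("CQ must exceed 1")
    span = params.CTM - params.CTO
    Z = np.log(params.CQ) * span
    Y = np.log(params.CQ) * (span + 2.0)
    X = (Z**2 * (1.0 + np.sqrt(1.0 + 40.0 / Y)) ** 2) / 400.0
    return X, span


def consumption_temp_factor(T, params: PhysiologyParams):
    """Thornton-Lessem temperature dependence of consumption, in [0, 1].

    f(T) = V**X * exp(X * (1 - V)) with V = (CTM - T)/(CTM - CTO);
    equals 1 exactly at T = CTO and 0 for T >= CTM.
    """
    X, span = _tl_params(params)
    T = np.asarray(T, dtype=float)
    V = (params.CTM - T) / span
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(V > 0.0, V**X * np.exp(X * (1.0 - V)), 0.0)
    return f if f.ndim else float(f)


def respiration_temp_factor(T, params: PhysiologyParams):
    """Exponential temperature dependence of respiration: exp(RQ * T)."""
    T = np.asarray(T, dtype=float)
    f = np.exp(params.RQ * T)
    return f if f.ndim else float(f)


def _budget_terms(mass, T, settings: SimulationSettings, p):
    """Vectorized budget terms. `p` maps parameter name -> scalar or array."""
    fC = _tl_factor_arrays(T, p)
    C = p["CA"] * mass ** p["CB"] * fC * settings.CP * mass * p["ED_prey"]
    R = (
        p["RA"] * mass ** p["RB"] * np.exp(p["RQ"] * T)
        * settings.RACT * mass * p["OXY"]
    )
    E = p["FA"] * C
    U = p["UA"] * C
    if settings.sda_on_consumption:
        SDA = p["SA"] * (C - E)
    else:
        SDA = p["SA"] * R
    G = C - (R + SDA + E + U)
    return C, R, SDA, E, U, G


def _tl_factor_arrays(T, p):
    span = p["CTM"] - p["CTO"]
    Z = np.log(p["CQ"]) * span
    Y = np.log(p["CQ"]) * (span + 2.0)
    X = (Z**2 * (1.0 + np.sqrt(1.0 + 40.0 / Y)) ** 2) / 400.0
    V = (p["CTM"] - T) / span
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(V > 0.0, V**X * np.exp(X * (1.0 - V)), 0.0)


def daily_energy_budget(
    mass: float,
    T: float,
    settings: SimulationSettings,
    params: PhysiologyParams,
    day: int = 1,
) -> DailyBudget:
    """One day's budget for a fish of given mass at temperature T (degC)."""
    if not mass > 0:
        raise ValueError("mass must be positive")
    p = {k: float(v) for k, v in params.as_dict().items()}
    C, R, SDA, E, U, G = (
        float(x) for x in _budget_terms(float(mass), float(T), settings, p)
    )
    mass_end = max(mass + G / params.ED_pred, settings.mass_floor)
    return DailyBudget(
        day=day, temperature=float(T), C=C, R=R, SDA=SDA, E=E, U=U, G=G,
        mass_start=float(mass), mass_end=mass_end,
    )


def simulate_trajectory(
    daily_temps,
    settings: SimulationSettings,
    params: PhysiologyParams,
) -> GrowthTrajectory:
    """Simulate daily growth over the year (days 1..n_days).

    Mass is updated as mass + G/ED_pred each day, clamped at the mass floor
    (no mortality is modelled; clamping is recorded on the trajectory).
    """
    temps = np.asarray(daily_temps, dtype=float)
    if temps.shape != (settings.n_days,):
        raise ValueError(
            f"daily_temps must have length n_days={settings.n_days}, "
            f"got shape {temps.shape}"
        )
    if np.isnan(temps).any():
        raise ValueError("daily_temps contains NaN")

    p = {k: float(v) for k, v in params.as_dict().items()}
    budgets = []
    mass = float(settings.initial_mass)
    clamped = False
    for day in range(1, settings.n_days + 1):
        T = float(temps[day - 1])
        C, R, SDA, E, U, G = (
            float(x) for x in _budget_terms(mass, T, settings, p)
        )
        mass_end = mass + G / params.ED_pred
        if mass_end < settings.mass_floor:
            mass_end = settings.mass_floor
            clamped = True
        budgets.append(DailyBudget(day, T, C, R, SDA, E, U, G, mass, mass_end))
        mass = mass_end

    G_vec = np.array([b.G for b in budgets])
    season_days = longest_positive_run(G_vec)
    eogs_day = last_positive_day(G_vec)
    eogs_length = None
    if eogs_day is not None:
        eogs_length = mass_to_length(budgets[eogs_day - 1].mass_end, settings)
    return GrowthTrajectory(
        budgets=tuple(budgets),
        end_of_year_mass=mass,
        growing_season_days=season_days,
        end_of_growing_season_day=eogs_day,
        end_of_growing_season_length=eogs_length,
        clamped=clamped,
    )


def simulate_batch(
    daily_temps: np.ndarray,
    settings: SimulationSettings,
    param_arrays: dict[str, np.ndarray],
    CP: float | None = None,
) -> dict[str, np.ndarray]:
    """Simulate many (temperature-series, parameter-set) pairs at once.

    Parameters
    ----------
    daily_temps
        Array of shape (n_series, n_days): one row per reach/year series.
    param_arrays
        Mapping of every :class:`PhysiologyParams` field to an array of
        shape (n_sets,) (scalars broadcast).
    CP
        Optional override of ``settings.CP`` (scenario consumption level).

    Returns
    -------
    dict with arrays over (n_series, n_sets):
    ``end_mass``, ``growing_season_days``, ``eogs_day`` (0 where no surplus
    day exists), ``eogs_mass`` (NaN where undefined), ``clamped``; plus
    ``mass`` and ``G`` of shape (n_series, n_sets, n_days).
    """
    temps = np.atleast_2d(np.asarray(daily_temps, dtype=float))
    n_series, n_days = temps.shape
    if n_days != settings.n_days:
        raise ValueError(f"expected {settings.n_days} daily temperatures")
    if np.isnan(temps).any():
        raise ValueError("daily temperatures contain NaN")
    if CP is not None:
        settings = settings.replace(CP=CP)

    p = {k: np.asarray(v, dtype=float) for k, v in param_arrays.items()}
    n_sets = max(v.size for v in p.values())
    shape = (n_series, n_sets)

    mass = np.full(shape, float(settings.initial_mass))
    masses = np.empty(shape + (n_days,))
    G_all = np.empty(shape + (n_days,))
    clamped = np.zeros(shape, dtype=bool)
    for d in range(n_days):
        T = temps[:, d][:, None]
        _, _, _, _, _, G = _budget_terms(mass, T, settings, p)
        ED_pred = p["ED_pred"]
        new_mass = mass + G / ED_pred
        below = new_mass < settings.mass_floor
        clamped |= below
        mass = np.where(below, settings.mass_floor, new_mass)
        masses[:, :, d] = mass
        G_all[:, :, d] = G

    surplus = G_all > 0.0
    season = _longest_run_bool(surplus)
    # last surplus day (1-based Julian); 0 where no surplus day at all
    day_idx = np.arange(1, n_days + 1)
    eogs_day = np.where(surplus.any(axis=-1), (surplus * day_idx).max(axis=-1), 0)
    eogs_mass = np.full(shape, np.nan)
    has = eogs_day > 0
    if has.any():
        idx = np.clip(eogs_day - 1, 0, n_days - 1)
        eogs_mass_all = np.take_along_axis(masses, idx[..., None], axis=-1)[..., 0]
        eogs_mass = np.where(has, eogs_mass_all, np.nan)
    return {
        "end_mass": masses[:, :, -1],
        "growing_season_days": season,
        "eogs_day": eogs_day,
        "eogs_mass": eogs_mass,
        "clamped": clamped,
        "mass": masses,
        "G": G_all,
    }


def _longest_run_bool(surplus: np.ndarray) -> np.ndarray:
    """Longest run of True along the last axis (vectorized)."""
    x = surplus.astype(np.int64)
    run = np.zeros(x.shape[:-1], dtype=np.int64)
    best = np.zeros_like(run)
    for d in range(x.shape[-1]):
        run = (run + 1) * x[..., d]
        best = np.maximum(best, run)
    return best


def longest_positive_run(G) -> int:
    """Length of the longest consecutive run of strictly positive values."""
    return int(_longest_run_bool(np.asarray(G, dtype=float)[None, :] > 0.0)[0])


def last_positive_day(G) -> int | None:
    """Highest 1-based index with a strictly positive value, or None."""
    pos = np.flatnonzero(np.asarray(G, dtype=float) > 0.0)
    return int(pos[-1]) + 1 if pos.size else None


def growing_season_metrics(trajectory: GrowthTrajectory) -> tuple[int, int | None]:
    """(longest surplus run, last surplus Julian day or None)."""
    G = [b.G for b in trajectory.budgets]
    if not G:
        raise ValueError("trajectory is empty")
    return longest_positive_run(G), last_positive_day(G)


def mass_to_length(mass, settings: SimulationSettings):
    """Invert the allometric length-weight relation: L = (W/a)**(1/b), mm."""
    mass = np.asarray(mass, dtype=float)
    if np.any(mass <= 0):
        raise ValueError("mass must be positive")
    L = (mass / settings.lw_a) ** (1.0 / settings.lw_b)
    return L if L.ndim else float(L)


def length_to_mass(length, settings: SimulationSettings):
    """W = a * L**b with L in mm, W in g."""
    length = np.asarray(length, dtype=float)
    if np.any(length <= 0):
        raise ValueError("length must be positive")
    W = settings.lw_a * length**settings.lw_b
    return W if W.ndim else float(W)


def trajectory_frame(trajectory: GrowthTrajectory) -> pd.DataFrame:
    """Daily budgets as a tidy table (one row per day)."""
    return pd.DataFrame(
        {
            "day": [b.day for b in trajectory.budgets],
            "temperature_C": [b.temperature for b in trajectory.budgets],
            "C_J": [b.C for b in trajectory.budgets],
            "R_J": [b.R for b in trajectory.budgets],
            "SDA_J": [b.SDA for b in trajectory.budgets],
            "E_J": [b.E for b in trajectory.budgets],
            "U_J": [b.U for b in trajectory.budgets],
            "G_J": [b.G for b in trajectory.budgets],
            "mass_g": [b.mass_end for b in trajectory.budgets],
        }
    )
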