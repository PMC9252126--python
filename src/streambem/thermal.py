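"""Daily water temperature from monthly air-temperature climatologies.

A two-step construction per reach: (1) convert each monthly mean air
temperature to water temperature through a logistic (sigmoid) air-water
relationship; (2) fit a single-harmonic sine to the 12 monthly water
temperatures, anchored at mid-month Julian days, and evaluate it on all
365 days. The sine fit uses the exact linear least-squares
reparameterization T(d) = mean + a*sin(wd) + b*cos(wd), so there is no
iterative optimizer and no initialization to document.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MID_MONTH_DAYS",
    "AirWaterModel",
    "MonthlyClimatology",
    "AnnualSineModel",
    "fixture_air_water_model",
    "air_to_water",
    "fit_annual_sine",
    "daily_temperatures",
    "daily_water_from_monthly_air",
]

#: Julian day of the middle of each month (non-leap year).
MID_MONTH_DAYS = np.array(
    [15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349], dtype=float
)

PERIOD_DAYS = 365.0


@dataclass(frozen=True)
class AirWaterModel:
    """Logistic air-to-water temperature response.

    water = lower + (upper - lower) / (1 + exp(steepness*(inflection - air)))
    """

    lower_asymptote: float
    upper_asymptote: float
    inflection: float
    steepness: float

    def __post_init__(self) -> None:
        if not self.upper_asymptote > self.lower_asymptote:
            raise ValueError("upper_asymptote must exceed lower_asymptote")
        if not self.steepness > 0:
            raise ValueError("steepness must be positive")


@dataclass(frozen=True)
class MonthlyClimatology:
    """Twelve monthly mean temperatures (degC), January..December."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != 12:
            raise ValueError(f"expected 12 monthly values, got {len(self.values)}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("monthly values must be finite")

    @property
    def mid_days(self) -> np.ndarray:
        return MID_MONTH_DAYS.copy()


@dataclass(frozen=True)
class AnnualSineModel:
    """T(d) = mean + amplitude * sin(2*pi*d/365 + phase)."""

    mean: float
    amplitude: float
    phase: float
    rss: float = 0.0
    period: float = PERIOD_DAYS

    def __post_init__(self) -> None:
        if not self.amplitude >= 0:
            raise ValueError("amplitude must be nonnegative")
        if self.period != PERIOD_DAYS:
            raise ValueError("period is fixed at 365 days")


def fixture_air_water_model() -> AirWaterModel:
    """Fixture logistic coefficients for a warm-temperate climate zone.

    Fixture values (plausible for warm-temperate streams), not taken from
    any published zone-specific regression.
    """
    return AirWaterModel(
        lower_asymptote=0.8, upper_asymptote=32.0, inflection=15.0, steepness=0.14
    )


def air_to_water(T_air, model: AirWaterModel):
    """Water temperature (degC) from air temperature via the logistic model."""
    T_air = np.asarray(T_air, dtype=float)
    span = model.upper_asymptote - model.lower_asymptote
    w = model.lower_asymptote + span / (
        1.0 + np.exp(model.steepness * (model.inflection - T_air))
    )
    return w if w.ndim else float(w)


def fit_annual_sine(monthly_water, mid_days=None) -> AnnualSineModel:
    """Least-squares sine fit to 12 (mid-month day, water temp) pairs.

    Solved exactly via the linear form mean + a*sin(wd) + b*cos(wd), then
    amplitude = hypot(a, b) and phase = atan2(b, a) in (-pi, pi].
    """
    y = np.asarray(monthly_water, dtype=float)
    if y.shape != (12,):
        raise ValueError(f"expected 12 monthly water temperatures, got {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError("monthly water temperatures must be finite")
    d = MID_MONTH_DAYS if mid_days is None else np.asarray(mid_days, dtype=float)
    w = 2.0 * np.pi * d / PERIOD_DAYS
    A = np.column_stack([np.ones_like(d), np.sin(w), np.cos(w)])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    mean, a, b = coef
    amplitude = float(np.hypot(a, b))
    phase = float(np.arctan2(b, a)) if amplitude > 0 else 0.0
    rss = float(np.sum((A @ coef - y) ** 2))
    return AnnualSineModel(mean=float(mean), amplitude=amplitude, phase=phase, rss=rss)


def daily_temperatures(model: AnnualSineModel, n_days: int = 365) -> np.ndarray:
    """Evaluate the annual sine on Julian days 1..n_days."""
    d = np.arange(1, n_days + 1, dtype=float)
    return model.mean + model.amplitude * np.sin(
        2.0 * np.pi * d / model.period + model.phase
    )


def daily_water_from_monthly_air(
    monthly_air, air_water: AirWaterModel, n_days: int = 365
) -> np.ndarray:
    """Full pipeline: monthly air -> sigmoid -> sine fit -> 365 daily values."""
    monthly_air = np.asarray(monthly_air, dtype=float)
    water = air_to_water(monthly_air, air_water)
    sine = fit_annual_sine(water)
    return daily_temperatures(sine, n_days=n_days)
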