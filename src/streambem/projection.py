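"""Per-reach, per-scenario projection of growth and growing season.

Each reach carries a monthly air-temperature climatology per climate key
(columns ``<climate_key>_month_1..12``). For every (reach, scenario) pair
the daily water-temperature series is built through the thermal pipeline,
the validated parameter ensemble is simulated over it, and ensemble
summaries are reported: mean and CV of end-of-year mass, median longest
surplus run (growing-season days), and the ensemble size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bem, thermal
from .ensemble import ParameterEnsemble, ensemble_summary
from .params import SimulationSettings

__all__ = [
    "Scenario",
    "DEFAULT_SCENARIOS",
    "project_reach",
    "project_all",
    "change_between",
    "regional_summary",
]


@dataclass(frozen=True)
class Scenario:
    """A named combination of climate columns and consumption level."""

    name: str
    climate_key: str
    CP: float

    def __post_init__(self) -> None:
        if not 0 <= self.CP <= 1:
            raise ValueError(f"scenario {self.name}: CP must lie in [0, 1]")


#: The five standard scenarios: historical baseline, two emissions pathways,
#: and the moderate pathway with consumption suppressed/enhanced by 10%.
DEFAULT_SCENARIOS = (
    Scenario("historical", "hist", 0.5),
    Scenario("rcp45", "rcp45", 0.5),
    Scenario("rcp85", "rcp85", 0.5),
    Scenario("rcp45_suppressed", "rcp45", 0.45),
    Scenario("rcp45_enhanced", "rcp45", 0.55),
)


def _month_cols(climate_key: str) -> list[str]:
    return [f"{climate_key}_month_{m}" for m in range(1, 13)]


def reach_daily_temps(
    reach_table: pd.DataFrame,
    climate_key: str,
    air_water: thermal.AirWaterModel,
    n_days: int = 365,
) -> np.ndarray:
    """Daily water temperatures for every reach: (n_reaches, n_days)."""
    cols = _month_cols(climate_key)
    missing = [c for c in cols if c not in reach_table.columns]
    if missing:
        raise KeyError(f"reach table lacks climatology columns: {missing}")
    monthly_air = reach_table[cols].to_numpy(dtype=float)
    water = thermal.air_to_water(monthly_air, air_water)
    out = np.empty((len(reach_table), n_days))
    for i in range(len(reach_table)):
        sine = thermal.fit_annual_sine(water[i])
        out[i] = thermal.daily_temperatures(sine, n_days=n_days)
    return out


def project_reach(
    reach_row: pd.Series,
    scenario: Scenario,
    validated: ParameterEnsemble,
    settings: SimulationSettings,
    air_water: thermal.AirWaterModel,
) -> dict:
    """Project one reach under one scenario; ensemble summaries as a dict."""
    table = reach_row.to_frame().T
    return _project_scenario(table, scenario, validated, settings, air_water)[0]


def _project_scenario(
    reach_table: pd.DataFrame,
    scenario: Scenario,
    validated: ParameterEnsemble,
    settings: SimulationSettings,
    air_water: thermal.AirWaterModel,
) -> list[dict]:
    if validated.n < 1:
        raise ValueError("need at least one validated parameter set")
    temps = reach_daily_temps(reach_table, scenario.climate_key, air_water,
                              n_days=settings.n_days)
    out = bem.simulate_batch(temps, settings, validated.as_arrays(),
                             CP=scenario.CP)
    end_mass = out["end_mass"]          # (n_reaches, n_sets)
    season = out["growing_season_days"]
    rows = []
    for i, reach_id in enumerate(reach_table["reach_id"]):
        if validated.n >= 2:
            mean_mass, cv = ensemble_summary(end_mass[i])
        else:
            mean_mass, cv = float(end_mass[i, 0]), 0.0
        rows.append(
            {
                "reach_id": reach_id,
                "scenario": scenario.name,
                "mean_mass_g": mean_mass,
                "cv_mass": cv,
                "growing_season_days": float(np.median(season[i])),
                "n_sets": validated.n,
            }
        )
    return rows


def project_all(
    reach_table: pd.DataFrame,
    scenarios,
    validated: ParameterEnsemble,
    settings: SimulationSettings,
    air_water: thermal.AirWaterModel,
    chunk_size: int | None = None,
) -> pd.DataFrame:
    """Cartesian product of reaches x scenarios, ordered by (reach_id, scenario).

    ``chunk_size`` splits the reach table into blocks that are projected
    independently; results are identical to a single pass (pure per-reach
    computation), it only bounds peak memory.
    """
    if len(reach_table) == 0 or not scenarios:
        raise ValueError("need at least one reach and one scenario")
    if reach_table["reach_id"].duplicated().any():
        dupes = reach_table.loc[reach_table["reach_id"].duplicated(), "reach_id"]
        raise ValueError(f"duplicate reach_ids: {sorted(set(dupes))}")
    rows: list[dict] = []
    n = len(reach_table)
    step = chunk_size or n
    for scenario in scenarios:
        for start in range(0, n, step):
            block = reach_table.iloc[start : start + step]
            rows.extend(
                _project_scenario(block, scenario, validated, settings, air_water)
            )
    df = pd.DataFrame(rows).sort_values(["reach_id", "scenario"], kind="mergesort")
    return df.reset_index(drop=True)


def change_between(
    results: pd.DataFrame, baseline: str, comparison: str
) -> pd.DataFrame:
    """Per-reach absolute and percent change between two scenarios.

    Percent change is (comparison - baseline)/baseline * 100; it is NaN
    (undefined) where the baseline is nonpositive.
    """
    have = set(results["scenario"].unique())
    for name in (baseline, comparison):
        if name not in have:
            raise ValueError(f"scenario {name!r} absent from results")
    b = results[results["scenario"] == baseline].set_index("reach_id")
    c = results[results["scenario"] == comparison].set_index("reach_id")
    if not b.index.sort_values().equals(c.index.sort_values()):
        raise ValueError("baseline and comparison cover different reaches")
    c = c.reindex(b.index)
    out = pd.DataFrame(
        {
            "reach_id": b.index,
            "baseline": baseline,
            "comparison": comparison,
            "mass_change_g": (c["mean_mass_g"] - b["mean_mass_g"]).to_numpy(),
            "season_change_days": (
                c["growing_season_days"] - b["growing_season_days"]
            ).to_numpy(),
        }
    )
    base_mass = b["mean_mass_g"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(
            base_mass > 0, (c["mean_mass_g"].to_numpy() - base_mass) / base_mass * 100,
            np.nan,
        )
    out["mass_change_pct"] = np.round(pct, 1)
    return out.reset_index(drop=True)


def regional_summary(
    results: pd.DataFrame, mask: pd.Series | None = None
) -> pd.DataFrame:
    """Median and range across reaches per scenario, optionally masked.

    ``mask`` is a boolean series aligned to the reach table (e.g. the
    historically occupied subset); by default all reaches are summarized.
    """
    df = results
    if mask is not None:
        keep = set(mask.index[mask.astype(bool)])
        df = df[df["reach_id"].isin(keep)]
    if df.empty:
        raise ValueError("no reaches left after masking")
    agg = df.groupby("scenario").agg(
        median_mass_g=("mean_mass_g", "median"),
        min_mass_g=("mean_mass_g", "min"),
        max_mass_g=("mean_mass_g", "max"),
        median_season_days=("growing_season_days", "median"),
        min_season_days=("growing_season_days", "min"),
        max_season_days=("growing_season_days", "max"),
        n_reaches=("reach_id", "count"),
    )
    return agg.reset_index()
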