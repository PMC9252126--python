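"""Physiological parameter sets and simulation settings.

The energy-balance model is parameterized by laboratory-derived constants
for a surrogate species: mass- and temperature-dependence of maximum
consumption and routine respiration, fixed waste proportions, energy
densities, and the oxycalorific coefficient. :class:`PhysiologyParams`
carries those constants; :class:`SimulationSettings` carries the
per-simulation knobs (initial mass, realized consumption proportion,
activity multiplier, length-weight relation).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "PhysiologyParams",
    "SimulationSettings",
    "DEFAULT_PERTURBED_NAMES",
    "fixture_params",
    "read_params_csv",
    "write_params_csv",
]

#: Parameters perturbed by default during ensemble resampling. CP, RACT,
#: ED_prey and OXY are simulation inputs or physical constants and stay fixed.
DEFAULT_PERTURBED_NAMES = (
    "CA", "CB", "CQ", "CTO", "CTM",
    "RA", "RB", "RQ", "FA", "UA", "SA", "ED_pred",
)

_UNITS = {
    "CA": "g_prey/g_fish/day", "CB": "dimensionless", "CQ": "dimensionless",
    "CTO": "degC", "CTM": "degC",
    "RA": "g_O2/g_fish/day", "RB": "dimensionless", "RQ": "1/degC",
    "FA": "proportion", "UA": "proportion", "SA": "proportion",
    "ED_prey": "J/g_wet", "ED_pred": "J/g_wet", "OXY": "J/g_O2",
}


@dataclass(frozen=True)
class PhysiologyParams:
    """Constants of the daily whole-fish energy budget.

    Parameters
    ----------
    CA, CB
        Coefficient and mass exponent of maximum mass-specific consumption
        (g prey / g fish / day at 1 g).
    CQ
        Approximate Q10 of consumption at low temperature (> 1).
    CTO
        Laboratory temperature preferendum (degC): consumption scope peaks here.
    CTM
        Temperature above which feeding ceases (degC).
    RA, RB
        Coefficient and mass exponent of routine respiration
        (g O2 / g fish / day at 1 g).
    RQ
        Temperature slope of respiration (1/degC).
    FA, UA
        Egestion and excretion as fixed proportions of consumption.
    SA
        Specific dynamic action as a fixed proportion of respiration.
    ED_prey, ED_pred
        Prey and predator wet-mass energy densities (J/g).
    OXY
        Oxycalorific coefficient (J released per g O2 consumed).
    """

    CA: float
    CB: float
    CQ: float
    CTO: float
    CTM: float
    RA: float
    RB: float
    RQ: float
    FA: float
    UA: float
    SA: float
    ED_prey: float
    ED_pred: float
    OXY: float

    def __post_init__(self) -> None:
        if not self.CTM > self.CTO:
            raise ValueError(f"CTM ({self.CTM}) must exceed CTO ({self.CTO})")
        if not self.CQ > 1:
            raise ValueError(f"CQ must exceed 1, got {self.CQ}")
        for name in ("CA", "RA", "ED_prey", "ED_pred", "OXY"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("FA", "UA", "SA"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1), got {v}")
        if not self.FA + self.UA < 1:
            raise ValueError("FA + UA must be < 1 (assimilation must be positive)")

    def replace(self, **changes: float) -> "PhysiologyParams":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))


@dataclass(frozen=True)
class SimulationSettings:
    """Per-run inputs of a growth simulation.

    ``CP`` is the proportion of maximum consumption actually realized (a
    surrogate for prey availability), ``RACT`` scales routine respiration
    for activity costs, and ``lw_a``/``lw_b`` define the allometric
    length-weight relation W = lw_a * L**lw_b (W in g, L in mm).
    """

    initial_mass: float = 6.4
    CP: float = 0.5
    RACT: float = 1.0
    n_days: int = 365
    lw_a: float = 4.83e-6
    lw_b: float = 3.191
    mass_floor: float = 0.01
    sda_on_consumption: bool = False

    def __post_init__(self) -> None:
        if not self.initial_mass > 0:
            raise ValueError("initial_mass must be positive")
        if not 0 <= self.CP <= 1:
            raise ValueError(f"CP must lie in [0, 1], got {self.CP}")
        if not self.RACT >= 1:
            raise ValueError(f"RACT must be >= 1, got {self.RACT}")
        if not self.n_days >= 1:
            raise ValueError("n_days must be >= 1")
        if not (self.lw_a > 0 and self.lw_b > 0):
            raise ValueError("length-weight coefficients must be positive")
        if not self.mass_floor > 0:
            raise ValueError("mass_floor must be positive")

    def replace(self, **changes) -> "SimulationSettings":
        return dataclasses.replace(self, **changes)


def fixture_params() -> PhysiologyParams:
    """Shipped fixture parameter set (black-bass-like, literature-plausible).

    These are fixture values for testing and examples, NOT measurements for
    any particular population. ED_pred in particular is a fixture constant
    (~1 kcal/g wet mass, typical of juvenile centrarchids).
    """
    return PhysiologyParams(
        CA=0.33, CB=-0.325, CQ=2.65, CTO=27.5, CTM=36.0,
        RA=0.00279, RB=-0.355, RQ=0.0811,
        FA=0.104, UA=0.068, SA=0.163,
        ED_prey=3698.0, ED_pred=4186.0, OXY=13560.0,
    )


def read_params_csv(path: str | Path) -> tuple[PhysiologyParams, list[str]]:
    """Read a parameter file: columns (name, value, units, perturb).

    Returns the parameter set and the list of names flagged for ensemble
    perturbation.
    """
    df = pd.read_csv(path)
    required = {"name", "value", "units", "perturb"}
    if set(df.columns) != required:
        raise ValueError(
            f"parameter file must have columns {sorted(required)}, "
            f"got {sorted(df.columns)}"
        )
    known = set(PhysiologyParams.field_names())
    names = list(df["name"])
    unknown = set(names) - known
    if unknown:
        raise ValueError(f"unknown parameter names: {sorted(unknown)}")
    missing = known - set(names)
    if missing:
        raise ValueError(f"missing parameters: {sorted(missing)}")
    if len(names) != len(set(names)):
        raise ValueError("duplicate parameter rows")
    values = {row["name"]: float(row["value"]) for _, row in df.iterrows()}
    perturbed = [
        row["name"] for _, row in df.iterrows()
        if str(row["perturb"]).strip().lower() in ("true", "1", "yes")
    ]
    return PhysiologyParams(**values), perturbed


def write_params_csv(
    params: PhysiologyParams,
    path: str | Path,
    perturbed_names: tuple[str, ...] = DEFAULT_PERTURBED_NAMES,
) -> None:
    rows = [
        {
            "name": name,
            "value": value,
            "units": _UNITS[name],
            "perturb": name in perturbed_names,
        }
        for name, value in params.as_dict().items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
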