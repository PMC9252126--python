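"""Parameter-ensemble resampling and growth validation.

Because physiological constants borrowed from a surrogate species are only
approximately right for the focal species, an ensemble of perturbed
parameter sets is generated by independent uniform resampling within
+/- perturb_fraction of each base value (default 5%). Each set is then run
over the empirical-validation temperature series; sets whose simulated
end-of-growing-season length falls within a relative tolerance (default
+/-2.5%) of the empirical target length are retained for projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bem
from .params import DEFAULT_PERTURBED_NAMES, PhysiologyParams, SimulationSettings

__all__ = [
    "ParameterEnsemble",
    "ValidationResult",
    "resample_parameters",
    "validate_ensemble",
    "ensemble_summary",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParameterEnsemble:
    """A base parameter set plus n perturbed copies, with provenance."""

    base: PhysiologyParams
    sets: tuple[PhysiologyParams, ...]
    perturb_fraction: float
    seed: int
    perturbed_names: tuple[str, ...]
    n_redraws: int = 0

    @property
    def n(self) -> int:
        return len(self.sets)

    def subset(self, indices) -> "ParameterEnsemble":
        sets = tuple(self.sets[i] for i in indices)
        return ParameterEnsemble(
            base=self.base, sets=sets, perturb_fraction=self.perturb_fraction,
            seed=self.seed, perturbed_names=self.perturbed_names,
            n_redraws=self.n_redraws,
        )

    def as_arrays(self) -> dict[str, np.ndarray]:
        """Parameter fields as (n,) arrays, for vectorized simulation."""
        names = PhysiologyParams.field_names()
        return {
            name: np.array([getattr(s, name) for s in self.sets], dtype=float)
            for name in names
        }

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([s.as_dict() for s in self.sets])
        df.insert(0, "set_id", np.arange(len(self.sets)))
        return df


@dataclass(frozen=True)
class ValidationResult:
    """Per-set simulated lengths, pass flags and the validated subset."""

    sim_length_mm: np.ndarray
    empirical_length_mm: float
    tolerance: float
    passed: np.ndarray
    validated_indices: np.ndarray

    @property
    def pass_fraction(self) -> float:
        return float(np.mean(self.passed))


def resample_parameters(
    base: PhysiologyParams,
    n: int,
    perturb_fraction: float = 0.05,
    seed: int = 0,
    perturbed_names=DEFAULT_PERTURBED_NAMES,
    max_redraws: int = 1000,
) -> ParameterEnsemble:
    """Draw n parameter sets uniformly within +/-perturb_fraction of base.

    Each named parameter is drawn independently from
    Uniform(base*(1-f), base*(1+f)); unnamed parameters stay exactly at the
    base value. Draws violating the parameter invariants (e.g. a perturbed
    CTO crossing CTM) are redrawn whole-set, so accepted margins remain
    uniform. Deterministic given the seed (numpy PCG64 Generator).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= perturb_fraction < 1:
        raise ValueError("perturb_fraction must lie in [0, 1)")
    perturbed_names = tuple(perturbed_names)
    known = set(PhysiologyParams.field_names())
    unknown = set(perturbed_names) - known
    if unknown:
        raise ValueError(f"unknown parameter names: {sorted(unknown)}")
    if not perturbed_names:
        log.warning("empty perturbed_names: ensemble is degenerate (all = base)")

    rng = np.random.default_rng(seed)
    base_dict = base.as_dict()
    sets: list[PhysiologyParams] = []
    n_redraws = 0

    def draw() -> PhysiologyParams:
        values = dict(base_dict)
        for name in perturbed_names:
            b = base_dict[name]
            lo, hi = b * (1 - perturb_fraction), b * (1 + perturb_fraction)
            if lo > hi:  # negative base value flips the bounds
                lo, hi = hi, lo
            values[name] = rng.uniform(lo, hi)
        return PhysiologyParams(**values)

    for _ in range(n):
        for attempt in range(max_redraws + 1):
            try:
                sets.append(draw())
                break
            except ValueError:
                n_redraws += 1
        else:
            raise RuntimeError(
                f"could not draw a valid parameter set in {max_redraws} redraws"
            )
    if n_redraws:
        log.warning("redrew %d invalid parameter sets", n_redraws)
    return ParameterEnsemble(
        base=base, sets=tuple(sets), perturb_fraction=perturb_fraction,
        seed=seed, perturbed_names=perturbed_names, n_redraws=n_redraws,
    )


def validate_ensemble(
    ensemble: ParameterEnsemble,
    validation_temps,
    settings: SimulationSettings,
    empirical_length: float,
    tolerance: float = 0.025,
) -> ValidationResult:
    """Retain parameter sets that reproduce the empirical growth target.

    Each set is simulated over every validation temperature series (one
    365-day series per reach-year); its mass on the last surplus day of
    each series is converted to length and averaged across series
    (unweighted). A set passes if that mean length lies within
    +/-tolerance (relative) of the empirical length. Sets with any series
    lacking a surplus day have undefined length and fail.
    """
    temps = np.atleast_2d(np.asarray(validation_temps, dtype=float))
    if temps.shape[0] < 1:
        raise ValueError("need at least one validation temperature series")
    if not empirical_length > 0:
        raise ValueError("empirical_length must be positive")
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")

    out = bem.simulate_batch(temps, settings, ensemble.as_arrays())
    eogs_mass = out["eogs_mass"]  # (n_series, n_sets); NaN if no surplus day
    defined = ~np.isnan(eogs_mass).any(axis=0)
    n_undef = int((~defined).sum())
    if n_undef:
        log.warning(
            "%d parameter sets had a validation series with no surplus day", n_undef
        )
    sim_length = np.full(ensemble.n, np.nan)
    if defined.any():
        lengths = bem.mass_to_length(eogs_mass[:, defined], settings)
        sim_length[defined] = lengths.mean(axis=0)
    with np.errstate(invalid="ignore"):
        rel_err = np.abs(sim_length - empirical_length) / empirical_length
        passed = defined & (rel_err <= tolerance)
    return ValidationResult(
        sim_length_mm=sim_length,
        empirical_length_mm=float(empirical_length),
        tolerance=float(tolerance),
        passed=passed,
        validated_indices=np.flatnonzero(passed),
    )


def ensemble_summary(values) -> tuple[float, float]:
    """(mean, CV) of per-set outputs; CV uses the sample (n-1) SD.

    CV is reported as a proportion. A nonpositive mean leaves the CV
    undefined (NaN, with a warning) rather than reporting a sign-flipped
    ratio.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values for an ensemble summary")
    mean = float(np.mean(v))
    if mean <= 0:
        log.warning("nonpositive ensemble mean (%g): CV undefined", mean)
        return mean, float("nan")
    return mean, float(np.std(v, ddof=1) / mean)
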