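"""Exchange-rate estimation from batch fermentation time courses.

The rate rule is the pseudo-steady-state one: the net concentration change
of a species over a short window of the nearly stationary growth phase,
divided by the window duration and the biomass, converted to
mmol gDW^-1 h^-1 via the species molar mass:

    rate = +/- (C(t2) - C(t1)) * 1000 / M / (t2 - t1) / X_mean

with the sign chosen so that uptake rates (glucose, ethanol) and formation
rates (total acid) are both positive in their nominal direction.  ``X_mean``
is the time-average (trapezoidal) biomass over the window, which equals the
endpoint mean for linear biomass drift and the constant for stationary
biomass.  Total acid, a titration measurement, is converted as acetic acid
equivalents (60.05 g mol^-1).

The default window is 48-60 h, the high-rate, near-stationary stretch of the
JST-S fermentations.  The two-point difference is the default estimator; an
ordinary least-squares slope over all samples in the window is available for
noisy data and reports a standard error.

Biomass must be supplied in gDW L^-1 (or converted by the caller with an
explicit wet-to-dry factor); no default conversion is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import RateEstimationError
from .solver import MeasuredRates

__all__ = [
    "SpeciesSpec",
    "SPECIES",
    "TimeCourse",
    "RateEstimate",
    "PseudoSteadyStateReport",
    "DEFAULT_WINDOW",
    "net_formation_rate",
    "estimate_measured_rates",
    "check_pseudo_steady_state",
    "TIMECOURSE_COLUMNS",
]

#: Near-stationary, high-rate window (hours) used when none is given.
DEFAULT_WINDOW = (48.0, 60.0)

#: Required CSV columns for a time course.
TIMECOURSE_COLUMNS = (
    "time_h",
    "glucose_gL",
    "ethanol_gL",
    "total_acid_gL",
    "biomass_gDW_L",
)


@dataclass(frozen=True)
class SpeciesSpec:
    """A measured species: molar mass and nominal exchange direction."""

    name: str
    molar_mass: float  # g mol^-1
    direction: str  # "uptake" or "formation"
    column: str

    def __post_init__(self) -> None:
        if not self.molar_mass > 0:
            raise ValueError("molar_mass must be positive")
        if self.direction not in ("uptake", "formation"):
            raise ValueError("direction must be 'uptake' or 'formation'")

    @property
    def sign(self) -> float:
        """+1 keeps formation positive; -1 flips uptake to positive."""
        return -1.0 if self.direction == "uptake" else 1.0


SPECIES: dict[str, SpeciesSpec] = {
    "glucose": SpeciesSpec("glucose", 180.16, "uptake", "glucose_gL"),
    "ethanol": SpeciesSpec("ethanol", 46.07, "uptake", "ethanol_gL"),
    "total_acid": SpeciesSpec("total_acid", 60.05, "formation", "total_acid_gL"),
}


class TimeCourse:
    """Sampled fermentation concentrations plus biomass.

    Thin wrapper over a DataFrame with columns :data:`TIMECOURSE_COLUMNS`
    (time strictly increasing, concentrations non-negative).  Species
    columns may be absent; operations that need them raise
    :class:`RateEstimationError` naming the missing species.
    """

    def __init__(self, data: pd.DataFrame):
        if "time_h" not in data.columns:
            raise RateEstimationError("time course needs a 'time_h' column")
        if len(data) < 2:
            raise RateEstimationError("time course needs at least 2 samples")
        t = np.asarray(data["time_h"], dtype=float)
        if not np.all(np.diff(t) > 0):
            raise RateEstimationError("sample times must be strictly increasing")
        for col in data.columns:
            if col == "time_h":
                continue
            if np.nanmin(np.asarray(data[col], dtype=float)) < 0:
                raise RateEstimationError(f"negative values in column {col!r}")
        self.data = data.reset_index(drop=True)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        time_h: Sequence[float],
        *,
        glucose_gL: Sequence[float] | None = None,
        ethanol_gL: Sequence[float] | None = None,
        total_acid_gL: Sequence[float] | None = None,
        biomass_gDW_L: Sequence[float] | None = None,
    ) -> "TimeCourse":
        cols: dict[str, Sequence[float]] = {"time_h": time_h}
        for name, values in (
            ("glucose_gL", glucose_gL),
            ("ethanol_gL", ethanol_gL),
            ("total_acid_gL", total_acid_gL),
            ("biomass_gDW_L", biomass_gDW_L),
        ):
            if values is not None:
                cols[name] = values
        return cls(pd.DataFrame(cols))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TimeCourse":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    # -- access ------------------------------------------------------------

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.data["time_h"], dtype=float)

    def column(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise RateEstimationError(f"time course has no column {name!r}")
        return np.asarray(self.data[name], dtype=float)

    def interp(self, column: str, t: float) -> float:
        times = self.times
        if not (times[0] <= t <= times[-1]):
            raise RateEstimationError(
                f"time {t} h outside sampled range [{times[0]}, {times[-1]}] h"
            )
        return float(np.interp(t, times, self.column(column)))

    def window_slice(self, window: tuple[float, float]) -> pd.DataFrame:
        t1, t2 = window
        mask = (self.times >= t1) & (self.times <= t2)
        return self.data.loc[mask]


def _check_window(tc: TimeCourse, window: tuple[float, float]) -> tuple[float, float]:
    t1, t2 = float(window[0]), float(window[1])
    if not t2 > t1:
        raise RateEstimationError(f"window ({t1}, {t2}) has non-positive length")
    times = tc.times
    if t1 < times[0] or t2 > times[-1]:
        raise RateEstimationError(
            f"window ({t1}, {t2}) h outside sampled range "
            f"[{times[0]}, {times[-1]}] h"
        )
    return t1, t2


def _mean_biomass(tc: TimeCourse, t1: float, t2: float) -> float:
    """Trapezoidal time-average of biomass over [t1, t2]."""
    times = tc.times
    biomass = tc.column("biomass_gDW_L")
    inner = times[(times > t1) & (times < t2)]
    grid = np.concatenate(([t1], inner, [t2]))
    values = np.interp(grid, times, biomass)
    if np.any(values <= 0):
        raise RateEstimationError("biomass must be positive over the window")
    return float(np.trapezoid(values, grid) / (t2 - t1))


@dataclass(frozen=True)
class RateEstimate:
    """An estimated exchange rate (mmol gDW^-1 h^-1) and its provenance."""

    species: str
    value: float
    window: tuple[float, float]
    biomass_used: float  # gDW L^-1, time-averaged over the window
    method: str  # "two_point" or "regression"
    stderr: float | None = None  # regression only

    def delta_concentration(self) -> float:
        """Invert the rate back to the signed g L^-1 change over the window."""
        spec = SPECIES[self.species]
        t1, t2 = self.window
        return (
            spec.sign
            * self.value
            * spec.molar_mass
            * (t2 - t1)
            * self.biomass_used
            / 1000.0
        )


def net_formation_rate(
    timecourse: TimeCourse,
    species: str,
    window: tuple[float, float] = DEFAULT_WINDOW,
    method: str = "two_point",
) -> RateEstimate:
    """Estimate one species' specific exchange rate over a window.

    ``method="two_point"`` applies the net-change rule to the window
    endpoints (linearly interpolated if they fall between samples);
    ``method="regression"`` fits an OLS slope to all samples inside the
    window (needs >= 3) and reports its standard error.
    """
    if species not in SPECIES:
        raise RateEstimationError(
            f"unknown species {species!r}; expected one of {sorted(SPECIES)}"
        )
    spec = SPECIES[species]
    t1, t2 = _check_window(timecourse, window)
    if spec.column not in timecourse.data.columns:
        raise RateEstimationError(
            f"time course is missing species {species!r} (column {spec.column!r})"
        )
    if "biomass_gDW_L" not in timecourse.data.columns:
        raise RateEstimationError("time course is missing biomass (biomass_gDW_L)")
    x_mean = _mean_biomass(timecourse, t1, t2)

    if method == "two_point":
        dc = timecourse.interp(spec.column, t2) - timecourse.interp(spec.column, t1)
        slope = dc / (t2 - t1)  # g L^-1 h^-1
        stderr = None
    elif method == "regression":
        window_data = timecourse.window_slice((t1, t2))
        if len(window_data) < 3:
            raise RateEstimationError(
                "regression method needs >= 3 samples in the window"
            )
        fit = stats.linregress(
            np.asarray(window_data["time_h"], dtype=float),
            np.asarray(window_data[spec.column], dtype=float),
        )
        slope = float(fit.slope)
        stderr = float(fit.stderr) * 1000.0 / spec.molar_mass / x_mean
    else:
        raise RateEstimationError(
            f"unknown method {method!r}; use 'two_point' or 'regression'"
        )

    value = spec.sign * slope * 1000.0 / spec.molar_mass / x_mean
    return RateEstimate(
        species=species,
        value=value,
        window=(t1, t2),
        biomass_used=x_mean,
        method=method,
        stderr=stderr,
    )


def estimate_measured_rates(
    timecourse: TimeCourse,
    window: tuple[float, float] = DEFAULT_WINDOW,
    *,
    biomass_rate: float | None = None,
    method: str = "two_point",
) -> MeasuredRates:
    """Bundle glucose uptake, ethanol uptake and acetate formation into the
    solver's rate vector.

    ``biomass_rate`` (the biomass formation flux, on the model's scale)
    should normally be supplied.  When omitted, the net-change rule is
    applied to the biomass series itself — (X(t2)-X(t1)) / ((t2-t1) * X_mean),
    units h^-1 — which is a specific growth rate, not necessarily on the
    published biomass-flux scale; prefer the explicit value when comparing
    against published fluxes.
    """
    estimates = {
        name: net_formation_rate(timecourse, name, window, method)
        for name in ("glucose", "ethanol", "total_acid")
    }
    if biomass_rate is None:
        t1, t2 = _check_window(timecourse, window)
        if "biomass_gDW_L" not in timecourse.data.columns:
            raise RateEstimationError("time course is missing biomass (biomass_gDW_L)")
        dx = timecourse.interp("biomass_gDW_L", t2) - timecourse.interp(
            "biomass_gDW_L", t1
        )
        biomass_rate = dx / (t2 - t1) / _mean_biomass(timecourse, t1, t2)
    return MeasuredRates(
        glc_uptake=estimates["glucose"].value,
        etoh_uptake=estimates["ethanol"].value,
        acetate_formation=estimates["total_acid"].value,
        biomass_rate=float(biomass_rate),
    )


@dataclass(frozen=True)
class PseudoSteadyStateReport:
    """Whether biomass is near-stationary over the evaluated window."""

    window: tuple[float, float]
    relative_change: float
    tolerance: float

    @property
    def passed(self) -> bool:
        return abs(self.relative_change) <= self.tolerance


def check_pseudo_steady_state(
    timecourse: TimeCourse,
    window: tuple[float, float] = DEFAULT_WINDOW,
    biomass_tolerance: float = 0.10,
) -> PseudoSteadyStateReport:
    """Check the stationary-biomass premise of the rate rule.

    Passes when ``|X(t2) - X(t1)| / X(t1) <= biomass_tolerance``.
    """
    t1, t2 = _check_window(timecourse, window)
    if "biomass_gDW_L" not in timecourse.data.columns:
        raise RateEstimationError("time course is missing biomass (biomass_gDW_L)")
    x1 = timecourse.interp("biomass_gDW_L", t1)
    x2 = timecourse.interp("biomass_gDW_L", t2)
    if x1 <= 0:
        raise RateEstimationError("biomass at window start must be positive")
    return PseudoSteadyStateReport(
        window=(t1, t2),
        relative_change=(x2 - x1) / x1,
        tolerance=float(biomass_tolerance),
    )
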