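"""Synthetic fermentation time courses with known ground-truth fluxes.

Inside the pseudo-steady analysis window the rate rule assumes zero-order
(linear) concentration dynamics, so that is exactly what is simulated:
each species concentration moves at ``rate * M * X / 1000`` g L^-1 h^-1
(sign per uptake/formation) around its initial value, biomass is constant or
drifts linearly, and each instrument adds independent Gaussian noise.
Default noise magnitudes are instrument-scale choices: 0.5 g L^-1 for the
titrated total acid, 0.2 g L^-1 for GC ethanol, 0.05 g L^-1 for HPLC
glucose, and noise-free biomass.  No batch growth kinetics (lag, inhibition,
substrate exhaustion) are modeled — the generator emulates only the window
the rate rule is valid in.

All randomness flows through an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .network import StoichiometricModel
from .rates import SPECIES, TimeCourse, estimate_measured_rates
from .solver import MeasuredRates, solve_model

__all__ = [
    "DEFAULT_NOISE_SD",
    "DEFAULT_INITIAL_CONCENTRATIONS",
    "SimulationConfig",
    "GroundTruth",
    "simulate_fermentation",
    "recovery_experiment",
]

#: Per-instrument additive noise SD, g L^-1.
DEFAULT_NOISE_SD = {
    "glucose": 0.05,   # HPLC
    "ethanol": 0.2,    # GC
    "total_acid": 0.5,  # NaOH titration
    "biomass": 0.0,
}

#: Plausible mid-fermentation starting concentrations, g L^-1.
DEFAULT_INITIAL_CONCENTRATIONS = {
    "glucose": 3.0,
    "ethanol": 20.0,
    "total_acid": 35.0,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth rates plus sampling and noise settings.

    ``times`` are the sampling instants (h, strictly increasing);
    ``biomass_level`` is the dry-weight biomass at the first sample and
    ``biomass_slope`` an optional linear drift (gDW L^-1 h^-1, default 0 —
    the stationary premise).
    """

    true_rates: MeasuredRates
    times: tuple[float, ...] = (48.0, 51.0, 54.0, 57.0, 60.0)
    biomass_level: float = 1.0
    biomass_slope: float = 0.0
    initial_concentrations: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INITIAL_CONCENTRATIONS)
    )
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_SD)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size < 2 or not np.all(np.diff(t) > 0):
            raise ValueError("times must hold >= 2 strictly increasing values")
        if self.biomass_level <= 0:
            raise ValueError("biomass_level must be positive")
        for name, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise_sd[{name!r}] must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator used: the rates, and optionally the implied full
    flux vector from the reference model."""

    rates: MeasuredRates
    fluxes: pd.Series | None = None
    warnings: tuple[str, ...] = ()


def _true_rate_for(config: SimulationConfig, species: str) -> float:
    return {
        "glucose": config.true_rates.glc_uptake,
        "ethanol": config.true_rates.etoh_uptake,
        "total_acid": config.true_rates.acetate_formation,
    }[species]


def simulate_fermentation(
    config: SimulationConfig,
    model: StoichiometricModel | None = None,
) -> tuple[TimeCourse, GroundTruth]:
    """Generate one noisy time course consistent with ``config.true_rates``.

    With linear biomass drift the concentration trajectory uses the exact
    integral of ``rate * M * X(t) / 1000``, so the noiseless course is
    exactly consistent with the generating rates under the trapezoidal
    biomass averaging of the estimator.  Concentrations are clipped at zero
    with a warning.  Passing ``model`` additionally solves the reference
    system at the true rates and attaches the implied 33-flux vector.
    """
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.times, dtype=float)
    tau = t - t[0]
    biomass = config.biomass_level + config.biomass_slope * tau
    if np.any(biomass <= 0):
        raise ValueError("biomass drift drives biomass non-positive in the window")
    # integral of X(t) dt from t[0]: level*tau + slope*tau^2/2
    biomass_integral = config.biomass_level * tau + 0.5 * config.biomass_slope * tau**2

    warnings: list[str] = []
    columns: dict[str, np.ndarray] = {"time_h": t}
    for species in ("glucose", "ethanol", "total_acid"):
        spec = SPECIES[species]
        rate = _true_rate_for(config, species)
        c0 = float(config.initial_concentrations.get(species, 0.0))
        clean = c0 + spec.sign * rate * spec.molar_mass * biomass_integral / 1000.0
        noisy = clean + rng.normal(
            0.0, float(config.noise_sd.get(species, 0.0)), size=t.shape
        )
        if np.any(noisy < 0):
            warnings.append(
                f"{species}: {int(np.sum(noisy < 0))} sample(s) clipped at 0 g/L"
            )
            noisy = np.clip(noisy, 0.0, None)
        columns[spec.column] = noisy

    biomass_noisy = biomass + rng.normal(
        0.0, float(config.noise_sd.get("biomass", 0.0)), size=t.shape
    )
    if np.any(biomass_noisy <= 0):
        warnings.append("biomass: non-positive noisy sample(s) clipped to 1e-6")
        biomass_noisy = np.clip(biomass_noisy, 1e-6, None)
    columns["biomass_gDW_L"] = biomass_noisy

    timecourse = TimeCourse(pd.DataFrame(columns))

    fluxes = None
    if model is not None:
        fluxes = solve_model(model, config.true_rates).fluxes
    truth = GroundTruth(
        rates=config.true_rates, fluxes=fluxes, warnings=tuple(warnings)
    )
    return timecourse, truth


def recovery_experiment(
    config: SimulationConfig,
    n_replicates: int,
    window: tuple[float, float] | None = None,
    method: str = "two_point",
) -> pd.DataFrame:
    """Monte-Carlo check of the rate estimator against the generator.

    Runs ``n_replicates`` independent simulations (child seeds spawned from
    ``config.seed``), estimates the three concentration-derived rates from
    each, and reports per-rate bias, SD and RMSE versus the ground truth.
    The biomass rate is passed through from the truth, so only glucose,
    ethanol and acetate are scored.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if window is None:
        window = (config.times[0], config.times[-1])
    child_seeds = np.random.SeedSequence(config.seed).generate_state(n_replicates)
    truth = config.true_rates.as_dict()
    keys = ("glc_uptake", "etoh_uptake", "acetate_formation")
    errors = {k: np.empty(n_replicates) for k in keys}
    for i, seed in enumerate(child_seeds):
        rep = replace(config, seed=int(seed) % (2**31))
        tc, _ = simulate_fermentation(rep)
        est = estimate_measured_rates(
            tc, window, biomass_rate=config.true_rates.biomass_rate, method=method
        )
        for k in keys:
            errors[k][i] = getattr(est, k) - truth[k]
    rows = []
    for k in keys:
        e = errors[k]
        rows.append(
            {
                "rate": k,
                "truth": truth[k],
                "bias": float(e.mean()),
                "sd": float(e.std(ddof=1)) if n_replicates > 1 else 0.0,
                "rmse": float(np.sqrt(np.mean(e**2))),
                "n_replicates": n_replicates,
            }
        )
    return pd.DataFrame(rows).set_index("rate")
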