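"""Assembly and solution of the square flux balance system A b = r.

The pseudo-steady-state balances make the system homogeneous except for the
four exchange rows, which carry the measured rates.  Because the reference
model is square and full rank, the flux vector is determined exactly; the
solver is a dense LU solve (``scipy.linalg.solve``) rather than the explicit
inverse-then-multiply of a spreadsheet, which is mathematically identical
and numerically better behaved.  Every solution is re-substituted into the
system and carries per-equation residuals.

No non-negativity constraint is imposed: the method is an unconstrained
linear solve, and a negative solved flux (a flux running against its written
direction) is reported as a warning, not an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import ModelError, SingularSystemError
from .network import (
    RATE_KEYS,
    StoichiometricModel,
    build_stoichiometric_matrix,
    flux_roles,
    validate_network,
)

__all__ = [
    "MeasuredRates",
    "LinearSystem",
    "FluxSolution",
    "assemble_system",
    "solve_fluxes",
    "solve_model",
    "compute_residuals",
    "sensitivity_scan",
    "solution_frame",
    "CONDITION_WARNING_THRESHOLD",
    "RESIDUAL_WARNING_THRESHOLD",
]

#: Above this condition number the solution carries an ill-conditioning warning.
CONDITION_WARNING_THRESHOLD = 1e8
#: A re-substitution residual above this triggers a warning on the solution.
RESIDUAL_WARNING_THRESHOLD = 1e-6


@dataclass(frozen=True)
class MeasuredRates:
    """The four measured exchange rates, all in mmol gDW^-1 h^-1.

    ``biomass_rate`` is taken on the same scale the flux model uses for the
    biomass formation flux.  Negative values are tolerated (they flip the
    nominal direction) but flagged by :meth:`warnings`.
    """

    glc_uptake: float
    etoh_uptake: float
    acetate_formation: float
    biomass_rate: float

    def __post_init__(self) -> None:
        for key in RATE_KEYS:
            v = getattr(self, key)
            if not math.isfinite(v):
                raise ValueError(f"rate {key!r} must be finite, got {v!r}")

    def as_dict(self) -> dict[str, float]:
        return {key: float(getattr(self, key)) for key in RATE_KEYS}

    def scaled(self, k: float) -> "MeasuredRates":
        return MeasuredRates(**{key: k * v for key, v in self.as_dict().items()})

    def warnings(self) -> list[str]:
        return [
            f"measured rate {key} is negative ({getattr(self, key):g})"
            for key in RATE_KEYS
            if getattr(self, key) < 0
        ]


@dataclass(frozen=True)
class LinearSystem:
    """A labeled square system ``matrix @ b = rhs``."""

    matrix: np.ndarray
    rhs: np.ndarray
    row_labels: tuple[str, ...]
    column_labels: tuple[str, ...]
    coefficient_set: str = ""
    source_warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class FluxSolution:
    """A solved flux vector with residual diagnostics.

    ``fluxes`` and ``residuals`` are pandas Series indexed by flux symbol and
    ``row:label`` respectively.  ``condition_number`` refers to the system
    matrix; ``coefficient_set`` names the biomass-drain coefficients used.
    """

    fluxes: pd.Series
    residuals: pd.Series
    max_abs_residual: float
    condition_number: float
    coefficient_set: str
    warnings: tuple[str, ...] = ()

    def __getitem__(self, flux: str) -> float:
        return float(self.fluxes[flux])

    def rounded(self, ndigits: int = 4) -> pd.Series:
        """Fluxes rounded half-to-even to ``ndigits`` decimals (report scale)."""
        return self.fluxes.map(lambda v: round(float(v), ndigits))


def assemble_system(model: StoichiometricModel, rates: MeasuredRates) -> LinearSystem:
    """Place the measured rates on the exchange rows of the model matrix.

    Balance, ratio and drain rows get rhs 0; the model must be square and
    full rank (checked before assembly).
    """
    report = validate_network(model)
    if not report.square:
        raise ModelError(
            f"model is not square: {report.n_equations} equations for "
            f"{report.n_fluxes} fluxes"
        )
    if not report.full_rank:
        raise ModelError(
            f"model is rank deficient (rank {report.rank} < {report.n_fluxes})"
        )
    labeled = build_stoichiometric_matrix(model)
    rate_values = rates.as_dict()
    rhs = np.zeros(len(labeled.row_labels))
    for i, eq in enumerate(model.equations):
        if eq.rate_key is not None:
            if eq.rate_key not in rate_values:
                raise ModelError(
                    f"exchange row {eq.row} wants unknown rate {eq.rate_key!r}"
                )
            rhs[i] = rate_values[eq.rate_key]
    return LinearSystem(
        matrix=labeled.matrix,
        rhs=rhs,
        row_labels=labeled.row_labels,
        column_labels=labeled.column_labels,
        coefficient_set=model.coefficient_set,
        source_warnings=tuple(rates.warnings()),
    )


def _dependent_rows(matrix: np.ndarray, row_labels: tuple[str, ...]) -> list[str]:
    """Rows implicated in the (near-)singularity, via the smallest left
    singular vectors."""
    u, s, _ = np.linalg.svd(matrix)
    tol = s.max() * max(matrix.shape) * np.finfo(float).eps if s.size else 0.0
    involved: set[str] = set()
    for k in np.flatnonzero(s <= tol):
        weights = np.abs(u[:, k])
        for i in np.flatnonzero(weights > 0.1 * weights.max()):
            involved.add(row_labels[i])
    return sorted(involved)


def solve_fluxes(system: LinearSystem) -> FluxSolution:
    """Solve the assembled system exactly and re-substitute.

    Raises :class:`SingularSystemError` (naming the dependent rows) if the
    matrix is singular to machine precision.
    """
    A, r = system.matrix, system.rhs
    if A.shape[0] != A.shape[1]:
        raise ModelError(f"system is not square: shape {A.shape}")
    cond = float(np.linalg.cond(A))
    rank = int(np.linalg.matrix_rank(A))
    if rank < A.shape[0]:
        rows = _dependent_rows(A, system.row_labels)
        raise SingularSystemError(
            f"singular system (rank {rank} of {A.shape[0]}); dependent rows: "
            + ", ".join(rows)
        )
    b = scipy.linalg.solve(A, r)
    residual = A @ b - r
    max_abs = float(np.max(np.abs(residual)))

    warn = list(system.source_warnings)
    if cond > CONDITION_WARNING_THRESHOLD:
        warn.append(f"ill-conditioned system: condition number {cond:.3g}")
    if max_abs > RESIDUAL_WARNING_THRESHOLD:
        warn.append(f"re-substitution residual {max_abs:.3g} exceeds "
                    f"{RESIDUAL_WARNING_THRESHOLD:g}")
    negative = [
        system.column_labels[j] for j in range(len(b)) if b[j] < -1e-12
    ]
    if negative:
        warn.append(
            "negative fluxes (running against the written direction): "
            + ", ".join(negative)
        )
    return FluxSolution(
        fluxes=pd.Series(b, index=list(system.column_labels)),
        residuals=pd.Series(residual, index=list(system.row_labels)),
        max_abs_residual=max_abs,
        condition_number=cond,
        coefficient_set=system.coefficient_set,
        warnings=tuple(warn),
    )


def solve_model(model: StoichiometricModel, rates: MeasuredRates) -> FluxSolution:
    """Convenience: assemble and solve in one step."""
    return solve_fluxes(assemble_system(model, rates))


def compute_residuals(
    model: StoichiometricModel,
    flux_vector,
    rates: MeasuredRates | None = None,
) -> tuple[pd.Series, float]:
    """Evaluate every model equation at a given flux vector.

    ``flux_vector`` may be a mapping/Series keyed by flux symbol or a plain
    sequence in p1..pN order.  With ``rates`` omitted the exchange rows are
    evaluated against rhs 0 of their homogeneous part — i.e. they report the
    exchange totals themselves — so passing the rates is required for a
    meaningful full-system residual.  Returns (per-row residual Series,
    max abs residual).
    """
    labeled = build_stoichiometric_matrix(model)
    n = len(labeled.column_labels)
    if isinstance(flux_vector, pd.Series):
        flux_vector = flux_vector.to_dict()
    if isinstance(flux_vector, dict):
        missing = [f for f in labeled.column_labels if f not in flux_vector]
        if missing:
            raise ModelError(f"flux vector is missing entries: {missing}")
        b = np.array([float(flux_vector[f]) for f in labeled.column_labels])
    else:
        b = np.asarray(flux_vector, dtype=float)
        if b.shape != (n,):
            raise ModelError(
                f"flux vector has length {b.size}, expected {n}"
            )
    rhs = np.zeros(n)
    if rates is not None:
        rate_values = rates.as_dict()
        for i, eq in enumerate(model.equations):
            if eq.rate_key is not None:
                rhs[i] = rate_values[eq.rate_key]
    residual = labeled.matrix @ b - rhs
    series = pd.Series(residual, index=list(labeled.row_labels))
    return series, float(np.max(np.abs(residual)))


def sensitivity_scan(
    model: StoichiometricModel,
    rates: MeasuredRates,
    relative_perturbation: float = 0.05,
) -> pd.DataFrame:
    """Finite-difference sensitivity of every flux to each exchange rate.

    Each rate is perturbed by ±``relative_perturbation`` (relative) in turn
    and the system re-solved.  Because the system is linear in the rhs the
    plus/minus deltas are symmetric; both are reported.  Columns are
    ``{rate}+`` and ``{rate}-`` holding flux deltas versus the base solve.
    """
    if not relative_perturbation >= 0:
        raise ValueError("relative_perturbation must be >= 0")
    base = solve_model(model, rates)
    columns: dict[str, pd.Series] = {}
    for key in RATE_KEYS:
        for sign, suffix in ((1.0, "+"), (-1.0, "-")):
            perturbed = dict(rates.as_dict())
            perturbed[key] = perturbed[key] * (1.0 + sign * relative_perturbation)
            sol = solve_model(model, MeasuredRates(**perturbed))
            columns[f"{key}{suffix}"] = sol.fluxes - base.fluxes
    return pd.DataFrame(columns)


def solution_frame(model: StoichiometricModel, solution: FluxSolution) -> pd.DataFrame:
    """Report table: flux id, role, full-precision value, 4-dp value, residual.

    The residual column carries the residual of the equation row with the
    same published number as the flux where one exists (rows 1..N), aligning
    the table with the published numbering.
    """
    roles = flux_roles(model)
    residual_by_row = {
        int(label.split(":", 1)[0]): v for label, v in solution.residuals.items()
    }
    rows = []
    for i, flux in enumerate(model.flux_names, start=1):
        rows.append(
            {
                "flux_id": flux,
                "role": roles[flux],
                "value": float(solution.fluxes[flux]),
                "value_4dp": round(float(solution.fluxes[flux]), 4),
                "equation_residual": residual_by_row.get(i, float("nan")),
            }
        )
    return pd.DataFrame(rows)
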