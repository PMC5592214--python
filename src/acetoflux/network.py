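"""Stoichiometric model of the *A. pasteurianus* JST-S central carbon network.

The network couples glycolysis (EMP), the pentose phosphate pathway, pyruvate
metabolism, the TCA cycle and the periplasmic ethanol oxidation chain
(PQQ-ADH -> ALDH).  It is expressed as a *determined* system: 33 flux
variables ``p1``..``p33`` constrained by exactly 33 linear equations —

* 20 pseudo-steady-state rows (internal pool balances plus fixed branch
  ratios such as ``p8 = 6 p9``),
* 9 biomass precursor drains ``p_k = c_pool * p33`` with dimensionless
  coefficients ``c_pool``,
* 4 exchange rows binding ``p1``, ``p15``, ``p14 + p16`` and ``p33`` to the
  measured glucose uptake, ethanol uptake, total acetate formation and
  biomass formation rates.

Two biomass-drain coefficient sets ship with the reference model.
``"as_printed"`` carries the published coefficients verbatim; the published
pyruvate (0.03604) and oxaloacetate (0.01959) values, however, are
inconsistent with the published solved flux vectors (the implied drains would
be ~4x and ~10x the reported ones).  ``"reconciled"`` replaces those two with
the values implied by the published fluxes themselves (drain / biomass flux:
0.008571 and 0.001904) and reproduces the published flux table for both
strains; it is the default for the case study.  The reference topology also
resolves two indexing slips in the published equation listing: the PEP
balance uses the PEP drain ``p28`` (not ``p29``, which is the pyruvate
drain), and the drain fluxes ``p25``/``p26`` belong to the Ru5P/F6P pools
respectively — the assignment under which the balance rows close on the
published vectors.

All fluxes are in mmol per gram cell dry weight per hour and are written
forward-positive.  Cofactors (NAD(P)H, ATP, FAD, CoA, CO2, ...) appear in the
reaction annotation strings only and are never balanced.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping

import numpy as np

from .errors import ModelError, ModelParseError, ModelStructureError

__all__ = [
    "Metabolite",
    "Reaction",
    "BiomassDrain",
    "CoefficientSet",
    "Equation",
    "StoichiometricModel",
    "LabeledMatrix",
    "ValidationReport",
    "RATE_KEYS",
    "build_reference_network",
    "build_stoichiometric_matrix",
    "validate_network",
]

#: Names of the four measured exchange rates, in published row order 30-33.
RATE_KEYS = ("glc_uptake", "etoh_uptake", "acetate_formation", "biomass_rate")


@dataclass(frozen=True)
class Metabolite:
    """A metabolite pool; ``balanced`` pools get a pseudo-steady-state row."""

    id: str
    name: str = ""
    balanced: bool = False


@dataclass(frozen=True)
class Reaction:
    """An enzymatic reaction of the network catalog.

    ``fluxes`` annotates which flux variables the reaction carries.  The
    mapping is not one-to-one: the transketolase/transaldolase lump carries
    two flux variables (p4 to F6P, p5 to G3P), while the lumped
    pyruvate-to-acetate route (p11 = p14) and the OAA-to-pyruvate flux p13
    have no single catalog entry.  The equation set, not this catalog, is the
    authority for the algebra.
    """

    number: int
    enzyme: str
    equation: str = ""
    fluxes: tuple[str, ...] = ()
    kind: str = "enzymatic"


@dataclass(frozen=True)
class BiomassDrain:
    """A precursor drain ``flux = coefficient * p33`` (coefficient per set)."""

    row: int
    flux: str
    pool: str

    @property
    def flux_index(self) -> int:
        return int(self.flux[1:])


@dataclass(frozen=True)
class CoefficientSet:
    """Named table of biomass-drain coefficients, keyed by precursor pool."""

    name: str
    values: Mapping[str, float]

    def __getitem__(self, pool: str) -> float:
        return self.values[pool]


@dataclass(frozen=True)
class Equation:
    """One linear constraint row: ``sum(terms[p] * p) = rhs``.

    ``rate_key`` is ``None`` for homogeneous rows (rhs 0) and one of
    :data:`RATE_KEYS` for exchange rows, whose rhs is the measured rate.
    """

    row: int
    label: str
    kind: str  # balance | ratio | drain | exchange
    terms: Mapping[str, float]
    rate_key: str | None = None


@dataclass(frozen=True)
class LabeledMatrix:
    """A stoichiometric system matrix with row and column labels."""

    matrix: np.ndarray
    row_labels: tuple[str, ...]
    column_labels: tuple[str, ...]

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


@dataclass(frozen=True)
class ValidationReport:
    """Structural/numerical diagnosis of a model; ``ok`` summarises it."""

    n_equations: int
    n_fluxes: int
    square: bool
    rank: int
    full_rank: bool
    condition_number: float
    orphan_fluxes: tuple[str, ...]
    unbalanced_pools: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return (
            self.square
            and self.full_rank
            and not self.orphan_fluxes
            and not self.unbalanced_pools
        )


@dataclass(frozen=True)
class StoichiometricModel:
    """The full flux model: metabolites, equations, drains, exchanges.

    The active :attr:`coefficient_set` selects the biomass-drain coefficients
    used when the drain equation rows are materialised; all shipped sets stay
    available on the instance so reports can state which one was used.
    """

    name: str
    metabolites: tuple[Metabolite, ...]
    reactions: tuple[Reaction, ...]
    drains: tuple[BiomassDrain, ...]
    balance_equations: tuple[Equation, ...]
    exchange_equations: tuple[Equation, ...]
    coefficient_sets: Mapping[str, CoefficientSet]
    coefficient_set: str
    n_fluxes: int
    description: str = ""

    # -- derived views ----------------------------------------------------

    @property
    def flux_names(self) -> tuple[str, ...]:
        return tuple(f"p{i}" for i in range(1, self.n_fluxes + 1))

    @property
    def biomass_flux(self) -> str:
        return f"p{self.n_fluxes}"

    @property
    def coefficients(self) -> CoefficientSet:
        return self.coefficient_sets[self.coefficient_set]

    @property
    def drain_equations(self) -> tuple[Equation, ...]:
        coeffs = self.coefficients
        return tuple(
            Equation(
                row=d.row,
                label=f"Biomass {d.pool}",
                kind="drain",
                terms={d.flux: 1.0, self.biomass_flux: -float(coeffs[d.pool])},
            )
            for d in self.drains
        )

    @property
    def equations(self) -> tuple[Equation, ...]:
        eqs = self.balance_equations + self.drain_equations + self.exchange_equations
        return tuple(sorted(eqs, key=lambda e: e.row))

    def with_coefficient_set(self, name: str) -> "StoichiometricModel":
        if name not in self.coefficient_sets:
            raise ModelError(
                f"unknown coefficient set {name!r}; "
                f"available: {sorted(self.coefficient_sets)}"
            )
        return replace(self, coefficient_set=name)

    def drain_for_pool(self, pool: str) -> BiomassDrain:
        for d in self.drains:
            if d.pool == pool:
                return d
        raise ModelStructureError(f"no biomass drain for pool {pool!r}")


# ---------------------------------------------------------------------------
# Reference model loading
# ---------------------------------------------------------------------------

_REFERENCE_CACHE: dict[str, StoichiometricModel] = {}


def _parse_terms(raw: Mapping[str, str], row: int) -> dict[str, float]:
    terms: dict[str, float] = {}
    for symbol, coeff in raw.items():
        try:
            value = float(coeff)
        except (TypeError, ValueError) as exc:
            raise ModelParseError(
                f"equation row {row}: coefficient for {symbol!r} is not a "
                f"number: {coeff!r}"
            ) from exc
        if not math.isfinite(value):
            raise ModelParseError(
                f"equation row {row}: non-finite coefficient for {symbol!r}"
            )
        terms[symbol] = value
    return terms


def model_from_dict(payload: Mapping) -> StoichiometricModel:
    """Construct a :class:`StoichiometricModel` from its dict serialization."""
    try:
        n_fluxes = int(payload["n_fluxes"])
        metabolites = tuple(
            Metabolite(m["id"], m.get("name", ""), bool(m.get("balanced", False)))
            for m in payload["metabolites"]
        )
        reactions = tuple(
            Reaction(
                int(r["number"]),
                r["enzyme"],
                r.get("equation", ""),
                tuple(r.get("fluxes", ())),
            )
            for r in payload.get("reactions", ())
        )
        drains = tuple(
            BiomassDrain(int(d["row"]), d["flux"], d["pool"])
            for d in payload["drains"]
        )
        balances = tuple(
            Equation(
                int(e["row"]),
                e.get("label", f"row {e['row']}"),
                e.get("kind", "balance"),
                _parse_terms(e["terms"], int(e["row"])),
            )
            for e in payload["balance_equations"]
        )
        exchanges = tuple(
            Equation(
                int(e["row"]),
                e.get("label", e["rate"]),
                "exchange",
                _parse_terms(e["terms"], int(e["row"])),
                rate_key=e["rate"],
            )
            for e in payload["exchanges"]
        )
        coefficient_sets = {
            name: CoefficientSet(
                name, {pool: float(v) for pool, v in values.items()}
            )
            for name, values in payload["coefficient_sets"].items()
        }
    except KeyError as exc:
        raise ModelStructureError(f"model definition missing field {exc}") from exc

    model = StoichiometricModel(
        name=payload.get("name", "model"),
        metabolites=metabolites,
        reactions=reactions,
        drains=drains,
        balance_equations=balances,
        exchange_equations=exchanges,
        coefficient_sets=coefficient_sets,
        coefficient_set=payload.get("active_coefficient_set")
        or next(iter(coefficient_sets)),
        n_fluxes=n_fluxes,
        description=payload.get("description", ""),
    )
    _check_structure(model)
    return model


def _check_structure(model: StoichiometricModel) -> None:
    """Raise :class:`ModelStructureError` on structural inconsistencies."""
    flux_names = set(model.flux_names)
    met_ids = [m.id for m in model.metabolites]
    if len(set(met_ids)) != len(met_ids):
        dupes = sorted({m for m in met_ids if met_ids.count(m) > 1})
        raise ModelStructureError(f"duplicate metabolite ids: {dupes}")

    pools = {m.id for m in model.metabolites}
    for d in model.drains:
        if d.pool not in pools:
            raise ModelStructureError(f"drain {d.flux} names unknown pool {d.pool!r}")
        for cs in model.coefficient_sets.values():
            if d.pool not in cs.values:
                raise ModelStructureError(
                    f"coefficient set {cs.name!r} has no value for pool {d.pool!r}"
                )
            if not float(cs.values[d.pool]) > 0:
                raise ModelStructureError(
                    f"coefficient set {cs.name!r}: non-positive coefficient "
                    f"for pool {d.pool!r}"
                )

    rows = [e.row for e in model.equations]
    if len(set(rows)) != len(rows):
        raise ModelStructureError("duplicate equation row numbers")

    for eq in model.equations:
        for symbol in eq.terms:
            if symbol not in flux_names:
                raise ModelStructureError(
                    f"equation row {eq.row} ({eq.label}) references unknown "
                    f"flux {symbol!r}"
                )

    # The biomass flux must be present somewhere; a model without it cannot
    # materialise its drain equations.
    used = {s for eq in model.equations for s in eq.terms}
    if model.biomass_flux not in used:
        raise ModelStructureError("biomass flux missing from the equation set")


def build_reference_network(
    coefficient_set_name: str = "reconciled",
) -> StoichiometricModel:
    """Return the packaged JST-S reference model.

    Parameters
    ----------
    coefficient_set_name:
        ``"reconciled"`` (default; reproduces the published flux table) or
        ``"as_printed"`` (published biomass-drain coefficients verbatim).
    """
    if coefficient_set_name not in _REFERENCE_CACHE:
        payload = json.loads(
            resources.files("acetoflux.data")
            .joinpath("jst_s_model.json")
            .read_text("utf-8")
        )
        base = model_from_dict(payload)
        if coefficient_set_name not in base.coefficient_sets:
            raise ModelError(
                f"unknown coefficient set {coefficient_set_name!r}; "
                f"available: {sorted(base.coefficient_sets)}"
            )
        _REFERENCE_CACHE[coefficient_set_name] = base.with_coefficient_set(
            coefficient_set_name
        )
    return _REFERENCE_CACHE[coefficient_set_name]


# ---------------------------------------------------------------------------
# Matrix assembly and validation
# ---------------------------------------------------------------------------


def build_stoichiometric_matrix(model: StoichiometricModel) -> LabeledMatrix:
    """Assemble the total system matrix A, rows in published equation order.

    Entry ``A[i, j]`` is the signed coefficient of flux ``p(j+1)`` in
    equation row ``i+1``; branch-ratio factors (0.5, 6, 4, ...) enter exactly
    as written.
    """
    cols = model.flux_names
    col_index = {name: j for j, name in enumerate(cols)}
    equations = model.equations
    A = np.zeros((len(equations), len(cols)))
    row_labels = []
    for i, eq in enumerate(equations):
        for symbol, coeff in eq.terms.items():
            if symbol not in col_index:
                raise ModelStructureError(
                    f"equation row {eq.row} ({eq.label}) references unknown "
                    f"flux {symbol!r}"
                )
            A[i, col_index[symbol]] = coeff
        row_labels.append(f"{eq.row}:{eq.label}")
    return LabeledMatrix(A, tuple(row_labels), tuple(cols))


def validate_network(model: StoichiometricModel) -> ValidationReport:
    """Report determinacy diagnostics: squareness, rank, conditioning.

    Also flags *orphan fluxes* (zero columns — a flux no equation touches)
    and *unbalanced pools* (a balanced metabolite whose balance row does not
    have both a producing and a consuming term).
    """
    labeled = build_stoichiometric_matrix(model)
    A = labeled.matrix
    n_eq, n_flux = A.shape
    square = n_eq == n_flux
    rank = int(np.linalg.matrix_rank(A))
    cond = float(np.linalg.cond(A)) if square else float("inf")

    orphans = tuple(
        labeled.column_labels[j] for j in range(n_flux) if not np.any(A[:, j])
    )

    balance_by_label = {e.label: e for e in model.balance_equations if e.kind == "balance"}
    unbalanced = []
    for met in model.metabolites:
        if not met.balanced:
            continue
        eq = balance_by_label.get(met.id)
        if eq is None:
            unbalanced.append(met.id)
            continue
        signs = {math.copysign(1, c) for c in eq.terms.values() if c != 0}
        if signs != {1.0, -1.0}:
            unbalanced.append(met.id)

    return ValidationReport(
        n_equations=n_eq,
        n_fluxes=n_flux,
        square=square,
        rank=rank,
        full_rank=rank == min(n_eq, n_flux) and square,
        condition_number=cond,
        orphan_fluxes=orphans,
        unbalanced_pools=tuple(unbalanced),
    )


def model_to_dict(model: StoichiometricModel) -> dict:
    """Serialize a model to the JSON-ready dict form (12-significant-digit
    decimal strings for all coefficients)."""

    def fmt(x: float) -> str:
        return f"{float(x):.12g}"

    return {
        "name": model.name,
        "description": model.description,
        "n_fluxes": model.n_fluxes,
        "active_coefficient_set": model.coefficient_set,
        "metabolites": [
            {"id": m.id, "name": m.name, "balanced": m.balanced}
            for m in model.metabolites
        ],
        "balance_equations": [
            {
                "row": e.row,
                "label": e.label,
                "kind": e.kind,
                "terms": {s: fmt(c) for s, c in e.terms.items()},
            }
            for e in model.balance_equations
        ],
        "drains": [
            {"row": d.row, "flux": d.flux, "pool": d.pool} for d in model.drains
        ],
        "coefficient_sets": {
            name: {pool: fmt(v) for pool, v in cs.values.items()}
            for name, cs in model.coefficient_sets.items()
        },
        "exchanges": [
            {
                "row": e.row,
                "rate": e.rate_key,
                "terms": {s: fmt(c) for s, c in e.terms.items()},
            }
            for e in model.exchange_equations
        ],
        "reactions": [
            {
                "number": r.number,
                "enzyme": r.enzyme,
                "equation": r.equation,
                "fluxes": list(r.fluxes),
            }
            for r in model.reactions
        ],
    }


def flux_roles(model: StoichiometricModel) -> dict[str, str]:
    """Human-readable role per flux symbol, for report tables."""
    roles = {name: "" for name in model.flux_names}
    for r in model.reactions:
        for f in r.fluxes:
            roles[f] = r.enzyme
    for d in model.drains:
        roles[d.flux] = f"biomass drain ({d.pool})"
    roles[model.biomass_flux] = "biomass formation"
    for name, role in list(roles.items()):
        if not role:
            roles[name] = "lumped/unassigned route"
    return roles
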