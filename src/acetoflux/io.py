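"""Model file round-tripping (JSON with decimal-string coefficients)."""

from __future__ import annotations

import json
from pathlib import Path

from .errors import ModelParseError
from .network import StoichiometricModel, model_from_dict, model_to_dict

__all__ = ["read_model", "write_model"]


def read_model(path: str | Path) -> StoichiometricModel:
    """Read a model file written by :func:`write_model`.

    Raises :class:`ModelParseError` on malformed JSON (with line number) or
    malformed coefficients, and :class:`ModelStructureError` on structural
    defects such as a missing biomass flux.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text("utf-8"))
    except json.JSONDecodeError as exc:
        raise ModelParseError(
            f"{path}: invalid JSON at line {exc.lineno}, column {exc.colno}: "
            f"{exc.msg}"
        ) from exc
    return model_from_dict(payload)


def write_model(model: StoichiometricModel, path: str | Path) -> None:
    """Write a model file; round-trips losslessly at 12 significant digits."""
    path = Path(path)
    path.write_text(json.dumps(model_to_dict(model), indent=1) + "\n", "utf-8")
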