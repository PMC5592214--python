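"""Exception hierarchy for acetoflux."""


class AcetofluxError(Exception):
    """Base class for all package-specific errors."""


class ModelError(AcetofluxError):
    """A stoichiometric model is invalid for the requested operation."""


class ModelStructureError(ModelError):
    """The model is structurally inconsistent (missing fluxes, bad references)."""


class ModelParseError(ModelError):
    """A model file could not be parsed; carries the offending location."""


class SingularSystemError(AcetofluxError):
    """The assembled flux system is singular and cannot be solved."""


class RateEstimationError(AcetofluxError):
    """A measured rate cannot be derived from the given time course."""
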