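"""Exception hierarchy shared across the package."""


class CytoEMDError(Exception):
    """Base class for all cytoemd errors."""


class DegenerateInputError(CytoEMDError):
    """Input is empty or too small for the requested operation."""


class ParameterError(CytoEMDError, ValueError):
    """A parameter is outside its valid range (e.g. logicle W < 0)."""


class SchemaError(CytoEMDError):
    """A binning schema is incompatible with the data it is applied to."""


class ChannelMismatchError(CytoEMDError):
    """A named channel is missing from an event matrix."""


class NormalizationError(CytoEMDError):
    """Signature weights do not form a probability distribution."""


class SolverError(CytoEMDError):
    """The transportation linear program failed to converge."""
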