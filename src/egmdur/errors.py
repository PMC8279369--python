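"""Exception hierarchy for egmdur."""


class EgmdurError(Exception):
    """Base class for all egmdur errors."""


class SchemaError(EgmdurError):
    """A required field or table is missing from an EAMX source."""


class FormatError(EgmdurError):
    """An EAMX source is internally inconsistent (e.g. trace length mismatch)."""


class ParameterError(EgmdurError, ValueError):
    """An algorithm parameter is outside its valid domain."""


class TraceLengthError(EgmdurError, ValueError):
    """A trace is too short for the requested operation."""


class DataError(EgmdurError, ValueError):
    """Input data cannot support the requested statistic."""


class ConsistencyError(EgmdurError):
    """Two inputs that must describe the same map disagree."""


class GridSearchError(EgmdurError):
    """The parameter search is undefined on the given cohort."""


class CapabilityError(EgmdurError):
    """The requested output needs data the map does not carry (e.g. a mesh)."""
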