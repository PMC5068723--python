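"""Exception hierarchy for entrainkit.

All errors raised by the package derive from :class:`EntrainkitError` so
callers can catch package failures with a single except clause (the study
pipeline relies on this to log-and-continue per animal).
"""


class EntrainkitError(Exception):
    """Base class for all entrainkit errors."""


class ParameterError(EntrainkitError, ValueError):
    """An argument is outside its documented domain."""


class ConfigurationError(EntrainkitError, ValueError):
    """A simulation or schedule configuration is inconsistent."""


class FormatError(EntrainkitError, ValueError):
    """An input file could not be parsed under the declared dialect."""


class RangeError(EntrainkitError, ValueError):
    """A timestamp or window falls outside the recording or schedule."""


class FitError(EntrainkitError, ValueError):
    """A model fit is ill-posed (insufficient points or phase coverage)."""


class DegenerateInputError(EntrainkitError, ValueError):
    """The input series carries no usable signal (e.g. constant)."""


class ProtocolError(EntrainkitError, ValueError):
    """The recording does not cover a named experimental segment."""
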