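"""Exception hierarchy.

Every error raised by cytolite derives from :class:`CytoliteError`, so callers
(notably the CLI) can catch one type and translate it to a nonzero exit code.
"""


class CytoliteError(Exception):
    """Base class for all cytolite errors."""


class FormatError(CytoliteError):
    """A file or keyword value violates the format it claims to follow."""


class IntegrityError(CytoliteError):
    """Internally inconsistent data (e.g. $TOT disagrees with the DATA size)."""


class UnsupportedFeatureError(CytoliteError):
    """A legal but unsupported feature of the FCS standard was encountered."""


class ChannelNotFoundError(CytoliteError, KeyError):
    """A channel short name ($PnN) does not exist in the sample."""


class StateError(CytoliteError):
    """Operation invalid for the object's current state (e.g. double scaling)."""


class SingularMatrixError(CytoliteError):
    """A spillover matrix is singular or numerically non-invertible."""


class DegenerateControlError(CytoliteError):
    """A single-stain control has no usable signal on its own channel."""


class GateDefinitionError(CytoliteError):
    """A gate's geometry is invalid (too few vertices, empty interval...)."""


class ParameterError(CytoliteError, ValueError):
    """An argument is outside its documented domain."""


class SessionVersionError(CytoliteError):
    """A session document declares a schema version this build cannot read."""
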