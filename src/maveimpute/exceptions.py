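"""Exception hierarchy.

``InputError`` subclasses signal problems with user-supplied files or
parameters (CLI exit code 2); everything else under ``MaveImputeError``
is an internal/pipeline failure (exit code 1).
"""


class MaveImputeError(Exception):
    """Base class for all maveimpute errors."""


class InputError(MaveImputeError):
    """User input (file, token, parameter) is invalid."""


class ParseError(InputError):
    """A variant token could not be parsed."""


class FormatError(InputError):
    """A delimited input file violates the documented dialect."""


class AnchorError(InputError):
    """Normalization anchors cannot be fit (no stop or no synonymous variants)."""


class ModelError(MaveImputeError):
    """Model training, cutoff selection or prediction failed."""


class AssemblyError(MaveImputeError):
    """The variant-effect map could not be assembled (missing cells)."""
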