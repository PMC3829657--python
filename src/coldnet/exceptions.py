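"""Exception hierarchy for coldnet.

Every error raised deliberately by the package derives from
:class:`ColdnetError`, so callers can catch pipeline failures without
intercepting programming errors.
"""


class ColdnetError(Exception):
    """Base class for all coldnet errors."""


class FormatError(ColdnetError):
    """A file violates its format contract (duplicate ids, bad header...)."""


class ParseError(FormatError):
    """A cell or token could not be interpreted; message names the location."""


class MetadataError(FormatError):
    """Sample metadata is missing or inconsistent with the expression table."""


class AlignmentError(FormatError):
    """Sequences that should form an alignment do not (unequal lengths...)."""


class InputError(ColdnetError):
    """A well-formed object violates an operation's precondition."""


class DesignError(InputError):
    """The experimental design cannot support the requested test."""


class ParameterError(ColdnetError):
    """An argument is outside its valid range or infeasible."""


class ConfigError(ParameterError):
    """A pipeline configuration failed validation."""


class NotIdentifiableError(ColdnetError):
    """A decomposition was requested in strict mode on a non-compliant pattern."""


class IrreducibleError(ColdnetError):
    """Greedy reduction emptied the connectivity pattern before compliance."""


class DegenerateTFError(ColdnetError):
    """A TF column is identically zero, so its scale cannot be normalized."""
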