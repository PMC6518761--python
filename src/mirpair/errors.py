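"""Exception hierarchy.

Every malformed-input condition raises a distinct, named error so callers
(and the CLI) can report which contract was violated rather than a bare
``ValueError`` from deep inside pandas.
"""


class MirpairError(Exception):
    """Base class for all package-specific errors."""


class DuplicateIdentifierError(MirpairError):
    """A feature, sample, or set name occurs more than once where unique ids are required."""


class NonNumericValueError(MirpairError):
    """A cell of an expression matrix could not be parsed as a number."""


class UnknownColumnError(MirpairError):
    """A delimited file is missing a required column or carries an undeclared one."""


class FlagValueError(MirpairError):
    """A 0/1 flag column contains a value outside {0, 1}."""


class GMTFormatError(MirpairError):
    """A GMT line has fewer than three tab-separated fields."""


class AmbiguousAliasError(MirpairError):
    """A miRNA name matches two or more distinct accessions in the alias table."""


class SampleMismatchError(MirpairError):
    """Two matrices that must share a sample set do not."""


class GroupingError(MirpairError):
    """Sample-group table violates the two-group / minimum-size contract."""


class DegenerateInputError(MirpairError):
    """Input too small or empty for the requested computation (e.g. empty universe)."""
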