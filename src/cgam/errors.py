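"""Exception hierarchy.

Data/format problems (bad files, missing labels, inconsistent series) raise
:class:`DataError` subclasses and map to exit code 1 in the CLI; caller mistakes
(bad parameter values, unknown options) raise :class:`UsageError` subclasses and
map to exit code 2.
"""


class CgamError(Exception):
    """Base class for all cgam errors."""


class DataError(CgamError):
    """A problem with the input data itself."""


class FormatError(DataError):
    """Malformed or internally inconsistent input file."""


class MissingLabelError(DataError):
    """A required marker label is absent from the input."""

    def __init__(self, label: str):
        self.label = label
        super().__init__(f"required marker label missing from input: {label!r}")


class IntegrityError(DataError):
    """Event or series sequencing violates a structural invariant."""


class InsufficientDataError(DataError):
    """Not enough rows/steps to carry out the computation."""


class UsageError(CgamError):
    """Invalid parameter or configuration supplied by the caller."""


class ParameterError(UsageError):
    """A numeric or categorical argument is out of its valid range."""
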