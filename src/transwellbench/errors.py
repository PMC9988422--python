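"""Exception hierarchy for transwellbench.

All package errors derive from :class:`TranswellError` so callers can catch
one base class; subclasses also derive from the closest builtin (ValueError /
IOError) where that matches common expectations.
"""


class TranswellError(Exception):
    """Base class for all transwellbench errors."""


class ValidationError(TranswellError, ValueError):
    """A domain object was constructed with invalid field values."""


class SchemaError(TranswellError, ValueError):
    """An input table does not conform to the required schema."""


class ParseError(TranswellError, ValueError):
    """A cell in an input table could not be parsed; carries the row number."""


class DuplicateRecordError(TranswellError, ValueError):
    """Two rows define the same (group, time) measurement."""


class InsufficientDataError(TranswellError, ValueError):
    """Too few points / replicates for the requested computation."""


class UnusableFitError(TranswellError, ValueError):
    """A slope fit is unusable (non-positive slope) where a usable one is required."""


class MembraneInconsistencyError(TranswellError, ValueError):
    """PS_total >= PS_mem: the cell layer cannot be leakier than the blank insert."""


class NegativeNetResistanceError(TranswellError, ValueError):
    """Coculture resistance below the blank-membrane resistance."""
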