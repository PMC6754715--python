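"""Exception hierarchy.

Every error raised by the library derives from :class:`HSMError` so callers
can catch the whole family; most also derive from the closest builtin
(`ValueError`) so sloppy callers still see something sensible.
"""


class HSMError(Exception):
    """Base class for all hsmodels errors."""


class InvalidArgumentError(HSMError, ValueError):
    """A scalar argument violates its precondition (non-finite, wrong sign...)."""


class IncompatibleGridsError(HSMError, ValueError):
    """Two objects that must share a grid do not."""


class DegenerateStateError(HSMError, ValueError):
    """A state vector carries (numerically) no probability mass."""


class OutOfRangeError(HSMError, ValueError):
    """A threshold lies outside the measurement interval [l, u]."""


class InvalidIntervalError(HSMError, ValueError):
    """An interval (a, b] with a >= b, or otherwise malformed."""


class EmptySupportError(HSMError, ValueError):
    """A requested support contains no grid cells after snapping."""


class InvalidOperatorError(HSMError, ValueError):
    """An operator does not satisfy the algebraic property its use requires."""


class ImpossibleOutcomeError(HSMError, ValueError):
    """Conditioning / collapsing on an outcome of (numerically) zero probability."""


class UnresolvedObservableError(HSMError, KeyError):
    """A context step references an observable label with no registered spec."""


class UnsupportedStructureError(HSMError, ValueError):
    """A product-space context outside the one-non-commuting-pair structure."""


class IncompletePartitionError(HSMError, ValueError):
    """A bin scheme does not partition the full measurement interval."""


class SchemaMismatchError(HSMError, ValueError):
    """Model tables and dataset records do not line up."""


class IncomparableFitsError(HSMError, ValueError):
    """Two fits being compared were not obtained on identical data."""


class UnidentifiableJointWarning(UserWarning):
    """Variable coverage across contexts cannot pin down the joint uniquely."""
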