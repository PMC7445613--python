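"""Exception taxonomy for accelresp.

All exceptions derive from :class:`AccelRespError` so callers can catch the
package's failures with a single handler; each also derives from
``ValueError`` so generic validation code behaves as expected.
"""


class AccelRespError(Exception):
    """Base class for all accelresp errors."""


class FormatError(AccelRespError, ValueError):
    """Input file or table does not have the expected structure."""


class DataError(AccelRespError, ValueError):
    """Data violates an invariant (ordering, minimum length, pairing)."""


class ParameterError(AccelRespError, ValueError):
    """A parameter is outside its valid domain."""


class DegeneracyError(AccelRespError, ValueError):
    """The computation is undefined for this input (rank-deficient mixture,
    all-zero signal, zero variance, all-tied differences)."""
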