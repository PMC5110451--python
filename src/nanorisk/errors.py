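"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError and
NetworkError -> 3, ZeroProbabilityError and other numerical failures -> 4.
"""


class NanoriskError(Exception):
    """Base class for all package errors."""


class NetworkError(NanoriskError):
    """Structural or parametric defect in a network specification."""


class CycleError(NetworkError):
    """The edge set contains a directed cycle."""


class CPTError(NetworkError):
    """A conditional probability table violates its invariants."""


class EvidenceError(NanoriskError):
    """Evidence names an unknown variable or an invalid state label."""


class ZeroProbabilityError(NanoriskError):
    """The entered evidence has probability zero under the network.

    Raised explicitly (never silently propagated as NaN) so callers can
    distinguish impossible evidence from a numerical failure.
    """


class DataError(NanoriskError):
    """A case table or other data input is malformed."""


class ConfigError(NanoriskError):
    """A run configuration or file is invalid."""
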