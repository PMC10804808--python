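"""Exception hierarchy.

``DataError`` marks problems with user-supplied data (malformed files,
violated invariants); the CLI maps it to exit code 1. Usage errors are
handled by click and exit with code 2.
"""


class CoexkitError(Exception):
    """Base class for all coexkit errors."""


class DataError(CoexkitError):
    """Invalid or inconsistent input data."""
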