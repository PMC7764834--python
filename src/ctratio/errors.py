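"""Exception hierarchy.

Validation errors (bad input data) and configuration errors (bad panel /
run configuration) are distinguished so the CLI can map them to exit code 2,
while I/O problems propagate as OSError (exit code 3).
"""


class CtRatioError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CtRatioError, ValueError):
    """Input data violates a contract (missing marker, out-of-range Ct, ...)."""


class ConfigError(CtRatioError, ValueError):
    """A panel, comparison or run configuration is inconsistent."""
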