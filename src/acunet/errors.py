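"""Exception hierarchy shared across the package."""


class AcunetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AcunetError, ValueError):
    """Invalid user input, malformed data, or violated invariants."""


class RefusalError(AcunetError, ValueError):
    """A brute-force oracle was asked for a problem size it will not attempt."""
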