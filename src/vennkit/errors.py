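"""Exception hierarchy shared across the toolkit."""


class VennKitError(Exception):
    """Base class for all vennkit errors."""


class FormatError(VennKitError):
    """Malformed input data (bad column count, empty token, bad count...).

    ``line`` is the 1-based line number in the offending input when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CapacityError(VennKitError):
    """A request outside a diagram type's supported set count."""


class SemanticsError(VennKitError):
    """An inclusive count table that no disjoint-region assignment satisfies."""

    def __init__(self, message: str, signature: str | None = None):
        self.signature = signature
        super().__init__(message)


class ResolutionError(VennKitError):
    """Grid resolution too coarse to locate a diagram region."""
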