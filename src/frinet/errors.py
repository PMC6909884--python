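"""Exception types shared across the package."""


class FrinetError(Exception):
    """Base class for package-specific errors."""


class ParseError(FrinetError, ValueError):
    """Malformed Newick / cluster-file input.

    Carries the 1-based ``line`` and ``column`` where scanning stopped.
    """

    def __init__(self, message, line=None, column=None):
        if line is not None:
            message = f"{message} (line {line}, column {column})"
        super().__init__(message)
        self.line = line
        self.column = column


class ResourceError(FrinetError, RuntimeError):
    """A configured search or enumeration cap was exceeded."""
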