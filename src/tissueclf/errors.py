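"""Exception types shared across the pipeline.

``ValidationError`` marks bad user input or violated invariants (CLI exit
code 2); plain ``OSError`` covers I/O failures (CLI exit code 3).
"""


class ValidationError(ValueError):
    """Invalid input data, parameters, or a violated domain invariant."""


class GCTParseError(ValidationError):
    """Malformed GCT file; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
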