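"""Exception types shared across the package."""


class InputError(ValueError):
    """Invalid user input: bad values, missing ids, degenerate tables."""


class ParseError(InputError):
    """A malformed line in an evidence or table file."""

    def __init__(self, path, line_number: int, message: str):
        self.path = str(path)
        self.line_number = line_number
        super().__init__(f"{self.path}:{line_number}: {message}")


class SchemaError(InputError):
    """A feature table or model archive with an incompatible schema."""
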