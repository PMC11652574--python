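"""Exception types shared across the package."""


class DyadGazeError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(DyadGazeError):
    """A CSV file or in-memory table violates the tidy-data schema.

    Carries enough context (file, row, rule) to locate the offending record.
    """

    def __init__(self, rule: str, file: str | None = None, row: object = None):
        self.rule = rule
        self.file = file
        self.row = row
        parts = [rule]
        if file is not None:
            parts.append(f"file={file}")
        if row is not None:
            parts.append(f"row={row}")
        super().__init__("; ".join(parts))


class GapError(DyadGazeError):
    """The raw gaze stream leaves part of the fusion timeline uncovered."""


class ConfigurationError(DyadGazeError):
    """A generator or pipeline configuration is internally inconsistent."""


class EmptyInputError(DyadGazeError):
    """An operation received no data where at least one record is required."""


class SampleSizeError(DyadGazeError):
    """A robust-statistics routine was given fewer observations than its bound."""
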