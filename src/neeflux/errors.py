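"""Exception hierarchy shared across the package."""


class NeefluxError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(NeefluxError):
    """A configuration object violates its documented constraints."""


class MissingColumnError(NeefluxError):
    """An input table lacks a required column."""

    def __init__(self, column: str, path: str | None = None):
        self.column = column
        self.path = path
        where = f" in {path}" if path else ""
        super().__init__(f"required column {column!r} missing{where}")


class DuplicateRecordError(NeefluxError):
    """Two records share a timestamp / composite date."""


class EmptyInputError(NeefluxError):
    """An operation received an empty sequence of records."""


class AllBadRecordsError(NeefluxError):
    """No record in the input passed quality control."""


class UndefinedRatioError(NeefluxError):
    """A band-ratio index was requested with a zero denominator."""


class InvalidStateError(NeefluxError):
    """A physical quantity left its admissible range (e.g. tau >= Ca)."""


class InsufficientDataError(NeefluxError):
    """Fewer valid observations than the configured minimum."""


class UnmappedTimestampError(NeefluxError):
    """A flux record falls outside every available parameter window."""
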