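"""Exception hierarchy shared across the package."""


class IrescanError(Exception):
    """Base class for all package errors."""


class FastaParseError(IrescanError):
    """Malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class AlphabetError(IrescanError):
    """A residue outside the allowed alphabet; names record and position."""

    def __init__(self, record_id: str, position: int, char: str):
        self.record_id = record_id
        self.position = position
        self.char = char
        super().__init__(
            f"non-ACGU residue {char!r} in record {record_id!r} "
            f"at position {position}"
        )


class DegenerateInputError(IrescanError):
    """Input too short/small for the requested operation."""


class EngineError(IrescanError):
    """A folding engine failed; carries raw engine output when available."""

    def __init__(self, message: str, raw_output: str | None = None):
        self.raw_output = raw_output
        super().__init__(message)


class ConfigError(IrescanError):
    """Invalid configuration values."""


class ValidationError(IrescanError):
    """Record-level data validation failure; carries offending ids."""

    def __init__(self, message: str, ids: list[str] | None = None):
        self.ids = ids or []
        if self.ids:
            message = f"{message}: {', '.join(self.ids)}"
        super().__init__(message)


class SchemaError(IrescanError):
    """Feature-name mismatch between a model and a prediction matrix."""

    def __init__(self, missing: list[str], extra: list[str]):
        self.missing = missing
        self.extra = extra
        parts = []
        if missing:
            parts.append(f"missing features: {missing[:5]}")
        if extra:
            parts.append(f"extra features: {extra[:5]}")
        super().__init__("feature schema mismatch; " + "; ".join(parts))
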