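"""Exception hierarchy for the toolkit."""


class AdrError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(AdrError):
    """A table file violates its declared schema (missing columns, unparseable
    values). Always fatal: the file cannot be interpreted."""


class UnknownIdentifierError(AdrError, KeyError):
    """A lookup referenced an ATC code, event code or accession the knowledge
    base does not contain."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)


class UnmappedEventError(UnknownIdentifierError):
    """An event token has no concept-identifier mapping."""


class InvalidArgumentError(AdrError, ValueError):
    """A statistical routine received arguments outside its domain."""
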