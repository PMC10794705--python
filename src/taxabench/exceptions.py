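"""Exception hierarchy for taxabench."""


class TaxaBenchError(Exception):
    """Base class for all taxabench errors."""


class InvalidNameError(TaxaBenchError):
    """Raised for empty or otherwise unusable organism name strings."""


class NameResolutionError(TaxaBenchError):
    """Raised when one or more names cannot be resolved to a TAXID.

    Carries the full list of offending names so a user can fix them in
    one pass instead of one at a time.
    """

    def __init__(self, unresolved):
        self.unresolved = list(unresolved)
        super().__init__(
            "could not resolve %d name(s) to TAXIDs: %s"
            % (len(self.unresolved), ", ".join(repr(n) for n in self.unresolved))
        )


class DumpParseError(TaxaBenchError):
    """Raised for malformed taxonomy dump records; includes the line number."""

    def __init__(self, path, lineno, message):
        self.path = path
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


class SchemaError(TaxaBenchError):
    """Raised when a table is missing mandatory columns or violates layout."""


class ProfileParseError(TaxaBenchError):
    """Raised for unparseable profiler output rows."""


class ValidationError(TaxaBenchError):
    """Raised when a parsed object violates its invariants."""


class DegenerateInputError(TaxaBenchError):
    """Raised for inputs that make a computation meaningless (e.g. zero totals)."""
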