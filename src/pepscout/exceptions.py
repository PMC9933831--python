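"""Exception hierarchy. Everything raised on purpose derives from PepscoutError."""


class PepscoutError(Exception):
    """Base class for all pepscout errors."""


class FastaFormatError(PepscoutError):
    """The input is not parseable FASTA (empty file, no '>' records, ...)."""


class DuplicateRecordError(PepscoutError):
    """Two records in one library share an accession."""

    def __init__(self, accession: str):
        self.accession = accession
        super().__init__(f"duplicate accession in proteome library: {accession!r}")


class ProteinNotFoundError(PepscoutError):
    """A requested accession is absent; carries near matches if any exist."""

    def __init__(self, accession: str, suggestions: tuple[str, ...] = ()):
        self.accession = accession
        self.suggestions = tuple(suggestions)
        msg = f"accession not found: {accession!r}"
        if self.suggestions:
            msg += f" (did you mean: {', '.join(self.suggestions)}?)"
        super().__init__(msg)


class UnknownProteaseError(PepscoutError):
    """An unrecognised cleavage-rule name; lists the supported rules."""

    def __init__(self, name: str, supported: tuple[str, ...]):
        self.name = name
        self.supported = tuple(supported)
        super().__init__(
            f"unknown protease {name!r}; supported rules: {', '.join(self.supported)}"
        )


class EmptyLibraryError(PepscoutError):
    """A peptide index cannot be built from an empty proteome library."""


class InvalidUSIError(PepscoutError):
    """A string does not follow the Universal Spectrum Identifier grammar."""


class SearchFailedError(PepscoutError):
    """Every query against every configured repository failed."""


class GenerationError(PepscoutError):
    """A fixture-world specification could not be satisfied."""
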