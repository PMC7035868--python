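"""Exception hierarchy shared across the package."""


class ScviewError(Exception):
    """Base class for all package errors."""


class ValidationError(ScviewError):
    """A dataset violates its structural invariants.

    Carries the full list of violation messages in ``violations``.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class FormatError(ScviewError):
    """An input file or directory is not in the expected format."""


class ConsistencyError(ScviewError):
    """Input components disagree with each other (e.g. matrix vs. barcodes)."""


class SpecificationError(ScviewError):
    """A filter/summary request references unknown columns, genes or embeddings."""


class AmbiguityError(SpecificationError):
    """A name resolves to more than one entity and needs a qualifier."""


class SourceError(ScviewError):
    """A data source could not be reached, listed or retrieved."""


class UnsupportedSchemeError(SourceError):
    """The URL scheme is not one of the supported protocols."""


class NotImplementedSchemeError(SourceError):
    """The scheme is recognized but deliberately not implemented (iRODS stub)."""
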