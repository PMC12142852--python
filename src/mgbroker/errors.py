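"""Exception hierarchy shared by all stages of the submission workflow."""


class MgBrokerError(Exception):
    """Base class for all errors raised by this package."""


class ConflictError(MgBrokerError):
    """A unique identifier (alias, bin id, accession) was used twice."""


class AccessionFormatError(MgBrokerError):
    """An accession string does not match the pattern for its object kind."""


class UnresolvedReferenceError(MgBrokerError):
    """A reference is neither a known alias nor a valid accession literal."""


class ScenarioError(MgBrokerError):
    """A submission scenario violates its prerequisites (e.g. MAGs without an assembly)."""


class ConfigParseError(MgBrokerError):
    """Configuration text could not be parsed; carries a line locus when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class FieldError(MgBrokerError):
    """A mandatory configuration field is absent; carries the dotted field path."""

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


class HeaderError(MgBrokerError):
    """A tabular input lacks a required column."""


class TableRangeError(MgBrokerError):
    """A tabular value is outside its permitted range; carries the row locus."""


class LineageDialectError(MgBrokerError):
    """A classification string uses an unrecognized rank prefix or shape."""


class EmptyLineageError(MgBrokerError):
    """All ranks of a lineage are empty; no candidate name can be derived."""


class UnsupportedDomainError(MgBrokerError):
    """The lineage domain is outside the Bacteria/Archaea rule table."""


class CoverageInputError(MgBrokerError):
    """An alignment map is unusable: no header, or unknown contigs requested."""


class DocumentError(MgBrokerError):
    """A registry-facing document could not be built (empty set, duplicates)."""


class ReceiptParseError(MgBrokerError):
    """A receipt is not well-formed XML or lacks its success attribute."""


class StagingError(MgBrokerError):
    """An upload bundle could not be staged (collisions, unwritable workdir)."""


class PreconditionError(MgBrokerError):
    """An operation was invoked before its prerequisite stage completed."""


class TransportError(MgBrokerError):
    """A service call failed at the transport level; retriable."""


class SubmissionError(MgBrokerError):
    """The registry rejected a submission; carries the receipt messages."""

    def __init__(self, message: str, messages: list | None = None):
        self.messages = messages or []
        super().__init__(message)


class TaxonomyHaltError(MgBrokerError):
    """Unresolvable bin/MAG taxonomies; submission refused before any service call."""

    def __init__(self, failures):
        self.failures = list(failures)
        ids = ", ".join(f.bin_id for f in self.failures)
        super().__init__(f"taxonomy resolution failed for: {ids}")


class ProductionOptInError(MgBrokerError):
    """Production mode requested without the explicit confirmation flag."""


class DatasetError(MgBrokerError):
    """The toy-dataset generator refused to run (e.g. non-empty target directory)."""
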