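"""Exception hierarchy shared across the pipeline stages."""


class AbcConformError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(AbcConformError):
    """A structure file could not be parsed in the declared format."""


class EmptyStructureError(AbcConformError):
    """A structure contains no protein residues."""


class EmptySelectionError(AbcConformError):
    """A chain/residue selection matched nothing."""


class TransformError(AbcConformError):
    """A rigid-body transform failed validation (non-orthonormal rotation)."""


class DomtbloutFormatError(AbcConformError):
    """A HMMER3 per-domain table row could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class AlignmentError(AbcConformError):
    """Structural alignment could not be performed on the given inputs."""


class ReferenceLibraryError(AbcConformError):
    """The reference library is missing, empty, or malformed."""


class FixtureSpecError(AbcConformError):
    """A synthetic-fixture specification is internally inconsistent."""
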