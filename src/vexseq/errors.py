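"""Exception hierarchy.

Every validation failure raises a named error so callers (and the CLI) can
report what rule was broken rather than a bare ValueError.
"""


class VexSeqError(Exception):
    """Base class for all package errors."""


class DesignConstraintError(VexSeqError):
    """An exon or region violates a library design rule."""


class MissingSequenceError(VexSeqError):
    """The genome does not cover the requested interval."""


class RefMismatchError(VexSeqError):
    """A variant's REF allele does not match the region/genome sequence."""


class NonCanonicalBoundaryError(VexSeqError):
    """Splice-site dinucleotides are not the canonical AG/GT."""


class FlankTooShortError(VexSeqError):
    """An intronic flank is too short for the requested transformation."""


class StrayMotifError(VexSeqError):
    """A restriction motif occurs outside its designated site."""

    def __init__(self, motif_name: str, motif: str, offset: int):
        self.motif_name = motif_name
        self.motif = motif
        self.offset = offset
        super().__init__(f"stray {motif_name} site ({motif}) at offset {offset}")


class OligoLengthError(VexSeqError):
    """Assembled oligo exceeds the configured maximum length."""


class InfeasibleBarcodeError(VexSeqError):
    """Requested barcode count cannot be satisfied under the constraints."""


class UndefinedRateError(VexSeqError):
    """A rate was requested from zero observations."""


class InsufficientDataError(VexSeqError):
    """Too few records for the requested statistic."""


class InvalidOrfError(VexSeqError):
    """ORF start does not point at an ATG codon."""
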