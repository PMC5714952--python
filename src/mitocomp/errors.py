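"""Exception hierarchy used across the toolkit."""


class MitocompError(Exception):
    """Base class for all toolkit errors."""


class ParseError(MitocompError):
    """Malformed input file."""


class AnnotationConflictError(MitocompError):
    """Two features resolve to the same canonical gene name."""


class BoundsError(MitocompError):
    """Feature coordinates fall outside the genome and are not wrap-flagged."""


class PrematureStopError(MitocompError):
    """An internal stop codon occurs before the final codon of a CDS."""

    def __init__(self, codon_index: int, codon: str):
        self.codon_index = codon_index
        self.codon = codon
        super().__init__(
            f"premature stop codon {codon!r} at codon index {codon_index}"
        )


class EmptyInputError(MitocompError):
    """An operation received an empty sequence or feature set."""


class FrameError(MitocompError):
    """Sequence length inconsistent with a codon reading frame."""


class AnnotationInconsistencyError(MitocompError):
    """Terminal bases inconsistent with the annotated (truncated) stop."""


class ContainmentError(MitocompError):
    """One feature is entirely contained in another; junction arithmetic undefined."""


class StructureError(MitocompError):
    """Unbalanced or inconsistent dot-bracket secondary structure."""


class ArityError(MitocompError):
    """Too few sequences for the requested statistic."""


class WindowError(MitocompError):
    """Sliding window longer than the alignment."""


class MissingAnchorError(MitocompError):
    """A gene required to anchor a region (e.g. trnI, rrnS) is not annotated."""


class SpecError(MitocompError):
    """A synthetic-genome specification is internally inconsistent."""
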