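"""Exception hierarchy shared by all genehurst modules."""


class GeneHurstError(Exception):
    """Base class for all package errors."""


class InputError(GeneHurstError):
    """Missing file, empty sample, or otherwise unusable input."""


class FormatError(GeneHurstError):
    """File exists but is not in the expected format."""


class RecordError(GeneHurstError):
    """A single gene-table row violates the schema or its invariants."""


class RangeError(GeneHurstError):
    """Gene coordinates fall outside the replicon."""


class RepliconMismatchError(GeneHurstError):
    """Gene references a replicon id that the genome does not provide."""


class AmbiguousBaseError(GeneHurstError):
    """Sequence contains a residue outside {A, C, G, T}."""

    def __init__(self, residue: str, position: int):
        self.residue = residue
        self.position = position
        super().__init__(
            f"ambiguous residue {residue!r} at 0-based position {position}"
        )


class DegenerateSeriesError(GeneHurstError):
    """Series is constant (zero variance) — no scaling exponent exists."""


class SeriesTooShortError(GeneHurstError):
    """Series shorter than the estimator's minimum length."""


class EstimationError(GeneHurstError):
    """All requested estimator modes failed on a series."""


class DomainError(GeneHurstError):
    """Parameter outside its mathematical domain."""


class DegenerateSampleError(GeneHurstError):
    """Sample has zero spread where a scale parameter must be estimated."""


class EmptyAnalysisError(GeneHurstError):
    """No genes survived the filters; nothing to analyze."""


class EmbeddingError(GeneHurstError):
    """Circulant embedding produced a materially negative eigenvalue."""
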