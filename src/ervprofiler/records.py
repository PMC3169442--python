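"""Core domain records shared by every stage of the pipeline.

All internal coordinates are 0-based, half-open.  The only 1-based boundary
in the package is SAM ingestion (``io.read_alignments``), which converts POS
on the way in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import FormatError, ParameterError
from .util import reverse_complement

_ALPHABET = frozenset("ACGTN")
_STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide sequence over {A,C,G,T,N}, stored uppercase."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise FormatError(f"sequence '{self.name}' is empty")
        bad = set(seq) - _ALPHABET
        if bad:
            raise FormatError(
                f"sequence '{self.name}' contains illegal character(s): {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self, name: str | None = None) -> "GenomeSequence":
        return GenomeSequence(name or self.name, reverse_complement(self.sequence))


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open stranded interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ParameterError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ParameterError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignedRead:
    """One placement of a sequencing read.

    ``n_hits`` is the number of equally good alignment locations for the
    read; a read is *unique* iff ``n_hits == 1``.  ``start`` is the 0-based
    position of the leftmost aligned base regardless of strand.
    """

    chrom: str
    start: int
    strand: str
    read_length: int = 50
    map_quality: int = 0
    n_hits: int = 1
    read_id: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ParameterError(f"negative alignment start {self.start}")
        if self.strand not in _STRANDS:
            raise ParameterError(f"invalid strand {self.strand!r}")
        if self.read_length <= 0:
            raise ParameterError("read_length must be positive")
        if self.map_quality < 0:
            raise ParameterError("map_quality must be non-negative")
        if self.n_hits < 1:
            raise ParameterError("n_hits must be >= 1")

    @property
    def end(self) -> int:
        return self.start + self.read_length

    @property
    def is_unique(self) -> bool:
        return self.n_hits == 1


@dataclass(frozen=True)
class ElementAnnotation:
    """A repeat element copy: genomic interval, family, intactness metadata.

    ``divergence`` is the substitution rate of this copy relative to the
    family consensus (used by the intactness filter).
    """

    interval: GenomicInterval
    family: str
    intact: bool = True
    divergence: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence < 1.0):
            raise ParameterError("divergence must be in [0, 1)")
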