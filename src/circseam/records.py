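"""Canonical circRNA back-splice records.

Every supported caller dialect is normalized to a :class:`CircRecord` in
BED-style coordinates: 0-based start, exclusive end, so ``end - start`` is
the genomic span of the circle for every input convention.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class Dialect(str, Enum):
    """Supported circRNA coordinate-file dialects."""

    BED = "bed"
    CIRI2 = "ciri2"
    FIND_CIRC = "find_circ"
    CIRCEXPLORER2 = "circexplorer2"
    DCC = "dcc"
    CIRCRNA_FINDER = "circrna_finder"
    KNIFE = "knife"
    MAPSPLICE = "mapsplice"


#: Maximum number of records processed per run.
RECORD_CAP = 100

VALID_STRANDS = {"+", "-"}


@dataclass(frozen=True)
class CircRecord:
    """One circRNA back-splice call in canonical genomic coordinates.

    Parameters
    ----------
    chrom : str
        Reference sequence name.
    start : int
        0-based inclusive position of the circle's first base.
    end : int
        0-based exclusive position past the circle's last base.
    strand : str
        ``'+'`` or ``'-'``. A ``'.'`` input strand is normalized to ``'+'``
        upstream with a warning.
    circ_id : str
        Label; generated as ``chrom:start-end:strand`` when the input has
        none.
    source_format : Dialect
        The dialect the record was parsed from.
    """

    chrom: str
    start: int
    end: int
    strand: str
    circ_id: str = ""
    source_format: Dialect = Dialect.BED

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.start}..{self.end} (need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.circ_id:
            object.__setattr__(
                self, "circ_id", f"{self.chrom}:{self.start}-{self.end}:{self.strand}"
            )

    @property
    def span(self) -> int:
        """Genomic span of the circle in nucleotides."""
        return self.end - self.start

    @property
    def key(self) -> tuple:
        """Dedup key: records sharing it describe the same back-splice."""
        return (self.chrom, self.start, self.end, self.strand)


@dataclass
class RecordBatch:
    """An ordered, deduplicated, capped set of :class:`CircRecord`.

    ``n_input`` counts data rows seen; ``n_kept`` counts records retained
    after dedup and the per-run cap. Order of kept records follows input
    order; duplicates keep the first occurrence.
    """

    records: list[CircRecord] = field(default_factory=list)
    n_input: int = 0
    n_kept: int = 0
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.n_kept != len(self.records):
            self.n_kept = len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)
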