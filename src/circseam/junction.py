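"""Back-splice junction templates.

A circRNA's only circle-specific sequence is the back-splice junction
(BSJ): the covalent joint between the circle's 3' end and its 5' start. To
let ordinary linear primer design target it, each circle is linearized
locally around the BSJ: the template is the 3'-flank of the circle
concatenated to its 5'-flank, with the junction position recorded.

Flank lengths come from the shift ranges (default 150 nt each side) and
are clamped to the circle's own span — a circle shorter than the windows
contributes at most one full turn per flank, never more, since wrapping
further would duplicate the junction inside the template.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .genome import GenomeSource, subsequence
from .records import CircRecord


@dataclass(frozen=True)
class JunctionTemplate:
    """Linear template around one back-splice junction.

    ``sequence[:junction_index]`` is the donor-side flank (the circle's 3'
    end); ``sequence[junction_index:]`` is the acceptor-side flank (the
    circle's 5' start). ``left_used``/``right_used`` are the flank lengths
    actually taken after clamping to the circle span.
    """

    record: CircRecord
    sequence: str
    junction_index: int
    left_used: int
    right_used: int

    def __post_init__(self):
        assert len(self.sequence) == self.left_used + self.right_used
        assert self.junction_index == self.left_used


def build_template(
    record: CircRecord,
    genome: GenomeSource,
    shift_left: int = 150,
    shift_right: int = 150,
) -> JunctionTemplate:
    """Build the junction template for one record.

    On ``'+'`` the donor flank is the genomic sequence ending at ``end``
    and the acceptor flank starts at ``start``. On ``'-'`` the template is
    built on the transcribed strand: the donor flank is the reverse
    complement of the genomic region starting at ``start`` and the
    acceptor flank is the reverse complement of the region ending at
    ``end``.
    """
    if shift_left < 1 or shift_right < 1:
        raise ValueError("shift ranges must be >= 1")
    span = record.span
    left_used = min(shift_left, span)
    right_used = min(shift_right, span)
    c, s, e = record.chrom, record.start, record.end
    if record.strand == "+":
        donor = subsequence(genome, c, e - left_used, e, "+")
        acceptor = subsequence(genome, c, s, s + right_used, "+")
    else:
        donor = subsequence(genome, c, s, s + left_used, "-")
        acceptor = subsequence(genome, c, e - right_used, e, "-")
    return JunctionTemplate(
        record=record,
        sequence=donor + acceptor,
        junction_index=left_used,
        left_used=left_used,
        right_used=right_used,
    )


def template_header(template: JunctionTemplate) -> str:
    r = template.record
    return (
        f"{r.circ_id}|junction={template.junction_index}|"
        f"{r.chrom}:{r.start}-{r.end}({r.strand})"
    )


def templates_to_fasta(templates: list[JunctionTemplate], path: str | Path) -> None:
    """Write templates as FASTA, one entry each.

    Header grammar: ``circ_id|junction=<j>|<chrom>:<start>-<end>(<strand>)``.
    Headers are uniquified with ``_2``, ``_3`` … suffixes when circ_ids
    collide.
    """
    seen: dict[str, int] = {}
    with Path(path).open("w") as fh:
        for tpl in templates:
            header = template_header(tpl)
            count = seen.get(header, 0) + 1
            seen[header] = count
            if count > 1:
                header = f"{header}_{count}"
            fh.write(f">{header}\n{tpl.sequence}\n")
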