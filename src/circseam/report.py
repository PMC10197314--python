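"""Result tables: primers.tsv, templates.fasta, failures.tsv, run log.

Output is deterministic byte-for-byte: UTF-8, LF line endings, '.'
decimal, floats formatted at fixed precision, stable column order. The
column order of primers.tsv is part of the public contract.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .conditions import PcrConditions
from .junction import JunctionTemplate, templates_to_fasta
from .primers import DesignConfig, PrimerPair
from .records import CircRecord, RecordBatch

PRIMERS_COLUMNS = [
    "circ_id",
    "set_rank",
    "forward_seq",
    "reverse_seq",
    "forward_start",
    "forward_len",
    "reverse_start",
    "reverse_len",
    "forward_tm",
    "reverse_tm",
    "forward_gc",
    "reverse_gc",
    "product_size",
    "junction_index",
    "pair_penalty",
    "annealing_temp",
    "extension_time_s",
    "cycles",
    "specificity",
]

FAILURES_COLUMNS = ["circ_id", "reason"]


@dataclass
class RecordResult:
    """Design outcome for one circRNA record."""

    record: CircRecord
    template: JunctionTemplate | None = None
    pairs: list[tuple[PrimerPair, PcrConditions]] = field(default_factory=list)
    failure: str | None = None

    @property
    def designed(self) -> bool:
        return bool(self.pairs)


@dataclass
class DesignResult:
    """Full pipeline output for one batch."""

    batch: RecordBatch
    config: DesignConfig
    results: list[RecordResult] = field(default_factory=list)
    seed: int | None = None

    @property
    def n_designed(self) -> int:
        return sum(1 for r in self.results if r.designed)

    @property
    def failures(self) -> list[RecordResult]:
        return [r for r in self.results if not r.designed]


def _primer_row(circ_id: str, rank: int, pair: PrimerPair, cond: PcrConditions,
                junction_index: int) -> str:
    f, r = pair.forward, pair.reverse
    vals = [
        circ_id,
        str(rank),
        f.sequence,
        r.sequence,
        str(f.template_start),
        str(f.length),
        str(r.template_start),
        str(r.length),
        f"{f.tm:.2f}",
        f"{r.tm:.2f}",
        f"{f.gc:.3f}",
        f"{r.gc:.3f}",
        str(pair.product_size),
        str(junction_index),
        f"{pair.pair_penalty:.3f}",
        f"{cond.annealing_temp:.1f}",
        str(cond.extension_time),
        str(cond.cycles),
        pair.specificity,
    ]
    return "\t".join(vals)


def write_report(result: DesignResult, out_dir: str | Path) -> dict[str, Path]:
    """Write all output files; returns a name → path mapping.

    ``primers.tsv`` has one row per reported pair (≤ n_kept · n_sets
    overall); every circ_id appears in exactly one of primers.tsv or
    failures.tsv. All files exist even for an empty run.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "primers": out / "primers.tsv",
        "templates": out / "templates.fasta",
        "failures": out / "failures.tsv",
        "log": out / "run_log.txt",
    }

    with paths["primers"].open("w", newline="") as fh:
        fh.write("\t".join(PRIMERS_COLUMNS) + "\n")
        for rr in result.results:
            if rr.template is None:
                continue
            for rank, (pair, cond) in enumerate(rr.pairs, start=1):
                fh.write(
                    _primer_row(rr.record.circ_id, rank, pair, cond,
                                rr.template.junction_index) + "\n"
                )

    templates = [rr.template for rr in result.results if rr.template is not None]
    templates_to_fasta(templates, paths["templates"]) if templates else paths[
        "templates"
    ].write_text("")

    with paths["failures"].open("w", newline="") as fh:
        fh.write("\t".join(FAILURES_COLUMNS) + "\n")
        for rr in result.failures:
            reason = rr.failure or "no primers found"
            fh.write(f"{rr.record.circ_id}\t{reason}\n")

    cfg = result.config
    lines = ["circseam run log", "================", ""]
    if result.seed is not None:
        lines.append(f"seed: {result.seed}")
    lines.append(f"records: input={result.batch.n_input} kept={result.batch.n_kept}")
    lines.append(f"designed: {result.n_designed} of {len(result.results)}")
    lines.append("")
    lines.append("config:")
    for key, value in sorted(vars(cfg).items()):
        lines.append(f"  {key} = {value}")
    if result.batch.warnings:
        lines.append("")
        lines.append("warnings:")
        for w in result.batch.warnings:
            lines.append(f"  - {w}")
    paths["log"].write_text("\n".join(lines) + "\n")
    return paths
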