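"""End-to-end design pipeline: records + genome → ranked primer sets.

Orchestrates parsing, junction-template construction, primer design,
locus-windowed specificity checking and condition recommendation. Records
that cannot be designed (unknown chromosome, N-masked flanks, no valid
pairs) are reported with a reason rather than aborting the run.
"""
from __future__ import annotations

from dataclasses import replace
from pathlib import Path

from .conditions import recommend_conditions
from .errors import OutOfBounds
from .formats import parse_records
from .genome import GenomeSource
from .junction import build_template
from .primers import (
    DesignConfig,
    enumerate_candidates,
    linear_specificity_check,
    pair_and_rank,
)
from .records import RecordBatch
from .report import DesignResult, RecordResult, write_report


def design_batch(
    batch: RecordBatch,
    genome: GenomeSource,
    cfg: DesignConfig | None = None,
    check_specificity: bool = True,
    seed: int | None = None,
) -> DesignResult:
    """Design primer sets for every record in a batch.

    The algorithm is fully deterministic; ``seed`` is only echoed into the
    run log for provenance.
    """
    cfg = cfg or DesignConfig()
    result = DesignResult(batch=batch, config=cfg, seed=seed)

    for record in batch:
        rr = RecordResult(record=record)
        result.results.append(rr)
        if record.chrom not in genome:
            rr.failure = f"sequence {record.chrom!r} absent from genome"
            batch.warnings.append(f"{record.circ_id}: {rr.failure}")
            continue
        try:
            template = build_template(record, genome, cfg.shift_left, cfg.shift_right)
        except OutOfBounds as exc:
            rr.failure = f"record exceeds contig bounds ({exc})"
            batch.warnings.append(f"{record.circ_id}: {rr.failure}")
            continue
        donor = template.sequence[: template.junction_index]
        acceptor = template.sequence[template.junction_index :]
        if set(donor) == {"N"} or set(acceptor) == {"N"}:
            rr.failure = "junction flank contains only N bases"
            batch.warnings.append(f"{record.circ_id}: {rr.failure}")
            continue
        rr.template = template
        fwd, rev = enumerate_candidates(template, cfg)
        pairs = pair_and_rank(fwd, rev, template, cfg)
        if not pairs:
            rr.failure = "no primers found"
            continue
        for pair in pairs:
            if check_specificity:
                ok, note = linear_specificity_check(
                    pair, record, genome, cfg.max_linear_product
                )
                pair = replace(
                    pair, specificity="pass" if ok else f"fail:{note}"
                )
            rr.pairs.append((pair, recommend_conditions(pair)))
    return result


def run_design(
    input_path: str | Path,
    genome: GenomeSource,
    cfg: DesignConfig | None = None,
    fmt: str = "auto",
    out_dir: str | Path | None = None,
    strict: bool = False,
    check_specificity: bool = True,
    seed: int | None = None,
) -> DesignResult:
    """Parse a coordinate file, design primers, optionally write reports."""
    batch = parse_records(input_path, fmt=fmt, strict=strict)
    result = design_batch(
        batch, genome, cfg, check_specificity=check_specificity, seed=seed
    )
    if out_dir is not None:
        write_report(result, out_dir)
    return result
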