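"""Deterministic synthetic genomes and circRNA call files.

Generates a random genome at a target GC, plants circRNA intervals at
known coordinates, and serializes the same truth set in all eight
supported caller dialects, each with its own coordinate convention. The
same seed always yields byte-identical files, making every pipeline stage
testable without any download.

Base composition is i.i.d. at the target GC; no higher-order genome
realism (repeats, isochores, splice motifs) is modelled except for
explicitly planted repeats used to provoke specificity-check failures.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import reverse_complement
from .records import CircRecord, Dialect

_BASES = np.array(list("ACGT"))


@dataclass
class PlantedRepeat:
    """Copy a circle's donor flank, reverse-complemented, downstream.

    The forward primer binds the donor flank pointing toward the circle
    end; the reverse-complemented copy at ``distance`` nt past the end
    gives it a second, left-pointing site, so the pair becomes convergent
    on the linear locus and fails the specificity check.
    """

    circle_index: int
    distance: int = 1000
    length: int = 150


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset; same seed → same bytes."""

    seed: int = 0
    n_contigs: int = 1
    contig_len: int = 10_000
    gc: float = 0.5
    n_circles: int = 10
    span_range: tuple[int, int] = (300, 800)
    strands: tuple[str, ...] = ("+", "-")
    planted_repeats: list[PlantedRepeat] = field(default_factory=list)
    mask_circles: tuple[int, ...] = ()  # indices whose flanks become all-N


@dataclass
class Fixture:
    """Paths and ground truth returned by :func:`make_fixture`."""

    genome_fasta: Path
    call_files: dict[Dialect, Path]
    truth_table: Path
    records: list[CircRecord]


def _random_contig(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def _plant_circles(
    rng: np.random.Generator, spec: FixtureSpec, contig_names: list[str]
) -> list[CircRecord]:
    records: list[CircRecord] = []
    lo, hi = spec.span_range
    margin = 10
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_names}
    attempts = 0
    while len(records) < spec.n_circles and attempts < spec.n_circles * 200:
        attempts += 1
        chrom = contig_names[int(rng.integers(len(contig_names)))]
        span = int(rng.integers(lo, hi + 1))
        if span + 2 * margin >= spec.contig_len:
            continue
        start = int(rng.integers(margin, spec.contig_len - span - margin))
        end = start + span
        if any(s < end + margin and start < e + margin for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        strand = spec.strands[int(rng.integers(len(spec.strands)))]
        idx = len(records) + 1
        records.append(
            CircRecord(chrom, start, end, strand, f"circ_{idx:03d}", Dialect.BED)
        )
    if len(records) < spec.n_circles:
        raise ValueError(
            f"could not place {spec.n_circles} non-overlapping circles in "
            f"{spec.n_contigs}x{spec.contig_len} nt"
        )
    return records


def _write_fasta(path: Path, contigs: dict[str, str], width: int = 70) -> None:
    with path.open("w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _write_dialects(out_dir: Path, records: list[CircRecord]) -> dict[Dialect, Path]:
    paths: dict[Dialect, Path] = {}

    def emit(dialect: Dialect, filename: str, header: str | None, rowfn) -> None:
        p = out_dir / filename
        with p.open("w") as fh:
            if header:
                fh.write(header + "\n")
            for r in records:
                fh.write(rowfn(r) + "\n")
        paths[dialect] = p

    emit(
        Dialect.BED, "calls.bed", None,
        lambda r: f"{r.chrom}\t{r.start}\t{r.end}\t{r.circ_id}\t0\t{r.strand}",
    )
    ciri_header = (
        "circRNA_ID\tchr\tcircRNA_start\tcircRNA_end\t#junction_reads\tSM_MS_SMS\t"
        "#non_junction_reads\tjunction_reads_ratio\tcircRNA_type\tgene_id\tstrand\t"
        "junction_reads_ID"
    )
    emit(
        Dialect.CIRI2, "calls.ciri2.txt", ciri_header,
        lambda r: (
            f"{r.circ_id}\t{r.chrom}\t{r.start + 1}\t{r.end}\t5\tMS\t10\t0.5\t"
            f"exon\tgene\t{r.strand}\tids"
        ),
    )
    fc_header = (
        "# chrom\tstart\tend\tname\tn_reads\tstrand\tn_uniq\tuniq_bridges\t"
        "best_qual_left\tbest_qual_right\ttissues\ttiss_counts\tedits\t"
        "anchor_overlap\tbreakpoints"
    )
    emit(
        Dialect.FIND_CIRC, "calls.find_circ.bed", fc_header,
        lambda r: (
            f"{r.chrom}\t{r.start}\t{r.end}\t{r.circ_id}\t5\t{r.strand}\t5\t2\t"
            f"40\t40\ttissue\t1\t0\t2\t1"
        ),
    )
    emit(
        Dialect.CIRCEXPLORER2, "calls.circexplorer2.txt", None,
        lambda r: (
            f"{r.chrom}\t{r.start}\t{r.end}\t{r.circ_id}\t0\t{r.strand}\t"
            f"{r.start}\t{r.end}\t0,0,0\t1\t{r.span}\t0\t5\tcircRNA\tgene\t"
            f"iso\t1\tNone"
        ),
    )
    emit(
        Dialect.DCC, "calls.dcc_circcoordinates.txt", None,
        lambda r: (
            f"{r.chrom}\t{r.start + 1}\t{r.end}\t{r.circ_id}\t1\t{r.strand}\t"
            f"exon-exon\tcircRNA"
        ),
    )
    emit(
        Dialect.CIRCRNA_FINDER, "calls.circrna_finder.bed", None,
        lambda r: f"{r.chrom}\t{r.start}\t{r.end}\t{r.circ_id}\t5\t{r.strand}",
    )
    emit(
        Dialect.KNIFE, "calls.knife_report.txt", None,
        lambda r: (
            f"{r.chrom}|geneA:{r.start + 1}|geneB:{r.end}|reg|{r.strand}\t0.99\t5"
        ),
    )
    emit(
        Dialect.MAPSPLICE, "calls.mapsplice_circular_rnas.txt", None,
        lambda r: (
            f"{r.chrom}~{r.chrom}\t{r.end}\t{r.start + 1}\t{r.circ_id}\t5\t"
            f"{r.strand * 2}"
        ),
    )
    return paths


def make_fixture(spec: FixtureSpec, out_dir: str | Path) -> Fixture:
    """Write genome FASTA + 8 dialect call files + truth table.

    The planted truth records parse back identically from every dialect
    file (names differ only for KNIFE, whose identifier *is* the junction
    name, so parsed KNIFE circ_ids carry coordinates instead of labels).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    names = [f"ctg{i + 1}" for i in range(spec.n_contigs)]
    arrays = {name: _random_contig(rng, spec.contig_len, spec.gc) for name in names}
    records = _plant_circles(rng, spec, names)

    contigs = {name: "".join(_BASES[arr]) for name, arr in arrays.items()}

    for rep in spec.planted_repeats:
        r = records[rep.circle_index]
        flank = contigs[r.chrom][r.end - rep.length : r.end]
        insert = reverse_complement(flank)
        pos = r.end + rep.distance
        seq = contigs[r.chrom]
        if pos + len(insert) > len(seq):
            raise ValueError("planted repeat exceeds contig bounds")
        contigs[r.chrom] = seq[:pos] + insert + seq[pos + len(insert):]

    for idx in spec.mask_circles:
        r = records[idx]
        seq = contigs[r.chrom]
        contigs[r.chrom] = seq[: r.start] + "N" * r.span + seq[r.end :]

    genome_fasta = out / "genome.fa"
    _write_fasta(genome_fasta, contigs)
    for stale in (out / "genome.fa.fai",):
        stale.unlink(missing_ok=True)

    call_files = _write_dialects(out, records)

    truth = out / "truth.tsv"
    with truth.open("w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tcirc_id\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\t{r.circ_id}\n")

    return Fixture(
        genome_fasta=genome_fasta,
        call_files=call_files,
        truth_table=truth,
        records=records,
    )
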