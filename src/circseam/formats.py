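"""Parsers for circRNA caller output dialects.

Eight dialects are read: plain BED, CIRI2, find_circ, CIRCexplorer2, DCC,
circRNA_finder, KNIFE and mapsplice. Each is converted to canonical
0-based half-open :class:`~circseam.records.CircRecord` coordinates at a
single per-dialect conversion site, so a 400-nt circle is 400 nt no matter
which caller reported it.

Column layouts follow each predictor's own documented output:

* BED / circRNA_finder / find_circ: 0-based half-open, strand in column 6.
* CIRI2: tab file with a ``circRNA_ID`` header, 1-based inclusive.
* CIRCexplorer2 ``circularRNA_known.txt``: BED12-plus (18 columns), 0-based.
* DCC ``CircCoordinates``: 1-based start, inclusive end.
* KNIFE: coordinates decoded from the junction name
  ``chrom|gene1:pos1|gene2:pos2|kind|strand`` (1-based splice positions).
* mapsplice ``circular_RNAs.txt``: ``chrom~chrom`` fusion notation with
  1-based junction coordinates.
"""
from __future__ import annotations

import re
from pathlib import Path

from .errors import CapExceeded, MalformedRow, UnrecognizedFormat
from .records import RECORD_CAP, CircRecord, Dialect, RecordBatch

_KNIFE_PART = re.compile(r"^(?P<gene>[^:|]*):(?P<pos>\d+)$")


def _is_int(tok: str) -> bool:
    try:
        int(tok)
        return True
    except ValueError:
        return False


def _norm_strand(tok: str, warnings: list[str] | None = None, line_no: int = 0) -> str:
    tok = tok.strip()
    if tok in ("+", "-"):
        return tok
    if tok in (".", ""):
        if warnings is not None:
            warnings.append(
                f"line {line_no}: strand '.' treated as '+' (strand unknown)"
            )
        return "+"
    # mapsplice writes doubled strands like '++' / '--'
    if tok in ("++", "--"):
        return tok[0]
    raise ValueError(f"invalid strand {tok!r}")


def detect_format(first_lines: list[str]) -> Dialect:
    """Infer the dialect from header tokens and column signatures.

    Only file content is inspected, never the filename. Raises
    :class:`UnrecognizedFormat` when no dialect matches.
    """
    stripped = [ln.rstrip("\r\n") for ln in first_lines]
    nonempty = [ln for ln in stripped if ln.strip()]
    if not nonempty:
        raise UnrecognizedFormat("no non-empty lines to inspect")

    first = nonempty[0]
    if first.startswith("circRNA_ID\t") or first.startswith("circRNA_ID "):
        return Dialect.CIRI2
    if first.lstrip("# ").startswith("chrom\t") and first.startswith("#"):
        return Dialect.FIND_CIRC

    data = [ln for ln in nonempty if not ln.startswith("#")]
    if not data:
        raise UnrecognizedFormat("only comment lines present")
    cols = data[0].split("\t")

    if "~" in cols[0] and len(cols) >= 3 and _is_int(cols[1]) and _is_int(cols[2]):
        return Dialect.MAPSPLICE
    if cols[0].count("|") >= 3 and ":" in cols[0]:
        return Dialect.KNIFE
    if (
        len(cols) >= 18
        and _is_int(cols[1])
        and _is_int(cols[2])
        and cols[13] in ("circRNA", "ciRNA")
    ):
        return Dialect.CIRCEXPLORER2
    if (
        len(cols) == 8
        and _is_int(cols[1])
        and _is_int(cols[2])
        and not _is_int(cols[3])
        and _is_int(cols[4])
        and cols[5] in ("+", "-", ".")
        and not _is_int(cols[6])
        and not _is_int(cols[7])
    ):
        return Dialect.DCC
    if 3 <= len(cols) <= 12 and _is_int(cols[1]) and _is_int(cols[2]):
        # circRNA_finder and find_circ (headerless) are column-compatible
        # with BED and parse identically.
        return Dialect.BED
    raise UnrecognizedFormat(
        f"no supported dialect matches a {len(cols)}-column line: {data[0]!r}"
    )


def _parse_bedlike(cols, line_no, warnings, dialect):
    if len(cols) < 3:
        raise ValueError("need at least 3 columns")
    chrom, start, end = cols[0], int(cols[1]), int(cols[2])
    name = cols[3] if len(cols) > 3 and cols[3] not in (".", "") else ""
    strand = _norm_strand(cols[5], warnings, line_no) if len(cols) > 5 else "+"
    return CircRecord(chrom, start, end, strand, name, dialect)


def _parse_ciri2(cols, header_idx, line_no, warnings):
    chrom = cols[header_idx["chr"]]
    start = int(cols[header_idx["circRNA_start"]]) - 1
    end = int(cols[header_idx["circRNA_end"]])
    name = cols[header_idx["circRNA_ID"]]
    strand = "+"
    if "strand" in header_idx and header_idx["strand"] < len(cols):
        strand = _norm_strand(cols[header_idx["strand"]], warnings, line_no)
    return CircRecord(chrom, start, end, strand, name, Dialect.CIRI2)


def _parse_dcc(cols, line_no, warnings):
    chrom, start, end = cols[0], int(cols[1]) - 1, int(cols[2])
    name = cols[3] if cols[3] not in (".", "") else ""
    strand = _norm_strand(cols[5], warnings, line_no)
    return CircRecord(chrom, start, end, strand, name, Dialect.DCC)


def _parse_knife(cols, line_no, warnings):
    parts = cols[0].split("|")
    if len(parts) < 4:
        raise ValueError("junction id needs >= 4 '|'-separated parts")
    chrom = parts[0]
    m1, m2 = _KNIFE_PART.match(parts[1]), _KNIFE_PART.match(parts[2])
    if not (m1 and m2):
        raise ValueError("junction id positions must be 'gene:pos'")
    p1, p2 = int(m1.group("pos")), int(m2.group("pos"))
    start, end = min(p1, p2) - 1, max(p1, p2)
    strand = "+"
    if len(parts) >= 5 and parts[4] in ("+", "-", "."):
        strand = _norm_strand(parts[4], warnings, line_no)
    return CircRecord(chrom, start, end, strand, cols[0], Dialect.KNIFE)


def _parse_mapsplice(cols, line_no, warnings):
    chrom = cols[0].split("~")[0]
    c1, c2 = int(cols[1]), int(cols[2])
    start, end = min(c1, c2) - 1, max(c1, c2)
    name = cols[3] if len(cols) > 3 and not _is_int(cols[3]) else ""
    strand = "+"
    for tok in cols[4:7]:
        if re.fullmatch(r"[+-.]{1,2}", tok):
            strand = _norm_strand(tok, warnings, line_no)
            break
    return CircRecord(chrom, start, end, strand, name, Dialect.MAPSPLICE)


def parse_records(
    path: str | Path,
    fmt: Dialect | str = "auto",
    cap: int = RECORD_CAP,
    strict: bool = False,
) -> RecordBatch:
    """Parse a circRNA coordinate file into a canonical :class:`RecordBatch`.

    Duplicate records (same chrom/start/end/strand) keep the first
    occurrence. Records beyond ``cap`` are dropped with a warning, or raise
    :class:`CapExceeded` when ``strict`` is set. An empty file yields an
    empty batch with a warning, not an error.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()

    batch = RecordBatch()
    if fmt == "auto" or fmt is None:
        try:
            dialect = detect_format(lines[:50])
        except UnrecognizedFormat:
            if not any(ln.strip() for ln in lines):
                batch.warnings.append(f"{path.name}: empty input, no records parsed")
                return batch
            raise
    else:
        dialect = Dialect(fmt)

    header_idx: dict[str, int] = {}
    seen: set[tuple] = set()
    dropped = 0

    for line_no, raw in enumerate(lines, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        if line.startswith(("track", "browser")):
            continue
        if dialect is Dialect.CIRI2 and line.startswith("circRNA_ID"):
            header_idx = {name: i for i, name in enumerate(line.split("\t"))}
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        try:
            if dialect in (Dialect.BED, Dialect.FIND_CIRC, Dialect.CIRCRNA_FINDER,
                           Dialect.CIRCEXPLORER2):
                rec = _parse_bedlike(cols, line_no, batch.warnings, dialect)
            elif dialect is Dialect.CIRI2:
                if not header_idx:
                    header_idx = {
                        "circRNA_ID": 0, "chr": 1, "circRNA_start": 2,
                        "circRNA_end": 3, "strand": 10,
                    }
                rec = _parse_ciri2(cols, header_idx, line_no, batch.warnings)
            elif dialect is Dialect.DCC:
                rec = _parse_dcc(cols, line_no, batch.warnings)
            elif dialect is Dialect.KNIFE:
                rec = _parse_knife(cols, line_no, batch.warnings)
            elif dialect is Dialect.MAPSPLICE:
                rec = _parse_mapsplice(cols, line_no, batch.warnings)
            else:  # pragma: no cover - enum is exhaustive
                raise ValueError(f"unhandled dialect {dialect}")
        except (ValueError, IndexError) as exc:
            raise MalformedRow(line_no, line, str(exc)) from exc

        batch.n_input += 1
        if rec.key in seen:
            continue
        seen.add(rec.key)
        if len(batch.records) >= cap:
            dropped += 1
            continue
        batch.records.append(rec)

    if dropped:
        if strict:
            raise CapExceeded(
                f"{batch.n_input} rows exceed the {cap}-record cap (strict mode)"
            )
        batch.warnings.append(
            f"input has {len(seen)} distinct records; kept the first {cap}, "
            f"dropped {dropped} (per-run cap)"
        )
    if batch.n_input == 0:
        batch.warnings.append(f"{path.name}: empty input, no records parsed")
    batch.n_kept = len(batch.records)
    return batch


def write_bed(batch: RecordBatch, path: str | Path) -> None:
    """Write a batch as BED6; round-trips through :func:`parse_records`."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in batch.records:
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.circ_id}\t0\t{rec.strand}\n"
            )
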