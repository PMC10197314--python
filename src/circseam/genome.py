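"""Random-access reference genome sequence.

Local FASTA files (plain or gzip) are indexed with pyfaidx. A genome can
also be named by NCBI assembly accession (e.g. ``GCF_001858045.2``): it is
downloaded once into a cache directory and then behaves exactly like a
local file. Nothing in the library ever requires the network when a local
FASTA is given.
"""
from __future__ import annotations

import gzip
import re
import shutil
import tempfile
import urllib.request
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import pyfaidx

from .errors import GenomeError, OutOfBounds, UnknownSequence

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ACCESSION_RE = re.compile(r"^GC[AF]_\d{9}\.\d+$")
_NON_ACGTN = re.compile(r"[^ACGTN]")

#: NCBI datasets v2 download endpoint (genome FASTA only).
NCBI_DATASETS_URL = (
    "https://api.ncbi.nlm.nih.gov/datasets/v2/genome/accession/"
    "{accession}/download?include_annotation_type=GENOME_FASTA"
)


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_accession(token: str) -> bool:
    """True for a syntactically valid NCBI assembly accession."""
    return bool(_ACCESSION_RE.match(token))


@dataclass
class GenomeSource:
    """Indexed, strand-aware access to a reference genome."""

    path: Path
    origin: str = "local_fasta"
    accession: str | None = None
    warnings: list[str] = field(default_factory=list)
    _fasta: pyfaidx.Fasta | None = field(default=None, repr=False)

    def __post_init__(self):
        if self._fasta is None:
            try:
                self._fasta = pyfaidx.Fasta(str(self.path))
            except (pyfaidx.FastaIndexingError, pyfaidx.FastaNotFoundError) as exc:
                raise GenomeError(f"cannot index FASTA {self.path}: {exc}") from exc
        if not len(self._fasta.keys()):
            raise GenomeError(f"{self.path}: no sequences found")

    @property
    def names(self) -> list[str]:
        return list(self._fasta.keys())

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(self._fasta[name]) for name in self._fasta.keys()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fasta

    def length(self, chrom: str) -> int:
        if chrom not in self._fasta:
            raise UnknownSequence(f"sequence {chrom!r} not in genome")
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        return subsequence(self, chrom, start, end, strand)


def subsequence(
    src: GenomeSource, chrom: str, start: int, end: int, strand: str = "+"
) -> str:
    """Extract ``[start, end)`` on the given strand, uppercased.

    ``'-'`` returns the reverse complement of the forward slice. Softmasked
    bases are uppercased; IUPAC ambiguity codes other than N are mapped to
    N (the primer engine rejects ambiguous windows anyway).
    """
    if chrom not in src._fasta:
        raise UnknownSequence(f"sequence {chrom!r} not in genome")
    n = len(src._fasta[chrom])
    if not (0 <= start < end <= n):
        raise OutOfBounds(f"{chrom}:{start}-{end} outside [0, {n})")
    seq = src._fasta[chrom][start:end].seq.upper()
    if _NON_ACGTN.search(seq):
        seq = _NON_ACGTN.sub("N", seq)
        src.warnings.append(
            f"{chrom}:{start}-{end}: ambiguity codes beyond N mapped to N"
        )
    if strand == "-":
        seq = reverse_complement(seq)
    elif strand != "+":
        raise ValueError(f"invalid strand {strand!r}")
    return seq


def _gunzip_to_cache(path: Path, cache_dir: Path | None) -> Path:
    """Decompress a gzip FASTA so pyfaidx can index it."""
    if cache_dir is None:
        cache_dir = Path(tempfile.mkdtemp(prefix="circseam_genome_"))
    cache_dir.mkdir(parents=True, exist_ok=True)
    out = cache_dir / path.name.removesuffix(".gz")
    if not out.exists():
        with gzip.open(path, "rb") as src, open(out, "wb") as dst:
            shutil.copyfileobj(src, dst)
    return out


def fetch_assembly(
    accession: str, cache_dir: Path, url_template: str = NCBI_DATASETS_URL
) -> Path:
    """Download an NCBI assembly FASTA into ``<cache>/<accession>/``.

    The download happens once; subsequent calls hit the cache. Network is
    required only on a cache miss.
    """
    target_dir = cache_dir / accession
    target = target_dir / f"{accession}.fna"
    if target.exists():
        return target
    target_dir.mkdir(parents=True, exist_ok=True)
    url = url_template.format(accession=accession)
    zip_path = target_dir / f"{accession}.zip"
    try:
        with urllib.request.urlopen(url) as resp, open(zip_path, "wb") as out:
            shutil.copyfileobj(resp, out)
        with zipfile.ZipFile(zip_path) as zf:
            fna_members = [m for m in zf.namelist() if m.endswith((".fna", ".fa"))]
            if not fna_members:
                raise GenomeError(f"no FASTA inside download for {accession}")
            with zf.open(fna_members[0]) as src, open(target, "wb") as dst:
                shutil.copyfileobj(src, dst)
    except OSError as exc:
        raise GenomeError(f"failed to fetch {accession}: {exc}") from exc
    finally:
        zip_path.unlink(missing_ok=True)
    return target


def open_genome(
    path_or_accession: str | Path,
    mode: str = "auto",
    cache_dir: str | Path | None = None,
) -> GenomeSource:
    """Open a genome from a local FASTA path or an NCBI assembly accession.

    ``mode`` is ``'local'``, ``'ncbi'`` or ``'auto'`` (accession syntax and
    a missing local file select remote). Gzip input is transparently
    decompressed. Remote mode downloads once into ``cache_dir`` (default
    ``~/.cache/circseam``) and then behaves as local.
    """
    token = str(path_or_accession)
    cache = Path(cache_dir) if cache_dir else Path.home() / ".cache" / "circseam"
    remote = mode == "ncbi" or (
        mode == "auto" and is_accession(token) and not Path(token).exists()
    )
    if remote:
        if not is_accession(token):
            raise GenomeError(f"{token!r} is not a valid assembly accession")
        fna = fetch_assembly(token, cache)
        return GenomeSource(path=fna, origin="ncbi_accession", accession=token)

    path = Path(token)
    if not path.exists():
        raise GenomeError(f"genome FASTA not found: {path}")
    if path.suffix == ".gz":
        path = _gunzip_to_cache(path, Path(cache_dir) if cache_dir else None)
    return GenomeSource(path=path)
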