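"""Primer candidate enumeration, pairing and ranking on junction templates.

The engine guarantees the circle-specificity contract: every reported
amplicon strictly contains the back-splice junction, so on the linear host
locus the pair is divergent and cannot amplify, while on the circular
isoform it converges across the junction.

Candidates are every template substring with length in the configured
window that passes GC, Tm, homopolymer, ambiguity and secondary-structure
screens; pairs are every forward/reverse combination with a product in the
size window, junction strictly inside, and Tm difference within bounds,
ranked by a Primer3-style penalty.
"""
from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass

from .genome import GenomeSource, reverse_complement, subsequence
from .junction import JunctionTemplate
from .records import CircRecord
from .thermo import gc_content, melting_temperature

_VALID = frozenset("ACGT")


@dataclass
class DesignConfig:
    """All design parameters with their defaults.

    Lengths are in nucleotides, temperatures in °C, concentrations in
    mol/L. Penalty weights follow common primer-design practice:
    ``w_len`` per nt from the optimum length, ``w_tm`` per °C from the
    optimum Tm, ``w_gc`` per unit fraction from 50% GC, ``w_diff`` per °C
    of pair Tm difference.
    """

    shift_left: int = 150
    shift_right: int = 150
    opt_len: int = 19
    min_len: int = 15
    max_len: int = 20
    product_min: int = 150
    product_max: int = 200
    tm_opt: float = 60.0
    tm_min: float = 57.0
    tm_max: float = 63.0
    max_tm_diff: float = 3.0
    n_sets: int = 4
    primer_conc: float = 50e-9
    monovalent_salt: float = 0.05
    gc_min: float = 0.20
    gc_max: float = 0.80
    max_homopolymer: int = 4
    w_len: float = 1.0
    w_tm: float = 1.0
    w_gc: float = 10.0
    w_diff: float = 0.5
    dimer_max: int = 8
    dimer3_max: int = 4
    hairpin_stem_max: int = 4
    max_linear_product: int = 5000
    primer_on_junction: bool = True

    def __post_init__(self):
        if not (1 <= self.min_len <= self.opt_len <= self.max_len):
            raise ValueError("need min_len <= opt_len <= max_len")
        if self.product_min > self.product_max:
            raise ValueError("need product_min <= product_max")
        if not (self.tm_min <= self.tm_opt <= self.tm_max):
            raise ValueError("need tm_min <= tm_opt <= tm_max")
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if self.shift_left < 1 or self.shift_right < 1:
            raise ValueError("shift ranges must be >= 1")


@dataclass(frozen=True)
class PrimerCandidate:
    """A single oligo, 5'→3', with its template binding site and scores.

    ``template_start`` is the 0-based start of the binding site on the
    template for both orientations; a reverse candidate's ``sequence`` is
    the reverse complement of the binding site.
    """

    sequence: str
    template_start: int
    length: int
    orientation: str  # "forward" | "reverse"
    tm: float
    gc: float
    self_dimer_score: int
    hairpin_score: int
    penalty: float

    @property
    def template_end(self) -> int:
        return self.template_start + self.length


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse pair with its amplicon on the template."""

    forward: PrimerCandidate
    reverse: PrimerCandidate
    product_start: int
    product_end: int
    product_size: int
    spans_junction: bool
    tm_diff: float
    pair_penalty: float
    specificity: str = "untested"  # "pass" | "fail:<reason>" | "untested"


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run > best:
            best = run
    return best if seq else 0


def self_dimer_scores(seq: str) -> tuple[int, int]:
    """(overall, 3'-anchored) self-dimer scores.

    Overall: the maximum number of Watson–Crick matches over all ungapped
    antiparallel offsets of the oligo against a second copy of itself —
    computed as identity matches between ``seq`` and its own reverse
    complement at every offset. 3'-anchored: the longest run of
    consecutive matches ending at the oligo's 3' terminal base, over the
    same offsets.
    """
    rc = reverse_complement(seq)
    n = len(seq)
    best_total = 0
    best_3p = 0
    for offset in range(-(n - 1), n):
        total = 0
        for i in range(n):
            j = i + offset
            if 0 <= j < n and seq[i] == rc[j]:
                total += 1
        if total > best_total:
            best_total = total
        # run of consecutive matches ending at seq's 3' end (i = n-1)
        run = 0
        i = n - 1
        while i >= 0 and 0 <= i + offset < n and seq[i] == rc[i + offset]:
            run += 1
            i -= 1
        if run > best_3p:
            best_3p = run
    return best_total, best_3p


_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def hairpin_stem(seq: str, min_loop: int = 3) -> int:
    """Longest self-complementary stem with a loop of ≥ ``min_loop`` nt."""
    n = len(seq)
    best = 0
    for a in range(n):
        for b in range(n - 1, a + min_loop, -1):
            k = 0
            while (
                a + k < b - k
                and (b - k) - (a + k) - 1 >= min_loop
                and (seq[a + k], seq[b - k]) in _PAIRS
            ):
                k += 1
            if k > best:
                best = k
    return best


def structure_screens(seq: str) -> tuple[int, int]:
    """(self_dimer_score, hairpin_score) for a primer sequence."""
    overall, _ = self_dimer_scores(seq)
    return overall, hairpin_stem(seq)


def _evaluate(seq: str, start: int, orientation: str, cfg: DesignConfig):
    """Screen one oligo; return a PrimerCandidate or None.

    Filters are ordered cheap-first (alphabet, homopolymer, GC, Tm) with
    the O(n²)/O(n³) structure screens last, which keeps exhaustive window
    enumeration fast.
    """
    if not _VALID.issuperset(seq):
        return None
    if max_homopolymer_run(seq) > cfg.max_homopolymer:
        return None
    gc = gc_content(seq)
    if not (cfg.gc_min <= gc <= cfg.gc_max):
        return None
    tm = melting_temperature(seq, cfg.primer_conc, cfg.monovalent_salt)
    if not (cfg.tm_min <= tm <= cfg.tm_max):
        return None
    dimer, dimer3 = self_dimer_scores(seq)
    if dimer > cfg.dimer_max or dimer3 > cfg.dimer3_max:
        return None
    stem = hairpin_stem(seq)
    if stem > cfg.hairpin_stem_max:
        return None
    penalty = (
        cfg.w_len * abs(len(seq) - cfg.opt_len)
        + cfg.w_tm * abs(tm - cfg.tm_opt)
        + cfg.w_gc * abs(gc - 0.5)
    )
    return PrimerCandidate(
        sequence=seq,
        template_start=start,
        length=len(seq),
        orientation=orientation,
        tm=tm,
        gc=gc,
        self_dimer_score=dimer,
        hairpin_score=stem,
        penalty=penalty,
    )


def enumerate_candidates(
    template: JunctionTemplate, cfg: DesignConfig
) -> tuple[list[PrimerCandidate], list[PrimerCandidate]]:
    """All passing forward and reverse candidates on a template.

    Forward candidates read the template strand; reverse candidates are
    the reverse complement of their binding site. Unless
    ``cfg.primer_on_junction``, candidates overlapping the junction point
    are excluded (by default only the *product* must contain it).
    """
    seq = template.sequence
    n = len(seq)
    j = template.junction_index
    fwd: list[PrimerCandidate] = []
    rev: list[PrimerCandidate] = []
    for start in range(n - cfg.min_len + 1):
        for length in range(cfg.min_len, cfg.max_len + 1):
            end = start + length
            if end > n:
                break
            if not cfg.primer_on_junction and start < j < end:
                continue
            window = seq[start:end]
            cand = _evaluate(window, start, "forward", cfg)
            if cand is not None:
                fwd.append(cand)
            rc = reverse_complement(window)
            cand = _evaluate(rc, start, "reverse", cfg)
            if cand is not None:
                rev.append(cand)
    return fwd, rev


def pair_and_rank(
    fwd: list[PrimerCandidate],
    rev: list[PrimerCandidate],
    template: JunctionTemplate,
    cfg: DesignConfig,
) -> list[PrimerPair]:
    """Valid junction-spanning pairs, ranked; at most ``cfg.n_sets``.

    A pair is valid when the product ``[f.start, r.end)`` has size within
    the window, strictly contains the junction, the primers do not
    overlap, and |ΔTm| ≤ ``max_tm_diff``. Ranking is by
    ``pair_penalty = f.penalty + r.penalty + w_diff·tm_diff`` with ties
    broken by (penalty, product_start, forward sequence).
    """
    j = template.junction_index
    rev_sorted = sorted(rev, key=lambda r: r.template_end)
    rev_ends = [r.template_end for r in rev_sorted]
    pairs: list[PrimerPair] = []
    for f in fwd:
        lo = bisect_left(rev_ends, f.template_start + cfg.product_min)
        hi = bisect_right(rev_ends, f.template_start + cfg.product_max)
        for r in rev_sorted[lo:hi]:
            p_start, p_end = f.template_start, r.template_end
            if r.template_start < f.template_end:
                continue  # overlapping primers
            if not (p_start < j < p_end):
                continue
            tm_diff = abs(f.tm - r.tm)
            if tm_diff > cfg.max_tm_diff:
                continue
            pairs.append(
                PrimerPair(
                    forward=f,
                    reverse=r,
                    product_start=p_start,
                    product_end=p_end,
                    product_size=p_end - p_start,
                    spans_junction=True,
                    tm_diff=tm_diff,
                    pair_penalty=f.penalty + r.penalty + cfg.w_diff * tm_diff,
                )
            )
    pairs.sort(
        key=lambda p: (p.pair_penalty, p.product_start, p.forward.sequence,
                       p.reverse.sequence)
    )
    return pairs[: cfg.n_sets]


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def linear_specificity_check(
    pair: PrimerPair,
    record: CircRecord,
    genome: GenomeSource,
    max_linear_product: int = 5000,
) -> tuple[bool, str]:
    """In-silico PCR of the pair against the linear genomic locus.

    Both primers are exact-matched on both strands of the window
    ``record ± max_linear_product``. The pair passes iff no convergent
    placement (a right-pointing site upstream of a left-pointing site)
    yields a linear product ≤ ``max_linear_product``. Junction-spanning
    pairs are divergent on the linear locus by construction, so a failure
    indicates a repeat-mediated secondary site.
    """
    chrom = record.chrom
    n = genome.length(chrom)
    w_start = max(0, record.start - max_linear_product)
    w_end = min(n, record.end + max_linear_product)
    window = subsequence(genome, chrom, w_start, w_end, "+")

    oligos = {pair.forward.sequence, pair.reverse.sequence}
    plus_sites: list[tuple[int, int]] = []  # (pos, len), primer points right
    minus_sites: list[tuple[int, int]] = []  # (pos, len), primer points left
    any_hit = False
    for oligo in oligos:
        for pos in _find_all(window, oligo):
            plus_sites.append((pos, len(oligo)))
            any_hit = True
        for pos in _find_all(window, reverse_complement(oligo)):
            minus_sites.append((pos, len(oligo)))
            any_hit = True
    if not any_hit:
        return True, "no exact primer matches in the linear window"

    for p_pos, _p_len in plus_sites:
        for m_pos, m_len in minus_sites:
            if m_pos >= p_pos and (m_pos + m_len) - p_pos <= max_linear_product:
                return False, (
                    f"convergent linear product of "
                    f"{(m_pos + m_len) - p_pos} nt at window offset {p_pos}"
                )
    return True, "divergent on the linear locus"


def design_primers(
    template: JunctionTemplate, cfg: DesignConfig | None = None
) -> list[PrimerPair]:
    """Convenience: enumerate, pair and rank on one template."""
    cfg = cfg or DesignConfig()
    fwd, rev = enumerate_candidates(template, cfg)
    return pair_and_rank(fwd, rev, template, cfg)
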