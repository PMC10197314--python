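"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity by a different route from the production
code (explicit full tables, exhaustive enumeration, naive string search)
so agreement is evidence, not tautology.
"""
from __future__ import annotations

import math
from itertools import groupby

# --- nearest-neighbor Tm, full explicit 16-entry table -------------------
# Unified DNA/DNA parameters (kcal/mol, cal/mol/K), every dinucleotide
# written out rather than folded through reverse complements.
NN_FULL = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}

COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def revcomp(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def tm_oracle(seq: str, primer_conc: float = 50e-9, salt: float = 0.05) -> float:
    """NN duplex Tm by direct summation over the explicit table."""
    dh = sum(NN_FULL[seq[i : i + 2]][0] for i in range(len(seq) - 1))
    ds = sum(NN_FULL[seq[i : i + 2]][1] for i in range(len(seq) - 1))
    for term in (seq[0], seq[-1]):
        if term in "GC":
            dh += 0.1
            ds += -2.8
        else:
            dh += 2.3
            ds += 4.1
    ds += 0.368 * (len(seq) - 1) * math.log(salt)
    return dh * 1000.0 / (ds + 1.987 * math.log(primer_conc / 4.0)) - 273.15


# --- structure screens ----------------------------------------------------

def _wc(a: str, b: str) -> bool:
    return COMP.get(a) == b


def dimer_oracle(seq: str) -> tuple[int, int]:
    """(overall, 3'-anchored) self-dimer scores.

    Two antiparallel copies: base i of one copy pairs with base j of the
    other whenever i + j is constant along the alignment. Enumerate every
    diagonal d = i + j.
    """
    n = len(seq)
    best_total = best_3p = 0
    for d in range(2 * n - 1):
        total = sum(
            1 for i in range(n) if 0 <= d - i < n and _wc(seq[i], seq[d - i])
        )
        best_total = max(best_total, total)
        run = 0
        i = n - 1
        while i >= 0 and 0 <= d - i < n and _wc(seq[i], seq[d - i]):
            run += 1
            i -= 1
        best_3p = max(best_3p, run)
    return best_total, best_3p


def hairpin_oracle(seq: str, min_loop: int = 3) -> int:
    """Longest hairpin stem by exhaustive substring/revcomp comparison."""
    n = len(seq)
    for stem in range(n // 2, 0, -1):
        for i in range(n - 2 * stem - min_loop + 1):
            for j in range(i + stem + min_loop, n - stem + 1):
                if seq[i : i + stem] == revcomp(seq[j : j + stem]):
                    return stem
    return 0


# --- candidate filtering --------------------------------------------------

def homopolymer_oracle(seq: str) -> int:
    return max(len(list(g)) for _, g in groupby(seq))


def passes_filters_oracle(seq: str, cfg) -> bool:
    """Independent re-application of every candidate screen."""
    if set(seq) - set("ACGT"):
        return False
    if homopolymer_oracle(seq) > cfg.max_homopolymer:
        return False
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    if not (cfg.gc_min <= gc <= cfg.gc_max):
        return False
    tm = tm_oracle(seq, cfg.primer_conc, cfg.monovalent_salt)
    if not (cfg.tm_min <= tm <= cfg.tm_max):
        return False
    overall, tail3 = dimer_oracle(seq)
    if overall > cfg.dimer_max or tail3 > cfg.dimer3_max:
        return False
    if hairpin_oracle(seq) > cfg.hairpin_stem_max:
        return False
    return True


def count_candidates_oracle(template_seq: str, cfg) -> tuple[int, int]:
    """(n_forward, n_reverse) by exhaustive window enumeration."""
    n = len(template_seq)
    n_fwd = n_rev = 0
    for start in range(n):
        for length in range(cfg.min_len, cfg.max_len + 1):
            if start + length > n:
                break
            window = template_seq[start : start + length]
            if passes_filters_oracle(window, cfg):
                n_fwd += 1
            if passes_filters_oracle(revcomp(window), cfg):
                n_rev += 1
    return n_fwd, n_rev


# --- pairing --------------------------------------------------------------

def valid_pairs_oracle(fwd, rev, junction_index: int, cfg) -> set[tuple]:
    """All valid (forward, reverse) combos by a plain double loop."""
    out = set()
    for f in fwd:
        for r in rev:
            size = (r.template_start + r.length) - f.template_start
            if not (cfg.product_min <= size <= cfg.product_max):
                continue
            if r.template_start < f.template_start + f.length:
                continue
            if not (f.template_start < junction_index < r.template_start + r.length):
                continue
            if abs(f.tm - r.tm) > cfg.max_tm_diff:
                continue
            out.add((f.sequence, f.template_start, r.sequence, r.template_start))
    return out


# --- in-silico PCR --------------------------------------------------------

def convergent_products_oracle(window: str, oligos, max_product: int) -> list[int]:
    """Every convergent linear product size by naive string scanning."""
    plus, minus = [], []
    for oligo in set(oligos):
        for i in range(len(window) - len(oligo) + 1):
            if window[i : i + len(oligo)] == oligo:
                plus.append((i, len(oligo)))
            if window[i : i + len(oligo)] == revcomp(oligo):
                minus.append((i, len(oligo)))
    sizes = []
    for p, _pl in plus:
        for m, ml in minus:
            if m >= p and (m + ml) - p <= max_product:
                sizes.append((m + ml) - p)
    return sorted(sizes)
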