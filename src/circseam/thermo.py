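"""Oligonucleotide thermodynamics: GC content and nearest-neighbor Tm.

The melting temperature model is the unified nearest-neighbor DNA/DNA
parameter set (SantaLucia 1998): per-dinucleotide ΔH°/ΔS° stacking terms
plus terminal-base initiation terms, an entropic monovalent-salt
correction of 0.368·(N−1)·ln[Na+] cal/(mol·K), and

    Tm(K) = ΔH° · 1000 / (ΔS° + R · ln(CT / 4))

for a non-self-complementary primer in excess over template (R = 1.987
cal/(mol·K), CT the total oligo concentration). Defaults are 50 nM primer
and 50 mM monovalent salt.
"""
from __future__ import annotations

import math

from .genome import reverse_complement

R_GAS = 1.987  # cal/(mol*K)

# Unified NN parameters, 5'->3' dinucleotide on one strand:
# (delta_H kcal/mol, delta_S cal/(mol*K))
NN_PARAMS = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
# Initiation terms keyed by terminal base.
INIT_GC = (0.1, -2.8)
INIT_AT = (2.3, 4.1)

_VALID = frozenset("ACGT")


def _check_seq(seq: str, min_len: int = 1) -> None:
    if len(seq) < min_len:
        raise ValueError(f"sequence too short ({len(seq)} < {min_len})")
    if not _VALID.issuperset(seq):
        bad = sorted(set(seq) - _VALID)
        raise ValueError(f"ambiguous or invalid bases {bad} in sequence")


def gc_content(seq: str) -> float:
    """Fraction of G+C bases; raises on empty or ambiguous input."""
    _check_seq(seq, 1)
    return (seq.count("G") + seq.count("C")) / len(seq)


def duplex_dh_ds(seq: str) -> tuple[float, float]:
    """Total ΔH° (kcal/mol) and ΔS° (cal/mol·K) of the perfect duplex."""
    dh, ds = 0.0, 0.0
    for i in range(len(seq) - 1):
        dinuc = seq[i : i + 2]
        if dinuc not in NN_PARAMS:
            dinuc = reverse_complement(dinuc)
        h, s = NN_PARAMS[dinuc]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = INIT_GC if terminal in "GC" else INIT_AT
        dh += h
        ds += s
    return dh, ds


def melting_temperature(
    seq: str,
    primer_conc: float = 50e-9,
    monovalent_salt: float = 0.05,
) -> float:
    """Nearest-neighbor duplex Tm in °C for a primer vs. its complement.

    Parameters
    ----------
    seq : str
        Primer sequence 5'→3', {A,C,G,T} only, length ≥ 8.
    primer_conc : float
        Total oligo concentration in mol/L (default 50 nM).
    monovalent_salt : float
        Monovalent cation concentration in mol/L (default 50 mM).
    """
    _check_seq(seq, 8)
    if primer_conc <= 0 or monovalent_salt <= 0:
        raise ValueError("concentrations must be positive")
    dh, ds = duplex_dh_ds(seq)
    ds += 0.368 * (len(seq) - 1) * math.log(monovalent_salt)
    tm_kelvin = dh * 1000.0 / (ds + R_GAS * math.log(primer_conc / 4.0))
    return tm_kelvin - 273.15
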