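"""Thermocycling condition recommendations per primer pair.

Bench-standard heuristics: annealing at 3 °C below the lower primer Tm,
extension at 30 s per started kb (minimum 30 s), 35 cycles, 95 °C
denaturation. The offset and per-kb rate are configurable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .primers import PrimerPair


@dataclass(frozen=True)
class PcrConditions:
    annealing_temp: float  # °C
    extension_time: int  # seconds
    cycles: int
    denaturation_temp: float  # °C

    def __post_init__(self):
        assert self.extension_time >= 30


def recommend_conditions(
    pair: PrimerPair, ta_offset: float = 3.0, ext_per_kb: int = 30
) -> PcrConditions:
    """Recommend cycling conditions for one pair.

    Annealing = min(Tm_f, Tm_r) − ``ta_offset``, rounded to 0.1 °C;
    extension = max(30, ceil(product/1000)·``ext_per_kb``) seconds.
    """
    ta = round(min(pair.forward.tm, pair.reverse.tm) - ta_offset, 1)
    ext = max(30, math.ceil(pair.product_size / 1000) * ext_per_kb)
    return PcrConditions(
        annealing_temp=ta,
        extension_time=ext,
        cycles=35,
        denaturation_temp=95.0,
    )
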