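"""Small shared helpers."""

from __future__ import annotations

import math

UND = "UND"

GENES = ("CYP2C9", "CYP2C19", "CYP2D6", "CYP3A5", "VKORC1")
GROUPS = ("Malay", "Indian", "Chinese")

CALLS = ("hom_ref", "het", "hom_var", "undetermined")


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Round with ties going away from zero (the convention of the
    frequency tables), unlike the banker's rounding of ``round``/numpy."""
    if x != x:  # NaN
        return x
    scale = 10.0**ndigits
    if x >= 0:
        return math.floor(x * scale + 0.5) / scale
    return -math.floor(-x * scale + 0.5) / scale
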