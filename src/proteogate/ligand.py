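"""Idealized charge geometry of tetra-cationic meso-substituted porphyrins.

A planar, four-fold symmetric (D4h-idealized) porphyrin carries one cationic
pyridinium arm at each meso position.  The four charges therefore sit at the
corners of a square; what matters for matching an anionic protein site is the
radial center-to-charge distance and, from it, the adjacent (side) and
diagonal charge spacings.

Each arm is a chain of rigid fragments along the meso axis:

    porphyrin center --(r_meso)--> meso carbon
    --(single bond)--> [para-phenylene spacer --(single bond)-->] * k
    --> pyridine ipso carbon --(ring span)--> para nitrogen (the cation)

The fragment lengths are standard design values for aromatic systems:

    R_MESO   = 3.45 Å   porphyrin center to meso carbon
    B_MESO   = 1.49 Å   meso carbon to first ring (biaryl single bond)
    D_PARA   = 2.78 Å   para-phenylene C1–C4 span
    B_RING   = 1.48 Å   ring–ring single bond
    D_PYR    = 2.79 Å   pyridine ipso-C to para-N span

With no spacer ring (the parent tetra(N-methylpyridyl)porphyrin) the adjacent
charge spacing evaluates to ~11 Å; a single para-phenylene spacer per arm
(the phenyl-pyridyl analogue) stretches it to ~17 Å, matching the wider
carboxylate clusters of the proteasome alpha-ring grooves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ArmSpec",
    "radial_charge_distance",
    "adjacent_charge_spacing",
    "diagonal_charge_spacing",
    "R_MESO",
    "B_MESO",
    "D_PARA",
    "B_RING",
    "D_PYR",
]

R_MESO = 3.45
B_MESO = 1.49
D_PARA = 2.78
B_RING = 1.48
D_PYR = 2.79


@dataclass(frozen=True)
class ArmSpec:
    """One meso arm: ``spacer_rings`` para-phenylene units before the pyridinium."""

    spacer_rings: int = 0

    def __post_init__(self) -> None:
        if self.spacer_rings < 0:
            raise ValueError("spacer_rings must be >= 0")


def radial_charge_distance(arm: ArmSpec) -> float:
    """Distance (Å) from the porphyrin center to the cationic para nitrogen."""
    return R_MESO + B_MESO + arm.spacer_rings * (D_PARA + B_RING) + D_PYR


def adjacent_charge_spacing(arm: ArmSpec) -> float:
    """Side of the square of four charges: ``radial · sqrt(2)`` (Å)."""
    return radial_charge_distance(arm) * math.sqrt(2.0)


def diagonal_charge_spacing(arm: ArmSpec) -> float:
    """Diagonal of the charge square: ``2 · radial`` (Å)."""
    return 2.0 * radial_charge_distance(arm)
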