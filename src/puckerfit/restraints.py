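"""Flat-well restraint bookkeeping.

Energies are zero on a flat interval with one-sided quadratic walls, the
form used for terminal-base-pair hydrogen-bond distance restraints
(flat 2.5-3.2 A, k = 20 kcal/(mol.A^2) below and 30 kcal/(mol.A^2) above)
and for keeping the glycosidic torsion chi in the anti region
(zero on [160, 310] deg, 10 kcal/(mol.rad^2) outside, evaluated through
the shorter angular path).  No forces: these are analysis/bookkeeping
functions, not an MD engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FlatWell",
    "flat_well_energy",
    "chi_well_energy",
    "TERMINAL_HBOND_WELL",
    "CHI_ANTI_WELL",
]


@dataclass(frozen=True)
class FlatWell:
    """Flat-bottomed well: zero on [lower_flat, upper_flat], quadratic walls.

    Force constants are in kcal/(mol.unit^2) where unit matches the
    coordinate (A for distances, radians for the chi well).
    """

    lower_flat: float
    upper_flat: float
    k_lower: float
    k_upper: float

    def __post_init__(self) -> None:
        if self.lower_flat > self.upper_flat:
            raise ValueError("lower_flat must not exceed upper_flat")
        if self.k_lower < 0 or self.k_upper < 0:
            raise ValueError("force constants must be nonnegative")


#: terminal base-pair H-bond heavy-atom distance well (A)
TERMINAL_HBOND_WELL = FlatWell(lower_flat=2.5, upper_flat=3.2, k_lower=20.0, k_upper=30.0)

#: glycosidic-torsion anti-region well (degrees; penalty per rad^2)
CHI_ANTI_WELL = FlatWell(lower_flat=160.0, upper_flat=310.0, k_lower=10.0, k_upper=10.0)


def flat_well_energy(x: float | np.ndarray, well: FlatWell) -> float | np.ndarray:
    """Energy (kcal/mol) of a linear coordinate in a flat-bottomed well.

    Zero inside [lower_flat, upper_flat]; k_lower*(lower-x)^2 below,
    k_upper*(x-upper)^2 above.  Continuous and C^1 at both walls.
    """
    x = np.asarray(x, dtype=float)
    below = np.where(x < well.lower_flat, well.k_lower * (well.lower_flat - x) ** 2, 0.0)
    above = np.where(x > well.upper_flat, well.k_upper * (x - well.upper_flat) ** 2, 0.0)
    out = below + above
    return float(out) if out.ndim == 0 else out


def chi_well_energy(chi: float | np.ndarray, well: FlatWell = CHI_ANTI_WELL) -> float | np.ndarray:
    """Energy (kcal/mol) of an angular flat well on the wrapped angle.

    The well is defined in degrees; outside the flat region the excursion
    to the NEAREST wall is measured through the shorter angular path and
    penalized quadratically in radians (k in kcal/(mol.rad^2)).  The flat
    interval is closed: both edges are exactly zero.
    """
    chi = np.asarray(chi, dtype=float) % 360.0

    def _shorter(delta_deg):
        # smallest absolute angular separation, degrees in [0, 180]
        d = np.abs((delta_deg + 180.0) % 360.0 - 180.0)
        return d

    inside = (chi >= well.lower_flat) & (chi <= well.upper_flat)
    d_lower = _shorter(chi - well.lower_flat)
    d_upper = _shorter(chi - well.upper_flat)
    d = np.minimum(d_lower, d_upper)
    k = np.where(d_lower <= d_upper, well.k_lower, well.k_upper)
    out = np.where(inside, 0.0, k * np.radians(d) ** 2)
    return float(out) if out.ndim == 0 else out
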