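"""Furanose pseudorotation algebra and backbone-angle extraction.

The five endocyclic deoxyribose torsions nu0..nu4 are summarized by the
pseudorotation phase ``P`` and amplitude ``tau_m`` (Altona-Sundaralingam).
North (N, C3'-endo) sugars characterize A-form nucleotides, south
(S, C2'-endo) sugars B-form ones.  This module converts between ring
torsions and ``(P, tau_m)``, classifies puckers, produces the constrained
pseudorotation-scan targets used in torsion-parameter derivation, and
extracts ring/backbone/glycosidic angles from PDB coordinates.

Conventions
-----------
* nu0 = C4'-O4'-C1'-C2', nu1 = O4'-C1'-C2'-C3', nu2 = C1'-C2'-C3'-C4',
  nu3 = C2'-C3'-C4'-O4', nu4 = C3'-C4'-O4'-C1'.
* nu_j = tau_m * cos(P + (j - 2) * 144 deg), hence nu2 = tau_m * cos(P).
* Raw torsions are reported in [-180, 180); backbone angles and P in
  [0, 360).  Wrapping is always explicit (`wrap180`, `wrap360`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RingTorsions",
    "PuckerState",
    "BackboneAngles",
    "DegenerateGeometryError",
    "PlanarRingError",
    "wrap180",
    "wrap360",
    "dihedral_angle",
    "pseudorotation",
    "ring_torsions_from_phase",
    "classify_pucker",
    "scan_targets",
    "scan_constraints",
    "read_pdb_residues",
    "angles_from_structure",
]

#: sin 36 deg + sin 72 deg, denominator constant of the phase formula
_SIN36_SIN72 = math.sin(math.radians(36.0)) + math.sin(math.radians(72.0))

#: default offset added to nu3 when deriving the delta backbone constraint
#: in a pseudorotation scan; calibrated once on the idealized B-form fixture
#: (delta - nu3 is 120.9 deg on the B-form and 122.1 deg on the A-form
#: fixture, i.e. nearly constant across the pseudorotation cycle for
#: standard exocyclic geometry).
DELTA_FROM_NU3_OFFSET = 120.9


class DegenerateGeometryError(ValueError):
    """Raised when a torsion is requested for (near-)collinear atoms."""


class PlanarRingError(ValueError):
    """Raised when a pseudorotation phase is requested for a planar ring."""


def wrap180(angle: float | np.ndarray) -> float | np.ndarray:
    """Wrap angle(s) in degrees to the interval [-180, 180)."""
    r = (np.asarray(angle) + 180.0) % 360.0
    # guard against floating modulo returning exactly 360.0 for tiny
    # negative inputs
    r = np.where(r >= 360.0, 0.0, r)
    return r - 180.0


def wrap360(angle: float | np.ndarray) -> float | np.ndarray:
    """Wrap angle(s) in degrees to the interval [0, 360)."""
    r = np.asarray(angle) % 360.0
    return np.where(r >= 360.0, 0.0, r)


@dataclass(frozen=True)
class RingTorsions:
    """The five endocyclic furanose torsions, degrees in [-180, 180)."""

    nu0: float
    nu1: float
    nu2: float
    nu3: float
    nu4: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("ring torsions must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.nu0, self.nu1, self.nu2, self.nu3, self.nu4])


@dataclass(frozen=True)
class PuckerState:
    """Pseudorotation phase P in [0, 360), amplitude tau_m >= 0, N/S class."""

    P: float
    tau_m: float
    pucker_class: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.P < 360.0):
            raise ValueError("P must lie in [0, 360)")
        if self.tau_m < 0.0:
            raise ValueError("tau_m must be nonnegative")
        if self.pucker_class not in ("N", "S"):
            raise ValueError("pucker_class must be 'N' or 'S'")


@dataclass
class BackboneAngles:
    """Backbone and glycosidic dihedrals of one nucleotide, deg in [0, 360).

    Terminal residues have no alpha (5') or epsilon/zeta (3'); those fields
    are NaN and listed in `missing`.
    """

    alpha: float
    beta: float
    gamma: float
    delta: float
    epsilon: float
    zeta: float
    chi: float
    chain: str = ""
    resseq: int = 0
    resname: str = ""
    missing: tuple[str, ...] = field(default_factory=tuple)


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion angle of four points, degrees in [-180, 180).

    Uses the IUPAC sign convention (positive = clockwise rotation of the
    far bond viewed from p2 towards p3).

    Raises
    ------
    DegenerateGeometryError
        If either atom triple is collinear (undefined torsion).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 * b2n or np.linalg.norm(n2) < 1e-10 * b2n:
        raise DegenerateGeometryError("collinear atom triple: torsion undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / b2n)
    return float(wrap180(math.degrees(math.atan2(y, x))))


def pseudorotation(rt: RingTorsions) -> PuckerState:
    """Compute the pseudorotation state from five ring torsions.

    ``P = atan2(((nu4+nu1)-(nu3+nu0)) / (2(sin36+sin72)), nu2)`` and
    ``tau_m = hypot`` of the two atan2 arguments, so the cos(P)=0 pole of
    the textbook tangent formula is avoided and tau_m is always >= 0.

    Raises
    ------
    PlanarRingError
        If all five torsions are (numerically) zero.
    """
    nu = rt.as_array()
    a = rt.nu2
    b = ((rt.nu4 + rt.nu1) - (rt.nu3 + rt.nu0)) / (2.0 * _SIN36_SIN72)
    tau_m = math.hypot(a, b)
    if tau_m < 1e-12 and np.all(np.abs(nu) < 1e-9):
        raise PlanarRingError("planar ring: pseudorotation phase undefined")
    P = float(wrap360(math.degrees(math.atan2(b, a))))
    return PuckerState(P=P, tau_m=tau_m, pucker_class=classify_pucker(P))


def ring_torsions_from_phase(P: float, tau_m: float) -> RingTorsions:
    """Inverse pseudorotation map: nu_j = tau_m * cos(P + (j-2)*144 deg)."""
    if tau_m < 0.0:
        raise ValueError("tau_m must be nonnegative")
    j = np.arange(5)
    nu = tau_m * np.cos(np.radians(P + (j - 2) * 144.0))
    nu = wrap180(nu)
    return RingTorsions(*[float(v) for v in nu])


def classify_pucker(P: float) -> str:
    """Classify a pseudorotation phase: 'N' iff wrapped P in (-90, 90).

    The boundaries +-90 deg classify S (strict inequality).
    """
    if not np.isfinite(P):
        raise ValueError("P must be finite")
    p = float(wrap180(P))
    # wrap180 maps +180 to -180; the test below is on the open interval
    return "N" if -90.0 < p < 90.0 else "S"


def scan_targets(start: float = 0.0, stop: float = 360.0, step: float = 10.0) -> np.ndarray:
    """Pseudorotation-scan grid [start, stop) at `step` intervals.

    Defaults give the 36 phases 0, 10, ..., 350 used for constrained
    conformer scans.  `step` must divide the range exactly.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    span = stop - start
    n = span / step
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"step {step} does not divide the range {span}")
    return start + step * np.arange(int(round(n)))


def scan_constraints(
    P: float,
    tau_m: float,
    tau1_offset: float = 0.0,
    delta_offset: float = DELTA_FROM_NU3_OFFSET,
    tau1_index: int = 1,
) -> tuple[float, float]:
    """Constrained values of the two scan dihedrals at phase ``P``.

    The scan dihedral tau1 is a ring torsion (default nu1,
    O4'-C1'-C2'-C3') taken directly from the inverse pseudorotation map
    plus ``tau1_offset``; delta (C5'-C4'-C3'-O3') is not a ring torsion
    but tracks nu3, so it is modeled as ``nu3 + delta_offset`` with a
    constant offset calibrated on idealized exocyclic geometry.

    Returns
    -------
    (tau1_value, delta_value) in degrees.
    """
    if tau_m <= 0.0:
        raise ValueError("tau_m must be positive")
    rt = ring_torsions_from_phase(P, tau_m)
    nus = rt.as_array()
    tau1 = float(nus[tau1_index]) + tau1_offset
    delta = float(rt.nu3) + delta_offset
    return tau1, delta


# ---------------------------------------------------------------------------
# structure input and per-residue angle extraction
# ---------------------------------------------------------------------------

_RING_TORSION_ATOMS = [
    ("C4'", "O4'", "C1'", "C2'"),  # nu0
    ("O4'", "C1'", "C2'", "C3'"),  # nu1
    ("C1'", "C2'", "C3'", "C4'"),  # nu2
    ("C2'", "C3'", "C4'", "O4'"),  # nu3
    ("C3'", "C4'", "O4'", "C1'"),  # nu4
]

_PURINES = {"DA", "DG", "A", "G", "ADE", "GUA", "RA", "RG"}
_PYRIMIDINES = {"DC", "DT", "C", "T", "U", "DU", "CYT", "THY", "URA", "RC", "RU"}


def read_pdb_residues(path, model: int = 0, altlocs: Sequence[str] = ("", " ", "A")):
    """Read residues from a PDB file into plain atom-coordinate records.

    Only ATOM/HETATM records are used; alternate locations other than
    blank or 'A' (configurable) are discarded; by default the first MODEL
    of a multi-model file is read.

    Returns
    -------
    list of dict with keys ``chain``, ``resseq``, ``resname``,
    ``atoms`` (name -> ndarray(3)).
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tolerate irregular fixture PDBs
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    models = list(structure)
    if model >= len(models):
        raise ValueError(f"model index {model} out of range ({len(models)} models)")
    out = []
    for chain in models[model]:
        for res in chain:
            atoms = {}
            for atom in res:
                if atom.get_altloc() not in altlocs:
                    continue
                atoms[atom.get_name()] = np.array(atom.get_coord(), dtype=float)
            if atoms:
                out.append(
                    {
                        "chain": chain.id,
                        "resseq": res.id[1],
                        "resname": res.get_resname().strip(),
                        "atoms": atoms,
                    }
                )
    return out


def _torsion_or_nan(atom_maps: Sequence[dict], names: Sequence[str]) -> float:
    """Torsion over four (atom-dict, name) pairs; NaN if missing/degenerate."""
    pts = []
    for amap, name in zip(atom_maps, names):
        if amap is None or name not in amap:
            return float("nan")
        pts.append(amap[name])
    try:
        return dihedral_angle(*pts)
    except DegenerateGeometryError:
        return float("nan")


def angles_from_structure(residues: Iterable[dict]) -> pd.DataFrame:
    """Ring, backbone and glycosidic angles for every nucleotide residue.

    Parameters
    ----------
    residues : iterable of dict
        Records as produced by `read_pdb_residues` (ordered 5'->3' within
        each chain).

    Returns
    -------
    DataFrame with one row per residue: chain, resseq, resname,
    alpha..zeta, chi (deg, [0, 360)), nu0..nu4 (deg, [-180, 180)),
    P, tau_m, pucker_class.  Residues missing a sugar-ring atom are
    skipped with a `UserWarning`; undefined terminal backbone angles are
    NaN.
    """
    residues = list(residues)
    rows = []
    for i, res in enumerate(residues):
        atoms = res["atoms"]
        prev_res = residues[i - 1] if i > 0 and residues[i - 1]["chain"] == res["chain"] else None
        next_res = (
            residues[i + 1]
            if i + 1 < len(residues) and residues[i + 1]["chain"] == res["chain"]
            else None
        )
        ring_names = {"O4'", "C1'", "C2'", "C3'", "C4'"}
        if not ring_names <= set(atoms):
            warnings.warn(
                f"residue {res['chain']}/{res['resseq']} {res['resname']}: "
                "missing sugar-ring atom, skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        nus = [dihedral_angle(*(atoms[n] for n in quad)) for quad in _RING_TORSION_ATOMS]
        try:
            state = pseudorotation(RingTorsions(*nus))
            P, tau_m, pclass = state.P, state.tau_m, state.pucker_class
        except PlanarRingError:
            P, tau_m, pclass = float("nan"), 0.0, ""

        prev_atoms = prev_res["atoms"] if prev_res else None
        next_atoms = next_res["atoms"] if next_res else None
        alpha = _torsion_or_nan(
            [prev_atoms, atoms, atoms, atoms], ["O3'", "P", "O5'", "C5'"]
        )
        beta = _torsion_or_nan([atoms] * 4, ["P", "O5'", "C5'", "C4'"])
        gamma = _torsion_or_nan([atoms] * 4, ["O5'", "C5'", "C4'", "C3'"])
        delta = _torsion_or_nan([atoms] * 4, ["C5'", "C4'", "C3'", "O3'"])
        epsilon = _torsion_or_nan(
            [atoms, atoms, atoms, next_atoms], ["C4'", "C3'", "O3'", "P"]
        )
        zeta = _torsion_or_nan(
            [atoms, atoms, next_atoms, next_atoms], ["C3'", "O3'", "P", "O5'"]
        )
        resname = res["resname"].upper()
        if resname in _PURINES:
            chi = _torsion_or_nan([atoms] * 4, ["O4'", "C1'", "N9", "C4"])
        elif resname in _PYRIMIDINES:
            chi = _torsion_or_nan([atoms] * 4, ["O4'", "C1'", "N1", "C2"])
        else:
            chi = float("nan")
        missing = tuple(
            name
            for name, val in zip(
                ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi"),
                (alpha, beta, gamma, delta, epsilon, zeta, chi),
            )
            if not np.isfinite(val)
        )
        rows.append(
            {
                "chain": res["chain"],
                "resseq": res["resseq"],
                "resname": res["resname"],
                "alpha": float(wrap360(alpha)),
                "beta": float(wrap360(beta)),
                "gamma": float(wrap360(gamma)),
                "delta": float(wrap360(delta)),
                "epsilon": float(wrap360(epsilon)),
                "zeta": float(wrap360(zeta)),
                "chi": float(wrap360(chi)),
                "nu0": nus[0],
                "nu1": nus[1],
                "nu2": nus[2],
                "nu3": nus[3],
                "nu4": nus[4],
                "P": P,
                "tau_m": tau_m,
                "pucker_class": pclass,
                "missing": ",".join(missing),
            }
        )
    return pd.DataFrame(rows)
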