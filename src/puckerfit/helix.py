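"""Base-pair reference frames and helical parameter algebra.

Base frames are obtained by least-squares superposition of standard-
reference-frame base geometries (Olson convention) onto observed base
ring atoms.  Intra-pair (shear..opening), step (shift..twist) and helical
(x-displacement, inclination, tip, hrise, htwist) parameters follow the
mid-frame (CEHS/3DNA-style) construction: the two triads are symmetrically
rotated onto their common hinge so that translations are read in the
mid-triad and the bend angle splits into roll/tilt (or the helical-axis
analogues).  Groove widths are cross-strand phosphorus separations in the
El Hassan-Calladine convention with a 5.8 A phosphate-radius correction.

Inclination and x-displacement are the primary monitors that separate
A-form (about +20 deg, -5 A) from B-form (about +1.5 deg, 0 A) duplexes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import pucker as _pucker

__all__ = [
    "BaseFrame",
    "PairParameters",
    "StepParameters",
    "HelicalParameters",
    "STANDARD_BASES",
    "base_frame",
    "flip_frame",
    "frames_to_params",
    "params_to_frames",
    "mid_frame",
    "pair_parameters",
    "step_parameters",
    "helical_parameters",
    "helical_frames",
    "groove_widths",
    "duplex_report",
    "superpose_rmsd",
]

# ---------------------------------------------------------------------------
# standard reference-frame base geometries (Olson convention), Angstrom.
# Coordinates are expressed IN the standard base frame, so the rigid
# transform that superposes them onto an observed base IS that base's frame.
# ---------------------------------------------------------------------------

STANDARD_BASES: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "C1'": (-2.479, 5.346, 0.000),
        "N9": (-1.291, 4.498, 0.000),
        "C8": (0.024, 4.897, 0.000),
        "N7": (0.877, 3.902, 0.000),
        "C5": (0.071, 2.771, 0.000),
        "C6": (0.369, 1.398, 0.000),
        "N6": (1.611, 0.909, 0.000),
        "N1": (-0.668, 0.532, 0.000),
        "C2": (-1.912, 1.023, 0.000),
        "N3": (-2.320, 2.290, 0.000),
        "C4": (-1.267, 3.124, 0.000),
    },
    "G": {
        "C1'": (-2.477, 5.399, 0.000),
        "N9": (-1.289, 4.551, 0.000),
        "C8": (0.023, 4.962, 0.000),
        "N7": (0.870, 3.969, 0.000),
        "C5": (0.071, 2.833, 0.000),
        "C6": (0.424, 1.460, 0.000),
        "O6": (1.554, 0.955, 0.000),
        "N1": (-0.700, 0.641, 0.000),
        "C2": (-1.999, 1.087, 0.000),
        "N2": (-2.949, 0.139, -0.001),
        "N3": (-2.342, 2.364, 0.001),
        "C4": (-1.265, 3.177, 0.000),
    },
    "C": {
        "C1'": (-2.477, 5.402, 0.000),
        "N1": (-1.285, 4.542, 0.000),
        "C2": (-1.472, 3.158, 0.000),
        "O2": (-2.628, 2.709, 0.001),
        "N3": (-0.391, 2.344, 0.000),
        "C4": (0.837, 2.868, 0.000),
        "N4": (1.875, 2.027, 0.001),
        "C5": (1.056, 4.275, 0.000),
        "C6": (-0.023, 5.068, 0.000),
    },
    "T": {
        "C1'": (-2.481, 5.354, 0.000),
        "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.135, 0.000),
        "O2": (-2.562, 2.608, 0.000),
        "N3": (-0.298, 2.407, 0.000),
        "C4": (1.024, 2.792, 0.000),
        "O4": (1.855, 1.881, 0.000),
        "C5": (1.141, 4.230, 0.000),
        "C7": (2.466, 4.709, 0.000),
        "C6": (0.024, 4.970, 0.000),
    },
}

#: ring atoms used for superposition (C1' included to pin the glycosidic end)
_FRAME_ATOMS = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "T": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

_RESNAME_TO_BASE = {
    "DA": "A", "A": "A", "ADE": "A",
    "DG": "G", "G": "G", "GUA": "G",
    "DC": "C", "C": "C", "CYT": "C",
    "DT": "T", "T": "T", "THY": "T", "U": "T", "DU": "T",
}

_FLIP = np.diag([1.0, -1.0, -1.0])


@dataclass(frozen=True)
class BaseFrame:
    """Right-handed orthonormal triad (columns x, y, z) plus origin (A)."""

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        axes = np.asarray(self.axes, dtype=float)
        if abs(np.linalg.det(axes) - 1.0) > 1e-9:
            raise ValueError("axes must be a proper rotation (det = 1)")
        if np.max(np.abs(axes.T @ axes - np.eye(3))) > 1e-9:
            raise ValueError("axes must be orthonormal")
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "axes", axes)

    @property
    def x(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[:, 2]


@dataclass(frozen=True)
class PairParameters:
    shear: float
    stretch: float
    stagger: float
    buckle: float
    propeller: float
    opening: float


@dataclass(frozen=True)
class StepParameters:
    shift: float
    slide: float
    rise: float
    tilt: float
    roll: float
    twist: float


@dataclass(frozen=True)
class HelicalParameters:
    x_displacement: float
    y_displacement: float
    hrise: float
    inclination: float
    tip: float
    htwist: float


# ---------------------------------------------------------------------------
# small rotation helpers
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def _rot(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about `axis` by `angle_deg` (right-hand rule)."""
    a = _unit(np.asarray(axis, dtype=float))
    t = math.radians(angle_deg)
    c, s = math.cos(t), math.sin(t)
    x, y, z = a
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) * c + s * K + (1 - c) * np.outer(a, a)


def _signed_angle(a: np.ndarray, b: np.ndarray, ref: np.ndarray) -> float:
    """Angle from a to b (deg, [-180, 180)) about reference direction."""
    a, b, ref = _unit(a), _unit(b), _unit(ref)
    return float(
        _pucker.wrap180(
            math.degrees(math.atan2(float(np.dot(np.cross(a, b), ref)), float(np.dot(a, b))))
        )
    )


def _kabsch(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t with R @ moving + t ~ target."""
    mc, tc = moving.mean(axis=0), target.mean(axis=0)
    H = (moving - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = tc - R @ mc
    return R, t


def superpose_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Plain coordinate RMSD (A) of two equal-size sets after superposition."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    R, t = _kabsch(a, b)
    moved = a @ R.T + t
    return float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# base frames
# ---------------------------------------------------------------------------


def base_frame(atoms: dict, resname: str) -> BaseFrame:
    """Reference frame of one base from its observed ring atoms.

    The standard base geometry (expressed in its own reference frame) is
    rigidly superposed onto the observed ring atoms; the fitted transform
    is the base frame.  At least three ring atoms must be present.
    """
    base = _RESNAME_TO_BASE.get(resname.strip().upper())
    if base is None:
        raise ValueError(f"unsupported residue name {resname!r}")
    std = STANDARD_BASES[base]
    names = [n for n in _FRAME_ATOMS[base] if n in atoms]
    if len(names) < 3:
        raise ValueError(f"need >=3 base ring atoms, found {len(names)}")
    obs = np.array([atoms[n] for n in names], dtype=float)
    ref = np.array([std[n] for n in names], dtype=float)
    R, t = _kabsch(ref, obs)
    return BaseFrame(origin=t, axes=R)


def flip_frame(f: BaseFrame) -> BaseFrame:
    """Negate the y and z axes (strand-2 base before pairing)."""
    return BaseFrame(origin=f.origin, axes=f.axes @ _FLIP)


# ---------------------------------------------------------------------------
# CEHS mid-frame parameter algebra
# ---------------------------------------------------------------------------


def frames_to_params(f1: BaseFrame, f2: BaseFrame) -> tuple[np.ndarray, np.ndarray]:
    """Six rigid-body parameters of frame 2 relative to frame 1.

    Returns (translations, rotations): translations (dx, dy, dz in A)
    are the origin difference expressed in the mid-triad; rotations
    (rx, ry, rz in deg) are the tilt/roll-like hinge decomposition plus
    the twist about the mid z-axis.
    """
    z1, z2 = f1.z, f2.z
    cz = np.cross(z1, z2)
    if np.linalg.norm(cz) < 1e-12:
        hinge = f1.x  # parallel z axes: bend is zero, hinge arbitrary
        gamma = 0.0
    else:
        hinge = _unit(cz)
        gamma = math.degrees(math.acos(np.clip(float(np.dot(z1, z2)), -1.0, 1.0)))
    R1p = _rot(hinge, +gamma / 2.0) @ f1.axes
    R2p = _rot(hinge, -gamma / 2.0) @ f2.axes
    zm = _unit(R1p[:, 2] + R2p[:, 2])
    twist = _signed_angle(R1p[:, 0], R2p[:, 0], zm)
    xm = R1p[:, 0] + R2p[:, 0]
    xm = _unit(xm - np.dot(xm, zm) * zm)
    ym = np.cross(zm, xm)
    Rm = np.column_stack([xm, ym, zm])
    trans = Rm.T @ (f2.origin - f1.origin)
    phi = _signed_angle(hinge, ym, zm)
    roll = gamma * math.cos(math.radians(phi))
    tilt = gamma * math.sin(math.radians(phi))
    return trans, np.array([tilt, roll, twist])


def params_to_frames(f1: BaseFrame, trans, rots) -> BaseFrame:
    """Rebuild frame 2 from frame 1 plus the six CEHS parameters."""
    dx, dy, dz = np.asarray(trans, dtype=float)
    tilt, roll, twist = np.asarray(rots, dtype=float)
    gamma = math.hypot(roll, tilt)
    phi = math.degrees(math.atan2(tilt, roll))
    e2, e3 = np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0])
    hinge_l = _rot(e3, -phi) @ e2
    A1 = _rot(hinge_l, -gamma / 2.0) @ _rot(e3, -twist / 2.0)
    A2 = _rot(hinge_l, +gamma / 2.0) @ _rot(e3, +twist / 2.0)
    Rm = f1.axes @ np.linalg.inv(A1)
    R2 = Rm @ A2
    o2 = f1.origin + Rm @ np.array([dx, dy, dz])
    return BaseFrame(origin=o2, axes=R2)


def mid_frame(f1: BaseFrame, f2: BaseFrame) -> BaseFrame:
    """Mid-triad of two frames with the mean origin (the base-pair frame)."""
    z1, z2 = f1.z, f2.z
    cz = np.cross(z1, z2)
    if np.linalg.norm(cz) < 1e-12:
        R1p, R2p = f1.axes, f2.axes
    else:
        hinge = _unit(cz)
        gamma = math.degrees(math.acos(np.clip(float(np.dot(z1, z2)), -1.0, 1.0)))
        R1p = _rot(hinge, +gamma / 2.0) @ f1.axes
        R2p = _rot(hinge, -gamma / 2.0) @ f2.axes
    zm = _unit(R1p[:, 2] + R2p[:, 2])
    xm = R1p[:, 0] + R2p[:, 0]
    xm = _unit(xm - np.dot(xm, zm) * zm)
    ym = np.cross(zm, xm)
    return BaseFrame(
        origin=0.5 * (f1.origin + f2.origin), axes=np.column_stack([xm, ym, zm])
    )


def pair_parameters(f1: BaseFrame, f2: BaseFrame, flip_second: bool = False) -> PairParameters:
    """Intra-base-pair parameters from the two base frames.

    `f2` is the partner-strand frame; pass ``flip_second=True`` when it is
    still in its own strand's frame (y, z are then negated before pairing).
    Shear/stretch/stagger are the translations, buckle/propeller/opening
    the hinge rotations of frame 1 relative to the (flipped) frame 2.
    """
    if flip_second:
        f2 = flip_frame(f2)
    trans, rots = frames_to_params(f2, f1)
    return PairParameters(
        shear=float(trans[0]),
        stretch=float(trans[1]),
        stagger=float(trans[2]),
        buckle=float(rots[0]),
        propeller=float(rots[1]),
        opening=float(rots[2]),
    )


def step_parameters(p1: BaseFrame, p2: BaseFrame) -> StepParameters:
    """Base-pair step parameters between two consecutive pair frames."""
    trans, rots = frames_to_params(p1, p2)
    return StepParameters(
        shift=float(trans[0]),
        slide=float(trans[1]),
        rise=float(trans[2]),
        tilt=float(rots[0]),
        roll=float(rots[1]),
        twist=float(rots[2]),
    )


def helical_parameters(p1: BaseFrame, p2: BaseFrame) -> HelicalParameters:
    """Helical-axis parameters of one step.

    The local helical axis is the rotation axis of the step transform;
    htwist is the rotation about it and hrise the origin displacement
    along it.  Inclination/tip decompose the angle between each pair
    z-axis and the helical axis (hinge decomposition as for roll/tilt);
    x-/y-displacement locate the pair origins relative to the axis in the
    axis-aligned triads.  Per-step values average the two pair frames.
    """
    Rt = p2.axes @ p1.axes.T
    tr = np.clip((np.trace(Rt) - 1.0) / 2.0, -1.0, 1.0)
    ang = math.degrees(math.acos(tr))
    if ang < 1e-9:
        h = _unit(p1.z + p2.z)
        htwist = 0.0
    else:
        rv = np.array(
            [Rt[2, 1] - Rt[1, 2], Rt[0, 2] - Rt[2, 0], Rt[1, 0] - Rt[0, 1]]
        )
        if np.linalg.norm(rv) < 1e-12:  # 180-degree rotation
            w, v = np.linalg.eigh(Rt + Rt.T)
            h = _unit(v[:, np.argmax(w)])
        else:
            h = _unit(rv)
        if np.dot(h, p1.z + p2.z) < 0:
            h = -h
            ang = -ang
        htwist = ang
    delta = p2.origin - p1.origin
    hrise = float(np.dot(delta, h))

    incs, tips, xds, yds = [], [], [], []
    # axis anchor point (perpendicular plane through the screw axis)
    if abs(htwist) > 1e-9:
        e1 = _unit(np.cross(h, p1.z) if np.linalg.norm(np.cross(h, p1.z)) > 1e-9
                   else np.cross(h, p1.x))
        e2 = np.cross(h, e1)
        om = math.radians(htwist)
        M = np.array([[math.cos(om) - 1.0, -math.sin(om)], [math.sin(om), math.cos(om) - 1.0]])
        dperp = delta - hrise * h
        rhs = np.array([np.dot(dperp, e1), np.dot(dperp, e2)])
        u2d = np.linalg.solve(M, rhs)  # u = o1 - p (perpendicular part)
        axis_point = p1.origin - (u2d[0] * e1 + u2d[1] * e2)
    else:
        axis_point = 0.5 * (p1.origin + p2.origin)

    for f in (p1, p2):
        cz = np.cross(f.z, h)
        if np.linalg.norm(cz) < 1e-12:
            incs.append(0.0)
            tips.append(0.0)
            Rp = f.axes
        else:
            hinge = _unit(cz)
            g = math.degrees(math.acos(np.clip(float(np.dot(f.z, h)), -1.0, 1.0)))
            Rp = _rot(hinge, g) @ f.axes
            phi = _signed_angle(hinge, Rp[:, 1], h)
            # inclination is the x-rotation (long-axis tilt, tilt-like
            # slot); tip the y-rotation; signs fixed so that A-DNA
            # geometry (base planes tilted with the backbone closable)
            # reports positive inclination
            incs.append(-g * math.sin(math.radians(phi)))
            tips.append(-g * math.cos(math.radians(phi)))
        u = f.origin - axis_point
        u = u - np.dot(u, h) * h
        xds.append(float(np.dot(u, Rp[:, 0])))
        yds.append(float(np.dot(u, Rp[:, 1])))

    return HelicalParameters(
        x_displacement=float(np.mean(xds)),
        y_displacement=float(np.mean(yds)),
        hrise=hrise,
        inclination=float(np.mean(incs)),
        tip=float(np.mean(tips)),
        htwist=float(htwist),
    )


def helical_frames(
    n: int,
    htwist: float,
    hrise: float,
    inclination: float = 0.0,
    tip: float = 0.0,
    x_displacement: float = 0.0,
    y_displacement: float = 0.0,
) -> list[BaseFrame]:
    """Regular helix of n base-pair frames with the given helical parameters.

    The helical axis is the global z-axis.  `helical_parameters` applied to
    any consecutive pair of the returned frames recovers the inputs, which
    makes this the generator of idealized A-/B-form duplex scaffolds.
    """
    gamma = math.hypot(inclination, tip)
    alpha = math.degrees(math.atan2(tip, inclination))
    a = np.array([math.cos(math.radians(alpha)), math.sin(math.radians(alpha)), 0.0])
    R0 = _rot(a, gamma) if gamma > 0 else np.eye(3)
    o0 = np.array([x_displacement, y_displacement, 0.0])
    frames = []
    for i in range(n):
        Rz = _rot(np.array([0.0, 0.0, 1.0]), htwist * i)
        frames.append(BaseFrame(origin=Rz @ o0 + np.array([0.0, 0.0, hrise * i]), axes=Rz @ R0))
    return frames


# ---------------------------------------------------------------------------
# groove widths (El Hassan-Calladine convention)
# ---------------------------------------------------------------------------

#: cross-strand index offset (in steps along each strand) giving the
#: closest minor-groove and the opposing major-groove P-P separations for
#: right-handed duplexes; calibrated on the idealized B-form fixture.
MINOR_GROOVE_OFFSET = 3
MAJOR_GROOVE_OFFSET = -3


def groove_widths(
    strand1_P: np.ndarray,
    strand2_P: np.ndarray,
    radius_correction: float = 5.8,
    interior_only: bool = False,
) -> pd.DataFrame:
    """Minor/major groove widths per level from phosphorus coordinates.

    Both strands are given 5'->3'; residue i of strand 1 pairs with
    residue n+1-i of strand 2.  The minor (major) groove width at a level
    is the cross-strand P-P distance offset by +-3 steps along the duplex,
    minus twice the 2.9 A phosphate radius (`radius_correction`, set 0 to
    report raw P-P distances).

    Returns
    -------
    DataFrame with columns level, minor, major (NaN where the offset runs
    off a strand end).
    """
    p1 = np.asarray(strand1_P, dtype=float)
    p2 = np.asarray(strand2_P, dtype=float)
    if len(p1) < 4 or len(p2) < 4:
        raise ValueError("need at least four phosphates per strand")
    n1, n2 = len(p1), len(p2)

    def _width(i: int, offset: int) -> float:
        # strand-2 phosphate list runs antiparallel: opposite index n2-1-i
        j = (n2 - 1 - i) + offset
        if 0 <= j < n2:
            return float(np.linalg.norm(p1[i] - p2[j]) - radius_correction)
        return float("nan")

    rows = []
    for i in range(n1):
        rows.append(
            {
                "level": i + 1,
                "minor": _width(i, MINOR_GROOVE_OFFSET),
                "major": _width(i, MAJOR_GROOVE_OFFSET),
            }
        )
    df = pd.DataFrame(rows)
    if interior_only:
        df = df.dropna().reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# whole-duplex report
# ---------------------------------------------------------------------------


def _circmean_deg(a: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        return float("nan")
    ang = math.degrees(
        math.atan2(np.mean(np.sin(np.radians(a))), np.mean(np.cos(np.radians(a))))
    )
    return float(_pucker.wrap360(ang))


def duplex_report(
    residues,
    pairing: list[tuple[int, int]] | None = None,
    exclude_terminal: int = 2,
    bi_only: bool = False,
    groove_radius_correction: float = 5.8,
) -> pd.DataFrame:
    """Average structural parameters of one duplex snapshot.

    Parameters
    ----------
    residues : list of residue records (`read_pdb_residues` format)
        Exactly two chains; strand 2 antiparallel to strand 1.
    pairing : optional list of (index1, index2)
        Indices into `residues` pairing the strands; default pairs the
        chains by order (residue i of chain 1 with residue n+1-i of
        chain 2).
    exclude_terminal : int
        Base pairs dropped from each duplex end before averaging.
    bi_only : bool
        Restrict backbone-angle averages to residues currently in the BI
        epsilon/zeta substate.
    groove_radius_correction : float
        Passed through to `groove_widths`.

    Returns
    -------
    DataFrame with columns parameter, mean, n.
    """
    from .stats import classify_bi_bii

    residues = list(residues)
    chains: dict[str, list[int]] = {}
    for i, r in enumerate(residues):
        chains.setdefault(r["chain"], []).append(i)
    if pairing is None:
        if len(chains) != 2:
            raise ValueError("default pairing requires exactly two chains")
        c1, c2 = chains.values()
        if len(c1) != len(c2):
            raise ValueError("strands differ in length; supply a pairing map")
        pairing = [(a, b) for a, b in zip(c1, reversed(c2))]

    angles = _pucker.angles_from_structure(residues)
    if angles.empty:
        angles = pd.DataFrame(
            columns=["chain", "resseq", "alpha", "beta", "gamma", "delta", "epsilon",
                     "zeta", "chi", "P", "tau_m", "pucker_class"]
        )
    angles = angles.set_index(
        pd.MultiIndex.from_frame(angles[["chain", "resseq"]])
    )

    pair_frames: list[BaseFrame | None] = []
    pair_params: list[PairParameters | None] = []
    for i1, i2 in pairing:
        r1, r2 = residues[i1], residues[i2]
        try:
            f1 = base_frame(r1["atoms"], r1["resname"])
            f2 = flip_frame(base_frame(r2["atoms"], r2["resname"]))
        except ValueError as exc:
            warnings.warn(f"pair ({i1},{i2}) skipped: {exc}", UserWarning, stacklevel=2)
            pair_frames.append(None)
            pair_params.append(None)
            continue
        pair_params.append(pair_parameters(f1, f2))
        pair_frames.append(mid_frame(f2, f1))

    n_pairs = len(pairing)
    keep = slice(exclude_terminal, n_pairs - exclude_terminal)
    kept_idx = list(range(n_pairs))[keep]
    if not kept_idx:
        raise ValueError("terminal exclusion leaves no base pairs")

    step_rows, hel_rows = [], []
    for a, b in zip(kept_idx[:-1], kept_idx[1:]):
        fa, fb = pair_frames[a], pair_frames[b]
        if fa is None or fb is None:
            continue
        step_rows.append(step_parameters(fa, fb))
        hel_rows.append(helical_parameters(fa, fb))

    # backbone angles over kept residues (both strands)
    kept_res = [residues[i] for a in kept_idx for i in pairing[a]]
    keys = [(r["chain"], r["resseq"]) for r in kept_res]
    sub = angles.loc[angles.index.intersection(keys)]
    if bi_only and len(sub):
        lab = classify_bi_bii(sub["epsilon"].to_numpy(), sub["zeta"].to_numpy())
        sub = sub[lab == "BI"]

    # groove widths from phosphorus atoms
    c1, c2 = chains.values()
    p1 = np.array([residues[i]["atoms"]["P"] for i in c1 if "P" in residues[i]["atoms"]])
    p2 = np.array([residues[i]["atoms"]["P"] for i in c2 if "P" in residues[i]["atoms"]])
    try:
        gw = groove_widths(p1, p2, radius_correction=groove_radius_correction,
                           interior_only=True)
        minor, major = float(gw["minor"].mean()), float(gw["major"].mean())
    except ValueError:
        minor = major = float("nan")

    out = []

    def add(name, value, n):
        out.append({"parameter": name, "mean": value, "n": n})

    for name in ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi", "P"):
        add(name, _circmean_deg(sub[name].to_numpy()), len(sub))
    add("tau_m", float(np.nanmean(sub["tau_m"].to_numpy())) if len(sub) else float("nan"),
        len(sub))
    add("percent_N", 100.0 * float(np.mean(sub["pucker_class"] == "N")) if len(sub) else
        float("nan"), len(sub))

    kept_pairs = [pair_params[i] for i in kept_idx if pair_params[i] is not None]
    for name in ("shear", "stretch", "stagger", "buckle", "propeller", "opening"):
        vals = [getattr(p, name) for p in kept_pairs]
        add(name, float(np.mean(vals)) if vals else float("nan"), len(vals))
    for name in ("shift", "slide", "rise", "tilt", "roll", "twist"):
        vals = [getattr(s, name) for s in step_rows]
        add(name, float(np.mean(vals)) if vals else float("nan"), len(vals))
    for name in ("x_displacement", "y_displacement", "hrise", "inclination", "tip", "htwist"):
        vals = [getattr(h, name) for h in hel_rows]
        add(name, float(np.mean(vals)) if vals else float("nan"), len(vals))
    add("minor_groove", minor, 1)
    add("major_groove", major, 1)
    return pd.DataFrame(out)
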