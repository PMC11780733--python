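"""Synthetic inputs with planted ground truth.

Three generators feed the validation machinery:

* `simulate_pucker_series` -- per-residue two-state (N/S) Markov chains
  with prescribed stationary north fraction and switching kinetics, plus
  categorical backbone-substate mixtures, emitted as a `DihedralSeries`.
* `synth_scan` -- pseudorotation-constrained torsion scans generated from
  known Fourier amplitudes, with the four energy components arranged so
  that the solvation-aware fit target reproduces the planted profile.
* `build_fiber_duplex` -- idealized A-/B-form duplex coordinates built by
  propagating standard base-pair frames along a regular helix with the
  form's canonical helical parameters and attaching a sugar-phosphate
  backbone with form-appropriate pucker and glycosidic torsion.

Every generator is deterministic under a fixed seed and returns the
ground truth alongside the data, so downstream estimators are always
tested against planted values, never against themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import helix as _helix
from . import pucker as _pucker
from .stats import DihedralSeries
from .torsion import ConformerRecord, FittedTypeSpec

__all__ = [
    "TwoStateSpec",
    "FiberSpec",
    "FIBER_FORMS",
    "simulate_pucker_series",
    "synth_scan",
    "build_fiber_duplex",
    "write_pdb",
]

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


# ---------------------------------------------------------------------------
# two-state pucker / backbone-substate time series
# ---------------------------------------------------------------------------


@dataclass
class TwoStateSpec:
    """Two-state N/S pucker chain with backbone substate mixtures.

    `switch_time` is the mean dwell time in frames averaged over visits
    (visits to N and S alternate, so tau_N = 2*switch_time*p_N and
    tau_S = 2*switch_time*(1-p_N) give both the stationary law and the
    requested mean dwell).
    """

    p_N: float = 0.15
    mean_P_N: float = 18.0
    mean_P_S: float = 150.0
    sigma_P: float = 12.0
    switch_time: float = 50.0
    n_frames: int = 10000
    n_residues: int = 1
    seed: int = 0
    p_BII: float = 0.25
    p_ag_flip: float = 0.015
    sigma_angle: float = 8.0
    frame_spacing_ps: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_N <= 1.0:
            raise ValueError("p_N must be in [0, 1]")
        if self.sigma_P <= 0:
            raise ValueError("sigma_P must be positive")
        if self.switch_time < 1:
            raise ValueError("switch_time must be >= 1 frame")


#: substate emission centers, degrees
_SUBSTATE_CENTERS = {
    "BI": {"epsilon": 185.0, "zeta": 265.0},
    "BII": {"epsilon": 265.0, "zeta": 185.0},
    "canonical": {"alpha": 295.0, "gamma": 52.0},
    "g+/t": {"alpha": 60.0, "gamma": 180.0},
}


def simulate_pucker_series(spec: TwoStateSpec):
    """Simulate the angle series; returns (DihedralSeries, ground_truth).

    The hidden chain is simulated exactly (per-frame Bernoulli switching
    with rates 1/tau_N, 1/tau_S); pseudorotation phases are the state
    mean plus wrapped Gaussian noise.  epsilon/zeta and alpha/gamma are
    drawn i.i.d. per frame from the categorical substate mixtures and
    emitted around the window centers.

    The ground-truth dict records the planted probabilities and the
    REALIZED hidden-state fractions and mean dwell time, so estimator
    tests can separate estimation error from sampling noise.
    """
    rng = np.random.default_rng(spec.seed)
    n_f, n_r = spec.n_frames, spec.n_residues
    if spec.p_N <= 0.0:
        states = np.zeros((n_f, n_r), dtype=bool)
    elif spec.p_N >= 1.0:
        states = np.ones((n_f, n_r), dtype=bool)
    else:
        tau_n = 2.0 * spec.switch_time * spec.p_N
        tau_s = 2.0 * spec.switch_time * (1.0 - spec.p_N)
        p_leave_n = min(1.0, 1.0 / tau_n)
        p_leave_s = min(1.0, 1.0 / tau_s)
        states = np.empty((n_f, n_r), dtype=bool)
        states[0] = rng.random(n_r) < spec.p_N
        u = rng.random((n_f - 1, n_r))
        for t in range(1, n_f):
            leave = np.where(states[t - 1], u[t - 1] < p_leave_n, u[t - 1] < p_leave_s)
            states[t] = states[t - 1] ^ leave
    means = np.where(states, spec.mean_P_N, spec.mean_P_S)
    P = _pucker.wrap360(means + rng.normal(0.0, spec.sigma_P, size=(n_f, n_r)))

    bii = rng.random((n_f, n_r)) < spec.p_BII
    eps = np.where(bii, _SUBSTATE_CENTERS["BII"]["epsilon"], _SUBSTATE_CENTERS["BI"]["epsilon"])
    zet = np.where(bii, _SUBSTATE_CENTERS["BII"]["zeta"], _SUBSTATE_CENTERS["BI"]["zeta"])
    agf = rng.random((n_f, n_r)) < spec.p_ag_flip
    alp = np.where(agf, _SUBSTATE_CENTERS["g+/t"]["alpha"], _SUBSTATE_CENTERS["canonical"]["alpha"])
    gam = np.where(agf, _SUBSTATE_CENTERS["g+/t"]["gamma"], _SUBSTATE_CENTERS["canonical"]["gamma"])
    noise = lambda: rng.normal(0.0, spec.sigma_angle, size=(n_f, n_r))  # noqa: E731
    angles = {
        "epsilon": _pucker.wrap360(eps + noise()),
        "zeta": _pucker.wrap360(zet + noise()),
        "alpha": _pucker.wrap360(alp + noise()),
        "gamma": _pucker.wrap360(gam + noise()),
    }

    # realized mean dwell over completed visits, pooled over residues
    dwells = []
    for j in range(n_r):
        s = states[:, j]
        change = np.nonzero(s[1:] != s[:-1])[0] + 1
        if len(change) >= 2:
            dwells.extend(np.diff(change))
    truth = {
        "p_N": spec.p_N,
        "p_BII": spec.p_BII,
        "p_ag_flip": spec.p_ag_flip,
        "realized_p_N": float(states.mean()),
        "realized_p_BII": float(bii.mean()),
        "realized_p_ag_flip": float(agf.mean()),
        "realized_mean_dwell": float(np.mean(dwells)) if dwells else float("nan"),
        "states": states,
    }
    series = DihedralSeries(
        P=P, angles=angles, frame_spacing_ps=spec.frame_spacing_ps
    )
    return series, truth


# ---------------------------------------------------------------------------
# Fourier-planted torsion scans
# ---------------------------------------------------------------------------


def synth_scan(
    fitted_types: list[FittedTypeSpec],
    amplitudes: dict,
    offset: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    tau_m: float = 38.0,
    instance_angle_fns: dict | None = None,
):
    """Generate a 36-point pseudorotation scan from planted amplitudes.

    Parameters
    ----------
    fitted_types : list of FittedTypeSpec
        The fit skeleton; instance ids 'tau1' and 'delta' get their
        angles from `scan_constraints`, other ids default to the tau1
        map unless `instance_angle_fns` provides a callable P -> degrees.
    amplitudes : dict
        Planted signed Vn/2 values keyed by (atom_types, periodicity),
        matching `FitResult.amplitudes`.
    offset : float
        Planted constant added to the reference side.
    noise_sd : float
        SD (kcal/mol) of i.i.d. Gaussian noise on the QM gas energy.

    Returns
    -------
    (records, ground_truth) where ground_truth holds the planted
    amplitudes, offset and the noiseless residual profile.
    """
    rng = np.random.default_rng(seed)
    grid = _pucker.scan_targets()
    records = []
    profile = []
    for P in grid:
        tau1, delta = _pucker.scan_constraints(P, tau_m)
        dihedrals = {}
        for ft in fitted_types:
            for inst in ft.instances:
                if instance_angle_fns and inst in instance_angle_fns:
                    dihedrals[inst] = float(instance_angle_fns[inst](P))
                elif inst == "delta":
                    dihedrals[inst] = delta
                else:
                    dihedrals[inst] = tau1
        e_torsion = offset
        for ft in fitted_types:
            for n in ft.periodicities:
                a = amplitudes.get((tuple(ft.atom_types), n), 0.0)
                for inst in ft.instances:
                    e_torsion += a * (1.0 + math.cos(math.radians(n * dihedrals[inst])))
        profile.append(e_torsion)
        # smooth conformation-dependent components; arranged so that
        # (e_qm_gas + g_solv_qm) - (e_mm_nontorsion + g_solv_mm) = e_torsion
        g_solv_qm = 0.5 * math.cos(math.radians(2.0 * P))
        g_solv_mm = 0.2 * math.cos(math.radians(P))
        e_mm = 1.0 + 0.4 * math.sin(math.radians(P))
        e_qm_gas = (
            e_torsion + e_mm + g_solv_mm - g_solv_qm + rng.normal(0.0, noise_sd)
            if noise_sd > 0
            else e_torsion + e_mm + g_solv_mm - g_solv_qm
        )
        records.append(
            ConformerRecord(
                P=float(P),
                dihedral_values=dihedrals,
                e_qm_gas=e_qm_gas,
                g_solv_qm=g_solv_qm,
                e_mm_nontorsion=e_mm,
                g_solv_mm=g_solv_mm,
            )
        )
    truth = {
        "amplitudes": dict(amplitudes),
        "offset": offset,
        "profile": np.array(profile),
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return records, truth


# ---------------------------------------------------------------------------
# idealized fiber duplexes
# ---------------------------------------------------------------------------

#: canonical per-form helical parameters and sugar/glycosidic geometry
FIBER_FORMS: dict[str, dict] = {
    "B": {
        "htwist": 36.0,
        "hrise": 3.38,
        "inclination": 1.5,
        "tip": 0.0,
        "x_displacement": 0.0,
        "y_displacement": 0.0,
        "P": 155.0,
        "tau_m": 36.0,
        "chi": 250.0,  # high-anti
        "epsilon": 185.0,
        "zeta": 265.0,
    },
    "A": {
        "htwist": 32.7,
        "hrise": 2.81,
        "inclination": 20.7,
        "tip": 0.0,
        "x_displacement": -5.3,
        "y_displacement": 0.0,
        "P": 18.0,
        "tau_m": 38.0,
        "chi": 202.0,  # anti
        "epsilon": 212.0,
        "zeta": 287.0,
    },
}


@dataclass
class FiberSpec:
    """Idealized duplex: helical form plus strand-1 sequence (5'->3')."""

    form: str = "B"
    sequence: str = "CGCGAATTCGCG"
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.form not in FIBER_FORMS:
            raise ValueError(f"form must be one of {sorted(FIBER_FORMS)}")
        seq = self.sequence.upper()
        if len(seq) < 2:
            raise ValueError("sequence must have length >= 2")
        bad = set(seq) - set("ACGT")
        if bad:
            raise ValueError(f"unsupported sequence characters: {sorted(bad)}")
        self.sequence = seq

    @property
    def parameters(self) -> dict:
        p = dict(FIBER_FORMS[self.form])
        p.update(self.overrides)
        return p


# -- sugar template construction -------------------------------------------

_RING_ORDER = ("O4'", "C1'", "C2'", "C3'", "C4'")
_RING_RADIUS = 1.26  # planar-projection radius, A


def _ring_coords(q: float, phase_deg: float) -> np.ndarray:
    """Pentagon ring with out-of-plane displacements z_j = q cos(phase + 4*pi*j/5)."""
    j = np.arange(5)
    theta = 2.0 * np.pi * j / 5.0
    z = q * np.cos(np.radians(phase_deg) + 4.0 * np.pi * j / 5.0)
    return np.column_stack([_RING_RADIUS * np.cos(theta), _RING_RADIUS * np.sin(theta), z])


def _ring_pucker(coords: np.ndarray) -> tuple[float, float]:
    atoms = dict(zip(_RING_ORDER, coords))
    nus = [
        _pucker.dihedral_angle(*(atoms[n] for n in quad))
        for quad in _pucker._RING_TORSION_ATOMS
    ]
    st = _pucker.pseudorotation(_pucker.RingTorsions(*nus))
    return st.P, st.tau_m


_ring_cache: dict[tuple[float, float], np.ndarray] = {}


def _solve_ring(P_target: float, tau_m_target: float) -> np.ndarray:
    """Find (q, phase) whose pentagon ring has the requested (P, tau_m)."""
    from scipy.optimize import fsolve

    key = (round(P_target, 9), round(tau_m_target, 9))
    if key in _ring_cache:
        return _ring_cache[key]

    def resid(x):
        q, phase = x
        P, tm = _ring_pucker(_ring_coords(abs(q), phase))
        return [float(_pucker.wrap180(P - P_target)), tm - tau_m_target]

    q0 = tau_m_target / 102.5
    best = None
    for phase0 in (P_target, P_target + 90.0, P_target + 180.0, P_target + 270.0):
        sol, info, ier, _ = fsolve(resid, [q0, phase0], full_output=True)
        err = np.max(np.abs(info["fvec"]))
        if ier == 1 and (best is None or err < best[1]):
            best = (sol, err)
    if best is None or best[1] > 1e-6:
        raise RuntimeError(f"ring pucker solve failed for P={P_target}, tau_m={tau_m_target}")
    q, phase = best[0]
    _ring_cache[key] = _ring_coords(abs(q), phase)
    return _ring_cache[key]


def _tetrahedral_pair(center, nb1, nb2, bond_length):
    """The two tetrahedral substituent positions on `center` given two neighbors."""
    u1 = (nb1 - center) / np.linalg.norm(nb1 - center)
    u2 = (nb2 - center) / np.linalg.norm(nb2 - center)
    bis = -(u1 + u2)
    bis /= np.linalg.norm(bis)
    perp = np.cross(u1, u2)
    perp /= np.linalg.norm(perp)
    half = math.radians(109.47 / 2.0)
    d1 = math.cos(half) * bis + math.sin(half) * perp
    d2 = math.cos(half) * bis - math.sin(half) * perp
    return center + bond_length * d1, center + bond_length * d2


def _place_by_torsion(a, b, c, bond_length, angle_deg, torsion_deg):
    """Place atom d with given c-d bond, b-c-d angle and a-b-c-d torsion."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(180.0 - angle_deg)
    tor = math.radians(torsion_deg)
    d2 = np.array(
        [
            math.cos(ang),
            math.sin(ang) * math.cos(tor),
            math.sin(ang) * math.sin(tor),
        ]
    )
    frame = np.column_stack([bc, m, n])
    return c + bond_length * (frame @ d2)


def _sugar_core(base: str, P: float, tau_m: float, chi: float) -> dict:
    """Ring + C5'/O3' atoms in the standard base frame for one nucleotide.

    The furanose ring is generated with the requested pseudorotation
    state, decorated with the exocyclic C5' and O3' at idealized
    geometry, then rigidly attached at C1' with the requested glycosidic
    torsion chi.  The 5'-phosphate arm (O5', P) is placed separately.
    """
    ring = dict(zip(_RING_ORDER, _solve_ring(P, tau_m)))
    up = np.cross(
        ring["C1'"] - ring["O4'"], ring["C2'"] - ring["C1'"]
    )  # face reference

    def pick(center, nb1, nb2, L, face_up: bool):
        c1, c2 = _tetrahedral_pair(ring[center], ring[nb1], ring[nb2], L)
        s1 = np.dot(c1 - ring[center], up)
        return c1 if (s1 > 0) == face_up else c2

    # face choices reproduce beta-D-deoxyribose: chirality at C1'/C3'/C4'
    # matches the CCD idealized nucleotides and canonical delta ranges
    # (~140 deg for S, ~85 deg for N sugars) emerge from the ring geometry
    atoms = dict(ring)
    atoms["_N"] = pick("C1'", "O4'", "C2'", 1.48, face_up=False)  # glycosidic N
    atoms["C5'"] = pick("C4'", "C3'", "O4'", 1.51, face_up=False)
    atoms["O3'"] = pick("C3'", "C2'", "C4'", 1.42, face_up=True)

    # rigid attachment: C1' to its standard position, glycosidic bond along
    # the standard C1'->N direction, rotation about the bond set by chi
    std = _helix.STANDARD_BASES[base]
    n_name = "N9" if base in ("A", "G") else "N1"
    c_name = "C4" if base in ("A", "G") else "C2"
    c1_std = np.array(std["C1'"])
    n_std = np.array(std[n_name])
    c_next = np.array(std[c_name])

    v_loc = atoms["_N"] - atoms["C1'"]
    v_std = n_std - c1_std
    R = _rotation_between(v_loc, v_std)
    moved = {k: R @ (v - atoms["C1'"]) + c1_std for k, v in atoms.items()}

    chi_now = _pucker.dihedral_angle(moved["O4'"], c1_std, n_std, c_next)
    axis = v_std / np.linalg.norm(v_std)
    # rotating the sugar (first torsion atom) by +t about C1'->N changes
    # the measured torsion by -t
    Rchi = _helix._rot(axis, chi_now - chi)
    final = {k: Rchi @ (v - c1_std) + c1_std for k, v in moved.items()}
    del final["_N"]
    return final


def _sugar_template(base: str, P: float, tau_m: float, chi: float,
                    gamma: float = 55.0, beta: float = 180.0) -> dict:
    """Standalone nucleotide template: core sugar plus a torsion-placed
    5'-phosphate arm with the given gamma (O5'-C5'-C4'-C3') and beta
    (P-O5'-C5'-C4') backbone torsions."""
    atoms = dict(_sugar_core(base, P, tau_m, chi))
    atoms["O5'"] = _place_by_torsion(
        atoms["C3'"], atoms["C4'"], atoms["C5'"], 1.43, 110.0, float(gamma)
    )
    atoms["P"] = _place_by_torsion(
        atoms["C4'"], atoms["C5'"], atoms["O5'"], 1.60, 120.0, float(beta)
    )
    return atoms


def _rotation_between(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    a = v_from / np.linalg.norm(v_from)
    b = v_to / np.linalg.norm(v_to)
    c = np.cross(a, b)
    d = float(np.dot(a, b))
    if np.linalg.norm(c) < 1e-12:
        if d > 0:
            return np.eye(3)
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return _helix._rot(perp, 180.0)
    axis = c / np.linalg.norm(c)
    return _helix._rot(axis, math.degrees(math.atan2(np.linalg.norm(c), d)))


def _solve_o5(p_atom, c5, c3_prev, o3_prev, zeta_target,
              r_po5: float = 1.59, r_o5c5: float = 1.43) -> np.ndarray:
    """Place O5' bonded to both P and C5', steering zeta towards target.

    The feasible O5' positions form the intersection circle of the two
    bond spheres; the point whose zeta torsion (C3'-O3'-P-O5' of the
    preceding linkage) is closest to `zeta_target` is chosen.  If the
    spheres do not intersect the point on the P->C5' segment at the
    P-O5' bond length is used (best-effort closure).
    """
    u = c5 - p_atom
    d = float(np.linalg.norm(u))
    u = u / d
    if d >= r_po5 + r_o5c5 - 1e-3 or d <= abs(r_po5 - r_o5c5) + 1e-3:
        # bonds cannot both close: open the P-O5'-C5' angle slightly off
        # the axis so downstream torsions stay defined
        e1 = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(e1) < 1e-9:
            e1 = np.cross(u, [1.0, 0.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        tilt = math.radians(15.0)
        best, best_err = None, None
        for t in np.arange(0.0, 360.0, 2.0):
            dirn = math.cos(tilt) * u + math.sin(tilt) * (
                math.cos(math.radians(t)) * e1 + math.sin(math.radians(t)) * e2
            )
            x = p_atom + r_po5 * dirn
            zeta = _pucker.dihedral_angle(c3_prev, o3_prev, p_atom, x)
            err = abs(float(_pucker.wrap180(zeta - zeta_target)))
            if best_err is None or err < best_err:
                best, best_err = x, err
        return best
    a = (r_po5**2 - r_o5c5**2 + d**2) / (2.0 * d)
    r = math.sqrt(max(r_po5**2 - a**2, 0.0))
    center = p_atom + a * u
    e1 = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-9:
        e1 = np.cross(u, [1.0, 0.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    best, best_err = None, None
    for t in np.arange(0.0, 360.0, 1.0):
        x = center + r * (math.cos(math.radians(t)) * e1 + math.sin(math.radians(t)) * e2)
        zeta = _pucker.dihedral_angle(c3_prev, o3_prev, p_atom, x)
        err = abs(float(_pucker.wrap180(zeta - zeta_target)))
        if best_err is None or err < best_err:
            best, best_err = x, err
    return best


def build_fiber_duplex(spec: FiberSpec):
    """Build idealized duplex coordinates; returns (residues, ground_truth).

    Residue records use the same layout as `read_pdb_residues` (chains A
    and B, strand 2 written 5'->3').  The ground-truth dict carries the
    planted helical parameters and sugar state for rebuild-oracle tests.
    """
    params = spec.parameters
    seq1 = spec.sequence
    n = len(seq1)
    frames = _helix.helical_frames(
        n,
        htwist=params["htwist"],
        hrise=params["hrise"],
        inclination=params["inclination"],
        tip=params["tip"],
        x_displacement=params["x_displacement"],
        y_displacement=params["y_displacement"],
    )
    templates: dict[tuple[str, int], dict] = {}

    # maps of 5'-neighbour local coordinates into the current residue's
    # local frame (regular helix: same relative transform at every step).
    # Strand 1 runs 5'->3' with increasing level; strand 2 (attached via
    # the y,z flip) runs 5'->3' with decreasing level.
    f0, f1 = frames[0], frames[1]
    flip = np.diag([1.0, -1.0, -1.0])

    def _prev_in_cur_1(v: np.ndarray) -> np.ndarray:
        return f1.axes.T @ (f0.axes @ v + f0.origin - f1.origin)

    def _prev_in_cur_2(v: np.ndarray) -> np.ndarray:
        return flip @ (f0.axes.T @ (f1.axes @ (flip @ v) + f1.origin - f0.origin))

    def template(base: str, strand: int) -> dict:
        if (base, strand) not in templates:
            prev_in_cur = _prev_in_cur_1 if strand == 1 else _prev_in_cur_2
            core = _sugar_core(base, params["P"], params["tau_m"], params["chi"])
            prev = {k: prev_in_cur(core[k]) for k in ("C4'", "C3'", "O3'")}
            # phosphate bonded to the previous residue's O3' with canonical
            # epsilon; O5' closes the two bonds to P and C5' with zeta as
            # close to canonical as the circle of solutions allows
            p_atom = _place_by_torsion(
                prev["C4'"], prev["C3'"], prev["O3'"], 1.60, 119.7, params["epsilon"]
            )
            o5 = _solve_o5(p_atom, core["C5'"], prev["C3'"], prev["O3'"], params["zeta"])
            atoms = {k: np.array(v) for k, v in _helix.STANDARD_BASES[base].items()}
            atoms.update(core)
            atoms["P"] = p_atom
            atoms["O5'"] = o5
            templates[(base, strand)] = atoms
        return templates[(base, strand)]

    strand1, strand2 = [], []
    for i, b1 in enumerate(seq1):
        b2 = _COMPLEMENT[b1]
        f = frames[i]
        atoms1 = {k: f.axes @ v + f.origin for k, v in template(b1, 1).items()}
        atoms2 = {k: f.axes @ (flip @ v) + f.origin for k, v in template(b2, 2).items()}
        strand1.append({"chain": "A", "resseq": i + 1, "resname": "D" + b1, "atoms": atoms1})
        strand2.append({"chain": "B", "resseq": i + 1, "resname": "D" + b2, "atoms": atoms2})
    strand2 = strand2[::-1]
    for j, r in enumerate(strand2):
        r["resseq"] = j + 1
    # 5'-terminal residues carry no phosphate group
    for r in (strand1[0], strand2[0]):
        r["atoms"].pop("P", None)
    residues = strand1 + strand2
    truth = {
        "form": spec.form,
        "sequence": seq1,
        **{k: params[k] for k in (
            "htwist", "hrise", "inclination", "tip", "x_displacement",
            "y_displacement", "P", "tau_m", "chi",
        )},
    }
    return residues, truth


def write_pdb(residues, path) -> None:
    """Write residue records as a minimal single-model PDB file."""
    serial = 1
    lines = []
    for res in residues:
        for name, xyz in res["atoms"].items():
            pdb_name = name if len(name) >= 4 else f" {name:<3s}"
            element = name[0]
            lines.append(
                f"ATOM  {serial:5d} {pdb_name:<4s} {res['resname']:>3s} "
                f"{res['chain']}{res['resseq']:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
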