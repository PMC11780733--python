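"""AMBER-style dihedral Fourier model, frcmod I/O, and solvation-aware refits.

The dihedral energy is the standard AMBER sum
``E(phi) = sum_n (Vn/2)/IDIVF * (1 + cos(n*phi - gamma_n))`` with phases
restricted to 0 or 180 deg, which makes the fit to a reference profile
linear in the half-barriers Vn/2.

The reference profile for a pseudorotation-constrained conformer scan is
assembled with conformation-dependent solvation on both sides, avoiding
double counting::

    residual_i = (E_QM_gas + G_solv_QM)_i - (E_MM_nontorsion + G_solv_MM)_i

so the fitted torsion absorbs exactly the part of the solvated QM surface
that the non-torsion MM terms (with their own solvation) do not describe.
High-level QM single points are combined by a composite scheme: two-point
complete-basis-set (CBS) extrapolation of HF and MP2 correlation energies
from aug-cc-pVTZ/aug-cc-pVQZ, a CCSD(T)-MP2 correction at aug-cc-pVDZ,
plus the solvation energy.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "HARTREE_TO_KCAL",
    "FourierTerm",
    "TorsionType",
    "ConformerRecord",
    "FittedTypeSpec",
    "FitSpec",
    "FitResult",
    "AdjustmentResult",
    "AdjustmentInfeasibleError",
    "FrcmodParseError",
    "RankDeficientError",
    "ParameterSet",
    "dihedral_energy",
    "hartree_to_kcal",
    "read_frcmod",
    "write_frcmod",
    "composite_reference_energy",
    "cbs_correlation",
    "cbs_hf",
    "fit_target",
    "fit_fourier",
    "empirical_adjustment",
]

HARTREE_TO_KCAL = 627.509474


def hartree_to_kcal(e_hartree):
    """Convert energies from hartree to kcal/mol."""
    return np.asarray(e_hartree, dtype=float) * HARTREE_TO_KCAL


@dataclass(frozen=True)
class FourierTerm:
    """One cosine term: (half_barrier/divider) * (1 + cos(n*phi - phase))."""

    periodicity: int
    half_barrier: float  # Vn/2, kcal/mol
    phase: float = 0.0  # degrees
    divider: int = 1  # frcmod IDIVF

    def __post_init__(self) -> None:
        if not 1 <= self.periodicity <= 6:
            raise ValueError("periodicity must be in 1..6")
        if self.divider < 1:
            raise ValueError("divider (IDIVF) must be >= 1")


@dataclass(frozen=True)
class TorsionType:
    """A dihedral type: ordered atom-type quadruple plus Fourier terms.

    Quadruple matching is palindromic: A-B-C-D is the same type as D-C-B-A.
    """

    atom_types: tuple[str, str, str, str]
    terms: tuple[FourierTerm, ...]

    def __post_init__(self) -> None:
        if len(self.atom_types) != 4:
            raise ValueError("atom_types must have four entries")
        if not self.terms:
            raise ValueError("at least one Fourier term required")

    @property
    def canonical_key(self) -> tuple[str, str, str, str]:
        fwd = tuple(self.atom_types)
        rev = tuple(reversed(fwd))
        return min(fwd, rev)

    def matches(self, quad: Sequence[str]) -> bool:
        q = tuple(quad)
        return q == tuple(self.atom_types) or q == tuple(reversed(self.atom_types))


def dihedral_energy(tt: TorsionType, phi) -> float | np.ndarray:
    """Torsion energy (kcal/mol) of one type at dihedral phi (degrees)."""
    phi = np.asarray(phi, dtype=float)
    e = np.zeros_like(phi, dtype=float)
    for t in tt.terms:
        e = e + (t.half_barrier / t.divider) * (
            1.0 + np.cos(np.radians(t.periodicity * phi - t.phase))
        )
    return float(e) if e.ndim == 0 else e


# ---------------------------------------------------------------------------
# frcmod dialect I/O (only the DIHE block is interpreted)
# ---------------------------------------------------------------------------


class FrcmodParseError(ValueError):
    """Malformed frcmod content; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


_BLOCK_HEADERS = ("MASS", "BOND", "ANGL", "ANGLE", "DIHE", "IMPR", "IMPROPER", "NONB", "NONBON")


@dataclass
class ParameterSet:
    """Parsed frcmod: interpreted DIHE types plus verbatim other blocks.

    `raw_lines` preserves the full file except the DIHE block body, with a
    placeholder marking where the DIHE entries are re-serialized, so that
    read -> write -> read is a fixed point.
    """

    title: str
    dihedrals: list[TorsionType] = field(default_factory=list)
    raw_lines: list[str] = field(default_factory=list)

    def find(self, quad: Sequence[str]) -> TorsionType | None:
        for tt in self.dihedrals:
            if tt.matches(quad):
                return tt
        return None


def _parse_dihe_line(line: str, lineno: int):
    """Parse one DIHE entry: quadruple, IDIVF, PK, PHASE, PN."""
    body = line.split("#")[0].rstrip()
    type_field = body[:11]
    if "-" not in type_field:
        raise FrcmodParseError(lineno, f"no atom-type quadruple in {line!r}")
    quad = tuple(p.strip() for p in type_field.split("-"))
    if len(quad) != 4 or any(not p for p in quad):
        raise FrcmodParseError(lineno, f"bad atom-type quadruple {type_field!r}")
    rest = body[11:].split()
    if len(rest) < 4:
        raise FrcmodParseError(lineno, "expected IDIVF PK PHASE PN after quadruple")
    try:
        idivf = int(float(rest[0]))
        pk = float(rest[1])
        phase = float(rest[2])
        pn = float(rest[3])
    except ValueError as exc:
        raise FrcmodParseError(lineno, f"non-numeric DIHE field: {exc}") from exc
    if int(abs(pn)) == 0:
        raise FrcmodParseError(lineno, "periodicity PN must be nonzero")
    return quad, idivf, pk, phase, pn


def read_frcmod(text: str) -> ParameterSet:
    """Parse an frcmod-dialect file.

    Only DIHE entries are interpreted; MASS/BOND/ANGLE/IMPROPER/NONBON
    blocks are carried through verbatim.  Multi-term dihedrals use the
    AMBER continuation convention: negative periodicity (PN) on every
    term except the last.
    """
    lines = text.splitlines()
    title = lines[0] if lines else ""
    raw: list[str] = []
    dihedrals: list[TorsionType] = []
    in_dihe = False
    pending_quad = None
    pending_terms: list[FourierTerm] = []
    dihe_marker_placed = False

    def _flush(lineno):
        nonlocal pending_quad, pending_terms
        if pending_quad is not None:
            raise FrcmodParseError(
                lineno, f"dihedral {'-'.join(pending_quad)} ends with a continuation term"
            )

    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        header = stripped.split()[0].upper() if stripped else ""
        if header in _BLOCK_HEADERS and (header != "DIHE" or not in_dihe):
            _flush(lineno)
            in_dihe = header == "DIHE"
            if in_dihe:
                raw.append(line)
                raw.append("<<<DIHE>>>")
                dihe_marker_placed = True
            else:
                raw.append(line)
            continue
        if in_dihe:
            if not stripped:  # blank line terminates the block
                _flush(lineno)
                in_dihe = False
                raw.append(line)
                continue
            quad, idivf, pk, phase, pn = _parse_dihe_line(line, lineno)
            term = FourierTerm(
                periodicity=int(abs(pn)), half_barrier=pk, phase=phase, divider=idivf
            )
            if pending_quad is not None and quad != pending_quad:
                raise FrcmodParseError(
                    lineno,
                    f"continuation term quadruple {'-'.join(quad)} does not match "
                    f"{'-'.join(pending_quad)}",
                )
            pending_quad = quad
            pending_terms.append(term)
            if pn > 0:  # last term of this type
                dihedrals.append(TorsionType(pending_quad, tuple(pending_terms)))
                pending_quad, pending_terms = None, []
        else:
            raw.append(line)
    _flush(len(lines))
    if not dihe_marker_placed:
        raw.append("DIHE")
        raw.append("<<<DIHE>>>")
    return ParameterSet(title=title, dihedrals=dihedrals, raw_lines=raw)


def _format_dihe_entry(tt: TorsionType) -> list[str]:
    out = []
    quad = "-".join(f"{a:<2s}" for a in tt.atom_types)
    for i, t in enumerate(tt.terms):
        pn = t.periodicity if i == len(tt.terms) - 1 else -t.periodicity
        out.append(
            f"{quad} {t.divider:4d} {t.half_barrier:14.8f} {t.phase:8.3f} {float(pn):6.1f}"
        )
    return out


def write_frcmod(pset: ParameterSet) -> str:
    """Serialize a ParameterSet back to frcmod text (canonical spacing)."""
    out: list[str] = []
    for line in pset.raw_lines:
        if line == "<<<DIHE>>>":
            for tt in pset.dihedrals:
                out.extend(_format_dihe_entry(tt))
        else:
            out.append(line)
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# composite QM reference energy
# ---------------------------------------------------------------------------


def cbs_correlation(e_tz: float, e_qz: float) -> float:
    """Two-point X^-3 CBS extrapolation of a correlation energy (X=3,4)."""
    return (64.0 * e_qz - 27.0 * e_tz) / 37.0


def cbs_hf(e_tz: float, e_qz: float) -> float:
    """Two-point X^-5 power-law CBS extrapolation of the HF energy (X=3,4)."""
    return (1024.0 * e_qz - 243.0 * e_tz) / 781.0


def composite_reference_energy(
    e_hf_tz: float,
    e_hf_qz: float,
    e_corr_tz: float,
    e_corr_qz: float,
    e_ccsdt_dz: float,
    e_mp2_dz: float,
    g_solv: float,
) -> float:
    """CCSD(T)/CBS-quality single point with solvation, kcal/mol.

    ``E = E_HF^CBS(TZ,QZ) + E_corr^CBS(TZ,QZ) + [E_CCSD(T) - E_MP2]_DZ
    + G_solv``.  The correlation CBS limit uses the two-point X^-3 scheme;
    the HF limit a two-point X^-5 power law (recorded in output metadata
    by callers).  All inputs must already be in kcal/mol for a common
    conformer.
    """
    return (
        cbs_hf(e_hf_tz, e_hf_qz)
        + cbs_correlation(e_corr_tz, e_corr_qz)
        + (e_ccsdt_dz - e_mp2_dz)
        + g_solv
    )


# ---------------------------------------------------------------------------
# fit target assembly and linear Fourier refit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConformerRecord:
    """One scan point: pseudorotation phase, dihedrals, energy components.

    Energies in kcal/mol: QM gas-phase total, QM solvation energy, MM
    energy with the fitted torsions removed, and MM solvation energy.
    """

    P: float
    dihedral_values: Mapping[str, float]  # instance id -> degrees
    e_qm_gas: float
    g_solv_qm: float
    e_mm_nontorsion: float
    g_solv_mm: float

    def __post_init__(self) -> None:
        for v in (self.e_qm_gas, self.g_solv_qm, self.e_mm_nontorsion, self.g_solv_mm):
            if not math.isfinite(v):
                raise ValueError("energy components must be finite")


def fit_target(records: Sequence[ConformerRecord], shift_min_to_zero: bool = True) -> np.ndarray:
    """Per-conformer residual profile the torsion fit must reproduce.

    residual = (E_QM_gas + G_solv_QM) - (E_MM_nontorsion + G_solv_MM),
    optionally shifted so its minimum is zero (reporting convention; the
    fit itself is gauge-invariant because an offset is always fitted).
    """
    res = np.array(
        [(r.e_qm_gas + r.g_solv_qm) - (r.e_mm_nontorsion + r.g_solv_mm) for r in records]
    )
    if shift_min_to_zero and len(res):
        res = res - res.min()
    return res


@dataclass(frozen=True)
class FittedTypeSpec:
    """Skeleton of one torsion type to fit: free amplitudes, fixed phases.

    `instances` names the keys of ConformerRecord.dihedral_values whose
    angles are instances of this type (all are summed per conformer).
    Phases default to 0 deg for every periodicity; fitted amplitudes are
    signed, and a negative amplitude is reported as a positive one with
    phase 180 deg.
    """

    atom_types: tuple[str, str, str, str]
    instances: tuple[str, ...]
    periodicities: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self) -> None:
        if not self.instances:
            raise ValueError("at least one dihedral instance required")
        if any(not 1 <= n <= 6 for n in self.periodicities):
            raise ValueError("periodicities must be in 1..6")


@dataclass
class FitSpec:
    fitted_types: list[FittedTypeSpec]
    weights: np.ndarray | None = None  # per-conformer, nonnegative
    include_offset: bool = True
    boltzmann_temperature: float | None = None  # K; down-weights high energies


@dataclass
class FitResult:
    torsion_types: list[TorsionType]
    offset: float
    amplitudes: dict[tuple[tuple[str, str, str, str], int], float]
    rmse: float
    residuals: np.ndarray
    condition_number: float
    metadata: dict


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""


def _design_matrix(records: Sequence[ConformerRecord], spec: FitSpec):
    cols = []
    labels = []
    for ft in spec.fitted_types:
        phis = np.array(
            [[r.dihedral_values[inst] for inst in ft.instances] for r in records]
        )  # (n_rec, n_inst)
        for n in ft.periodicities:
            col = np.sum(1.0 + np.cos(np.radians(n * phis)), axis=1)
            cols.append(col)
            labels.append((tuple(ft.atom_types), n))
    X = np.column_stack(cols)
    if spec.include_offset:
        X = np.column_stack([X, np.ones(len(records))])
        labels.append(("offset", 0))
    return X, labels


def fit_fourier(records: Sequence[ConformerRecord], spec: FitSpec) -> FitResult:
    """Weighted linear least-squares refit of torsion amplitudes.

    With phases fixed at 0/180 deg the model is linear in the Vn/2
    amplitudes; contributions of all instances of a fitted type are
    summed per conformer.  The target is `fit_target(records)`.

    Raises
    ------
    RankDeficientError
        If the design matrix is rank deficient (collinear columns named).
    ValueError
        If there are fewer conformers than free parameters.
    """
    y = fit_target(records, shift_min_to_zero=False)
    X, labels = _design_matrix(records, spec)
    n_rec, n_par = X.shape
    if n_rec < n_par:
        raise ValueError(f"{n_rec} conformers < {n_par} free parameters")

    w = np.ones(n_rec) if spec.weights is None else np.asarray(spec.weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if spec.boltzmann_temperature is not None:
        rt = 1.987204e-3 * spec.boltzmann_temperature
        w = w * np.exp(-(y - y.min()) / rt)
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw

    s = np.linalg.svd(Xw, compute_uv=False)
    if s[0] == 0 or s[-1] / s[0] < 1e-10:
        _, _, vt = np.linalg.svd(Xw)
        null = np.abs(vt[-1])
        bad = [labels[i] for i in np.nonzero(null > 0.3)[0]]
        raise RankDeficientError(f"rank-deficient design; collinear columns: {bad}")

    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    pred = X @ beta
    resid = y - pred
    rmse = float(np.sqrt(np.average(resid**2, weights=w)))

    amplitudes: dict = {}
    torsion_types = []
    i = 0
    for ft in spec.fitted_types:
        terms = []
        for n in ft.periodicities:
            a = float(beta[i])
            amplitudes[(tuple(ft.atom_types), n)] = a
            phase = 0.0 if a >= 0 else 180.0
            terms.append(FourierTerm(periodicity=n, half_barrier=abs(a), phase=phase))
            i += 1
        torsion_types.append(TorsionType(tuple(ft.atom_types), tuple(terms)))
    offset = float(beta[-1]) if spec.include_offset else 0.0
    return FitResult(
        torsion_types=torsion_types,
        offset=offset,
        amplitudes=amplitudes,
        rmse=rmse,
        residuals=resid,
        condition_number=float(s[0] / s[-1]),
        metadata={
            "hf_cbs_scheme": "two-point X^-5 power law (TZ,QZ)",
            "corr_cbs_scheme": "two-point X^-3 (TZ,QZ)",
            "phases": "fixed {0, 180} deg; negative amplitudes folded into phase 180",
        },
    )


# ---------------------------------------------------------------------------
# targeted empirical adjustment of one minimum
# ---------------------------------------------------------------------------


class AdjustmentInfeasibleError(ValueError):
    """The requested energy change cannot be represented; carries a report."""

    def __init__(self, message: str, report: dict):
        super().__init__(message)
        self.report = report


@dataclass
class AdjustmentResult:
    torsion_type: TorsionType
    achieved_delta_target: float
    achieved_delta_hold: float
    delta_terms: tuple[FourierTerm, ...]


def empirical_adjustment(
    tt: TorsionType,
    target_center: float,
    delta_e: float,
    *,
    hold_center: float | None = None,
    window_halfwidth: float = 10.0,
    periodicities: Iterable[int] = (1, 2, 3),
    n_points: int = 5,
    tolerance: float = 0.1,
) -> AdjustmentResult:
    """Shift the energy of one region of a torsion profile by ``delta_e``.

    Used for the final empirical touch of a refit: e.g. stabilizing the
    north pseudorotation minimum slightly without disturbing the south
    one.  A least-squares correction over the allowed periodicities is
    solved so the energy (relative to the hold region, the natural gauge
    for torsion profiles) changes by `delta_e` across a window around
    `target_center` and by ~0 around `hold_center` (default: the current
    global minimum away from the target window).

    Raises
    ------
    AdjustmentInfeasibleError
        If the achieved changes deviate from the request by more than
        `tolerance` * |delta_e|.
    """
    if not math.isfinite(delta_e):
        raise ValueError("delta_e must be finite")
    if delta_e == 0.0:
        return AdjustmentResult(tt, 0.0, 0.0, ())

    if hold_center is None:
        grid = np.arange(0.0, 360.0, 1.0)
        e = dihedral_energy(tt, grid)
        away = np.abs((grid - target_center + 180.0) % 360.0 - 180.0) > 60.0
        if not np.any(away):
            raise ValueError("no grid points away from target window")
        hold_center = float(grid[away][np.argmin(e[away])])

    ns = tuple(periodicities)
    pts_t = target_center + np.linspace(-window_halfwidth, window_halfwidth, n_points)
    pts_h = hold_center + np.linspace(-window_halfwidth, window_halfwidth, n_points)

    def basis(phi):
        phi = np.atleast_1d(phi)
        return np.column_stack([np.cos(np.radians(n * phi)) for n in ns])

    b_h0 = basis(np.array([hold_center]))[0]
    rows = np.vstack([basis(pts_t) - b_h0, basis(pts_h) - b_h0])
    rhs = np.concatenate([np.full(n_points, delta_e), np.zeros(n_points)])
    coef, *_ = np.linalg.lstsq(rows, rhs, rcond=None)

    delta_terms = tuple(
        FourierTerm(periodicity=n, half_barrier=abs(a), phase=0.0 if a >= 0 else 180.0)
        for n, a in zip(ns, coef)
        if abs(a) > 1e-12
    )
    new_tt = replace(tt, terms=tt.terms + delta_terms)

    def rel_change(phi):
        d = dihedral_energy(new_tt, phi) - dihedral_energy(tt, phi)
        d0 = dihedral_energy(new_tt, hold_center) - dihedral_energy(tt, hold_center)
        return d - d0

    ach_t = float(rel_change(target_center))
    ach_h = float(np.max(np.abs(rel_change(pts_h))))
    tol = tolerance * abs(delta_e)
    if abs(ach_t - delta_e) > tol or ach_h > tol:
        raise AdjustmentInfeasibleError(
            "requested adjustment not representable with periodicities "
            f"{ns}: target achieved {ach_t:+.4f} (requested {delta_e:+.4f}), "
            f"hold-region drift {ach_h:.4f}",
            report={
                "achieved_delta_target": ach_t,
                "requested_delta": delta_e,
                "hold_drift": ach_h,
                "periodicities": ns,
            },
        )
    return AdjustmentResult(new_tt, ach_t, ach_h, delta_terms)
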