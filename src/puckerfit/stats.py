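"""Trajectory-level conformational statistics.

Per-residue north-pucker populations (%N), potentials of mean force of
the pseudorotation phase, and backbone substate (BI/BII, alpha/gamma)
classification and bookkeeping.  Input is a rectangular frames x residues
table of backbone angles and pseudorotation phases (`DihedralSeries`),
typically pre-extracted from a trajectory.

The PMF of an angle theta uses ``PMF = -RT ln(n_bin / n_max)`` on a
fixed-width histogram (default 3 deg bins); confidence intervals on bin
counts are +-1.96 x SEM with the SEM estimated by block averaging over
time, which accounts for frame autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pucker import wrap180, wrap360

__all__ = [
    "R_KCAL",
    "DihedralSeries",
    "PmfProfile",
    "percent_N",
    "pmf",
    "rotamer_window",
    "classify_bi_bii",
    "classify_alpha_gamma",
    "substate_populations",
]

#: gas constant, kcal/(mol.K)
R_KCAL = 1.987204e-3

ANGLE_NAMES = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi")

#: tripartite rotamer windows, degrees (half-open)
ROTAMER_WINDOWS = {
    "g+": (0.0, 120.0),
    "t": (120.0, 240.0),
    "g-": (240.0, 360.0),
}


@dataclass
class DihedralSeries:
    """Frames x residues angle series with residue metadata.

    Attributes
    ----------
    P : ndarray (n_frames, n_residues)
        Pseudorotation phase, degrees.
    angles : dict of name -> ndarray (n_frames, n_residues)
        Backbone/glycosidic angles, degrees in [0, 360).
    residues : DataFrame
        One row per residue: chain, resseq, resname.
    frame_spacing_ps : float
        Time between stored frames.
    """

    P: np.ndarray
    angles: dict = field(default_factory=dict)
    residues: pd.DataFrame | None = None
    frame_spacing_ps: float = 10.0

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim == 1:
            self.P = self.P[:, None]
        n_f, n_r = self.P.shape
        for name, arr in self.angles.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n_f, n_r):
                raise ValueError(f"angle series {name!r} is not rectangular")
            self.angles[name] = arr
        if self.residues is None:
            self.residues = pd.DataFrame(
                {"chain": "A", "resseq": np.arange(1, n_r + 1), "resname": "DN"}
            )
        if len(self.residues) != n_r:
            raise ValueError("residue metadata does not match series width")

    @property
    def n_frames(self) -> int:
        return self.P.shape[0]

    @property
    def n_residues(self) -> int:
        return self.P.shape[1]

    def interior_mask(self, exclude_terminal: int) -> np.ndarray:
        """Boolean residue mask dropping N pairs from each end of each chain."""
        mask = np.ones(self.n_residues, dtype=bool)
        if exclude_terminal > 0:
            for _, idx in self.residues.groupby("chain", sort=False).indices.items():
                idx = np.sort(idx)
                mask[idx[:exclude_terminal]] = False
                mask[idx[len(idx) - exclude_terminal:]] = False
        if not mask.any():
            raise ValueError("terminal exclusion leaves no residues")
        return mask

    def to_table(self) -> pd.DataFrame:
        """Tidy long-format table: frame, chain, resseq, P and angle columns."""
        n_f, n_r = self.P.shape
        frames = np.repeat(np.arange(n_f), n_r)
        res = self.residues.iloc[np.tile(np.arange(n_r), n_f)].reset_index(drop=True)
        data = {"frame": frames, "chain": res["chain"], "resseq": res["resseq"],
                "resname": res["resname"], "P": self.P.ravel()}
        for name, arr in self.angles.items():
            data[name] = arr.ravel()
        return pd.DataFrame(data)

    @classmethod
    def from_table(cls, table: pd.DataFrame, frame_spacing_ps: float = 10.0):
        table = table.sort_values(["frame", "chain", "resseq"], kind="stable")
        first = table[table["frame"] == table["frame"].iloc[0]]
        residues = first[["chain", "resseq", "resname"]].reset_index(drop=True)
        n_r = len(residues)
        n_f = len(table) // n_r
        if n_f * n_r != len(table):
            raise ValueError("table is not rectangular in frames x residues")
        angles = {
            name: table[name].to_numpy().reshape(n_f, n_r)
            for name in ANGLE_NAMES
            if name in table.columns
        }
        return cls(
            P=table["P"].to_numpy().reshape(n_f, n_r),
            angles=angles,
            residues=residues,
            frame_spacing_ps=frame_spacing_ps,
        )


def _is_north(P: np.ndarray) -> np.ndarray:
    p = wrap180(P)
    return (p > -90.0) & (p < 90.0)


def percent_N(series: DihedralSeries, exclude_terminal: int = 0):
    """North-pucker population per residue and in aggregate, percent.

    The aggregate averages frames x residues after dropping
    `exclude_terminal` residues from each end of each chain.

    Returns
    -------
    (per_residue, aggregate) : (pd.Series, float)
    """
    if series.n_frames == 0:
        raise ValueError("empty series")
    north = _is_north(series.P)
    per_res = pd.Series(100.0 * north.mean(axis=0), index=series.residues.index)
    mask = series.interior_mask(exclude_terminal)
    aggregate = float(100.0 * north[:, mask].mean())
    return per_res, aggregate


@dataclass
class PmfProfile:
    """PMF of an angular variable on a fixed histogram.

    Empty bins have NaN pmf/CI entries (never clamped to a large number);
    `counts` sums to the number of frames used.
    """

    bin_centers: np.ndarray
    counts: np.ndarray
    pmf: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    temperature: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "count": self.counts,
                "pmf": self.pmf,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def pmf(
    values,
    bin_width: float = 3.0,
    temperature: float = 298.15,
    n_blocks: int = 10,
) -> PmfProfile:
    """PMF of an angle from its histogram: -RT ln(n_bin/n_max).

    Parameters
    ----------
    values : array-like
        Angles in degrees (any wrap; histogrammed on [0, 360)).
    bin_width : float
        Histogram bin width, degrees (must divide 360).
    temperature : float
        Kelvin; RT uses R = 1.987204e-3 kcal/(mol.K).
    n_blocks : int
        Number of equal time blocks for the count SEM (95% CI is
        +-1.96 x SEM); requires the input to be in frame order.
    """
    v = wrap360(np.asarray(values, dtype=float).ravel())
    n_bins = 360.0 / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_width must divide 360")
    n_bins = int(round(n_bins))
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts, _ = np.histogram(v, bins=edges)
    if counts.max() == 0:
        raise ValueError("no data to histogram")
    rt = R_KCAL * temperature
    nmax = counts.max()
    with np.errstate(divide="ignore"):
        vals = -rt * np.log(counts / nmax)
    vals = np.where(counts > 0, vals, np.nan)

    # block-averaged SEM on each bin count
    blocks = np.array_split(v, max(1, n_blocks))
    bc = np.stack([np.histogram(b, bins=edges)[0] * (len(v) / max(len(b), 1)) for b in blocks])
    # bc rows are per-block counts rescaled to the full-series total
    sem = bc.std(axis=0, ddof=1) / np.sqrt(len(blocks)) if len(blocks) > 1 else np.zeros(n_bins)
    half = 1.96 * sem
    with np.errstate(divide="ignore", invalid="ignore"):
        lo = -rt * np.log((counts + half) / nmax)
        hi = -rt * np.log((counts - half) / nmax)
    lo = np.where(counts > 0, lo, np.nan)
    hi = np.where((counts - half) > 0, hi, np.nan)
    return PmfProfile(
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        counts=counts,
        pmf=vals,
        ci_low=lo,
        ci_high=hi,
        temperature=temperature,
    )


def rotamer_window(angle) -> np.ndarray:
    """Map angles (deg) to 'g+' [0,120), 't' [120,240) or 'g-' [240,360)."""
    a = wrap360(np.asarray(angle, dtype=float))
    out = np.where(a < 120.0, "g+", np.where(a < 240.0, "t", "g-"))
    return out


def classify_bi_bii(epsilon, zeta):
    """BI iff epsilon trans and zeta g-; BII iff epsilon g- and zeta trans."""
    scalar = np.ndim(epsilon) == 0
    e = np.atleast_1d(rotamer_window(epsilon))
    z = np.atleast_1d(rotamer_window(zeta))
    out = np.full(e.shape, "other", dtype=object)
    out[(e == "t") & (z == "g-")] = "BI"
    out[(e == "g-") & (z == "t")] = "BII"
    return out[0] if scalar else out


def classify_alpha_gamma(alpha, gamma):
    """'canonical' iff alpha g- and gamma g+; 'g+/t' iff alpha g+ and gamma t."""
    scalar = np.ndim(alpha) == 0
    a = np.atleast_1d(rotamer_window(alpha))
    g = np.atleast_1d(rotamer_window(gamma))
    out = np.full(a.shape, "other", dtype=object)
    out[(a == "g-") & (g == "g+")] = "canonical"
    out[(a == "g+") & (g == "t")] = "g+/t"
    return out[0] if scalar else out


def substate_populations(series: DihedralSeries, exclude_terminal: int = 0):
    """Backbone substate percentages per residue and aggregated.

    Returns
    -------
    (per_residue, aggregate) : (DataFrame, dict)
        Per-residue columns BI/BII/other and canonical/'g+/t'/other-ag
        (percent, each family sums to 100 per residue); the aggregate
        dict averages over interior residues only.
    """
    need = {"epsilon", "zeta", "alpha", "gamma"}
    if not need <= set(series.angles):
        raise ValueError(f"series must carry angles {sorted(need)}")
    ez = classify_bi_bii(series.angles["epsilon"], series.angles["zeta"])
    ag = classify_alpha_gamma(series.angles["alpha"], series.angles["gamma"])
    rows = []
    for j in range(series.n_residues):
        row = {
            "chain": series.residues["chain"].iloc[j],
            "resseq": series.residues["resseq"].iloc[j],
        }
        for lab in ("BI", "BII", "other"):
            row[lab] = 100.0 * np.mean(ez[:, j] == lab)
        for lab in ("canonical", "g+/t"):
            row[f"ag_{lab}"] = 100.0 * np.mean(ag[:, j] == lab)
        row["ag_other"] = 100.0 - row["ag_canonical"] - row["ag_g+/t"]
        rows.append(row)
    per_res = pd.DataFrame(rows)
    mask = series.interior_mask(exclude_terminal)
    agg = {
        lab: float(100.0 * np.mean(ez[:, mask] == lab)) for lab in ("BI", "BII", "other")
    }
    agg.update(
        {
            f"ag_{lab}": float(100.0 * np.mean(ag[:, mask] == lab))
            for lab in ("canonical", "g+/t", "other")
        }
    )
    agg["n_residues"] = int(mask.sum())
    return per_res, agg
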