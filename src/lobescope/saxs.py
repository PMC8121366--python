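"""Small-angle scattering utilities.

Model intensities come from the Debye equation over point scatterers

    I(q) = sum_i sum_j f_i f_j sin(q d_ij) / (q d_ij),      I(0) = (sum_i f_i)^2,

at atom granularity (f = electron count of the element) or residue
granularity (one center per residue at the Cα with f = residue electron
count). No hydration-shell correction is applied; curves are meant for
shape-level comparison and for fitting a scale (+ constant background) to an
experimental curve by weighted least squares.

Real-space quantities follow the standard definitions: Rg as the (optionally
mass-weighted) second moment of the coordinate distribution, P(r) as the
normalized histogram of all pairwise distances with Dmax its support limit,
and the Guinier fit as an iterative linear fit of ln I against q^2 restricted
to the largest low-q window with q*Rg <= 1.3.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.spatial.distance import pdist

from .structio import Structure

__all__ = [
    "ScatteringCurve",
    "DistanceDistribution",
    "GuinierResult",
    "radius_of_gyration",
    "distance_distribution",
    "debye_intensity",
    "guinier_fit",
    "fit_model_to_curve",
    "read_curve",
    "write_curve",
]

# electron counts of neutral atoms
_ELEMENT_ELECTRONS = {"H": 1, "C": 6, "N": 7, "O": 8, "S": 16, "SE": 34, "P": 15}

# residue heavy+H electron counts, from the chemical formula of the residue as
# incorporated in a chain (C,H,N,O,S counts per residue minus water)
_RESIDUE_FORMULAS = {
    "GLY": (2, 3, 1, 1, 0), "ALA": (3, 5, 1, 1, 0), "SER": (3, 5, 1, 2, 0),
    "PRO": (5, 7, 1, 1, 0), "VAL": (5, 9, 1, 1, 0), "THR": (4, 7, 1, 2, 0),
    "CYS": (3, 5, 1, 1, 1), "LEU": (6, 11, 1, 1, 0), "ILE": (6, 11, 1, 1, 0),
    "ASN": (4, 6, 2, 2, 0), "ASP": (4, 5, 1, 3, 0), "GLN": (5, 8, 2, 2, 0),
    "LYS": (6, 12, 2, 1, 0), "GLU": (5, 7, 1, 3, 0), "MET": (5, 9, 1, 1, 1),
    "HIS": (6, 7, 3, 1, 0), "PHE": (9, 9, 1, 1, 0), "ARG": (6, 12, 4, 1, 0),
    "TYR": (9, 9, 1, 2, 0), "TRP": (11, 10, 2, 1, 0),
}
_Z = {"C": 6, "H": 1, "N": 7, "O": 8, "S": 16}


def residue_electrons(name: str) -> float:
    """Electron count of a residue as part of a chain (ALA used for unknowns)."""
    c, h, n, o, s = _RESIDUE_FORMULAS.get(name.upper(), _RESIDUE_FORMULAS["ALA"])
    return c * _Z["C"] + h * _Z["H"] + n * _Z["N"] + o * _Z["O"] + s * _Z["S"]


# average residue masses are handled in the oligomer module; here only electrons


@dataclasses.dataclass
class ScatteringCurve:
    q: np.ndarray  # 1/Angstrom, strictly increasing, >= 0
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must be matching 1-D arrays")
        if np.any(self.q < 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be non-negative and strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must match q in shape")


@dataclasses.dataclass
class DistanceDistribution:
    r: np.ndarray  # bin centers, Angstrom
    p_of_r: np.ndarray  # unit-area density
    dmax: float
    rg: float


@dataclasses.dataclass
class GuinierResult:
    rg: float
    i0: float
    n_points: int
    residual: float
    qrg_max: float


def _scattering_centers(structure: Structure, granularity: str):
    if granularity == "atom":
        atoms = list(structure.iter_atoms(include_hydrogens=False))
        coords = np.asarray([a.coords for _, _, a in atoms])
        f = np.asarray([_ELEMENT_ELECTRONS.get(a.element.upper(), 6) for _, _, a in atoms], dtype=float)
    elif granularity == "residue":
        coords, f = [], []
        for chain in structure.chains:
            for res in chain.residues:
                ca = res.get_atom("CA")
                if ca is not None:
                    coords.append(ca.coords)
                    f.append(residue_electrons(res.name))
        coords = np.asarray(coords)
        f = np.asarray(f, dtype=float)
    else:
        raise ValueError(f"unknown granularity {granularity!r}")
    if len(coords) == 0:
        raise ValueError("structure provides no scattering centers")
    return coords, f


def radius_of_gyration(structure: Structure, weighting: str = "uniform") -> float:
    """Rg (A): sqrt(sum w |r - rbar|^2 / sum w) over heavy atoms.

    ``weighting='uniform'`` treats every atom equally; ``'mass'`` weights by
    (integer) atomic mass via the electron-count proxy table.
    """
    atoms = list(structure.iter_atoms(include_hydrogens=False))
    if not atoms:
        raise ValueError("structure contains no heavy atoms")
    coords = np.asarray([a.coords for _, _, a in atoms])
    if weighting == "uniform":
        w = np.ones(len(coords))
    elif weighting == "mass":
        w = np.asarray([2.0 * _ELEMENT_ELECTRONS.get(a.element.upper(), 6) for _, _, a in atoms])
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    center = (w[:, None] * coords).sum(axis=0) / w.sum()
    return float(np.sqrt((w * ((coords - center) ** 2).sum(axis=1)).sum() / w.sum()))


def distance_distribution(structure: Structure, bin_width: float = 1.0) -> DistanceDistribution:
    """P(r): unit-area histogram of all pairwise heavy-atom distances.

    Rg is recovered from the second moment of P(r): Rg^2 = (1/2) <r^2>_P.
    """
    coords = structure.coordinates(include_hydrogens=False)
    if len(coords) < 2:
        raise ValueError("need at least two atoms for a distance distribution")
    d = pdist(coords)
    dmax = float(d.max())
    n_bins = max(1, int(math.ceil(dmax / bin_width)))
    counts, edges = np.histogram(d, bins=n_bins, range=(0.0, n_bins * bin_width))
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = counts / (counts.sum() * bin_width)
    rg = math.sqrt(0.5 * float((density * centers**2).sum() * bin_width))
    return DistanceDistribution(r=centers, p_of_r=density, dmax=dmax, rg=rg)


def debye_intensity(
    structure: Structure,
    q_grid: np.ndarray,
    granularity: str = "atom",
) -> ScatteringCurve:
    """Debye-equation scattering curve of a structure on ``q_grid`` (1/A)."""
    q = np.asarray(q_grid, dtype=float)
    coords, f = _scattering_centers(structure, granularity)
    if len(coords) == 1:
        return ScatteringCurve(q=q, intensity=np.full_like(q, float(f[0] ** 2)))
    d = pdist(coords)
    ff = np.outer(f, f)
    iu = np.triu_indices(len(f), k=1)
    cross_ff = ff[iu]
    self_term = float((f**2).sum())
    intensity = np.empty_like(q)
    for k, qk in enumerate(q):
        if qk == 0.0:
            intensity[k] = float(f.sum() ** 2)
        else:
            x = qk * d
            intensity[k] = self_term + 2.0 * float((cross_ff * np.sin(x) / x).sum())
    return ScatteringCurve(q=q, intensity=np.clip(intensity, 0.0, None))


def guinier_fit(curve: ScatteringCurve, qrg_max: float = 1.3, min_points: int = 5) -> GuinierResult:
    """Guinier analysis: ln I = ln I0 - (Rg^2/3) q^2 on the low-q window.

    Iterates the window so that q*Rg <= ``qrg_max`` for every point used.
    Raises on non-decaying data (positive slope) or too few admissible points.
    """
    q, intensity = curve.q, curve.intensity
    usable = (q > 0) & (intensity > 0)
    q, intensity = q[usable], intensity[usable]
    if len(q) < min_points:
        raise ValueError(f"need >= {min_points} positive-q, positive-I points")
    n = len(q)
    for _ in range(50):
        slope, icpt = np.polyfit(q[:n] ** 2, np.log(intensity[:n]), 1)
        if slope >= 0:
            raise ValueError("Guinier fit found non-decaying intensity (positive slope)")
        rg = math.sqrt(-3.0 * slope)
        n_new = int(np.searchsorted(q, qrg_max / rg, side="right"))
        n_new = max(min_points, min(n_new, len(q)))
        if n_new == n:
            break
        n = n_new
    resid = float(np.sqrt(np.mean((np.log(intensity[:n]) - (icpt + slope * q[:n] ** 2)) ** 2)))
    return GuinierResult(rg=rg, i0=float(math.exp(icpt)), n_points=n,
                         residual=resid, qrg_max=float(q[n - 1] * rg))


def fit_model_to_curve(
    model: ScatteringCurve,
    experiment: ScatteringCurve,
    fit_constant: bool = True,
) -> tuple[float, float, float]:
    """Least-squares scale (and constant background) of a model onto data.

    Minimizes chi^2 = sum ((s*I_m + c - I_e) / sigma)^2 / (N - dof); the model
    is linearly interpolated onto the experimental grid over the overlapping
    q range. Returns (scale, constant, reduced chi).
    """
    if experiment.sigma is None:
        raise ValueError("experimental curve must carry uncertainties")
    lo = max(model.q[0], experiment.q[0])
    hi = min(model.q[-1], experiment.q[-1])
    mask = (experiment.q >= lo) & (experiment.q <= hi) & (experiment.sigma > 0)
    if mask.sum() < 3:
        raise ValueError("model and experiment share too few q points")
    qe = experiment.q[mask]
    ie = experiment.intensity[mask]
    se = experiment.sigma[mask]
    im = np.interp(qe, model.q, model.intensity)

    if fit_constant:
        design = np.column_stack([im / se, 1.0 / se])
    else:
        design = (im / se)[:, None]
    coeffs, *_ = np.linalg.lstsq(design, ie / se, rcond=None)
    scale = float(coeffs[0])
    const = float(coeffs[1]) if fit_constant else 0.0
    dof = max(1, mask.sum() - (2 if fit_constant else 1))
    chi2 = float((((scale * im + const - ie) / se) ** 2).sum() / dof)
    return scale, const, chi2


def read_curve(path, q_unit: str = "A^-1") -> ScatteringCurve:
    """Read a 3-column (q, I[, sigma]) whitespace/CSV text curve."""
    data = np.loadtxt(path, comments=("#", ";"), delimiter=None)
    if data.ndim == 1:
        data = data[None, :]
    q = data[:, 0]
    if q_unit in ("nm^-1", "nm-1"):
        q = q / 10.0
    elif q_unit not in ("A^-1", "A-1"):
        raise ValueError(f"unknown q unit {q_unit!r}")
    sigma = data[:, 2] if data.shape[1] > 2 else None
    return ScatteringCurve(q=q, intensity=data[:, 1], sigma=sigma)


def write_curve(curve: ScatteringCurve, path) -> None:
    cols = [curve.q, curve.intensity]
    if curve.sigma is not None:
        cols.append(curve.sigma)
    np.savetxt(path, np.column_stack(cols), header="q(A^-1) I sigma"[: 12 + 6 * len(cols)])
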