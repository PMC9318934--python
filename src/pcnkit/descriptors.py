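"""Global structural descriptors of one Cα frame.

The structure half of the per-frame descriptor table:

- ``RG``, ``RGh``, ``RGp``: mass-weighted radius of gyration of all,
  hydrophobic-only and polar-only residues (each about its own barycentre).
- ``AS``: asymmetry index, the relative shape anisotropy kappa^2 of the
  gyration tensor — 0 for spherical symmetry, 1 for collinear points.
- ``MFD``: mass fractal dimension, the least-squares slope of
  log M(r) vs log r where M(r) is the mass within radius r of the
  barycentre (~3 for a compact solid, ~2.5-2.7 for globular proteins).
- ``rho``, ``eps``: mass density and porosity. The molecular envelope is
  the convex hull of the Cα cloud; occupied volume is the union of spheres
  of a probe radius centred on each Cα, estimated by seeded Monte-Carlo
  integration inside the hull. rho = total mass / hull volume;
  eps = 1 − occupied fraction.
- ``corrHBKD``: hydrophobic-core correlation, the Pearson correlation of
  residue hydropathy with distance from the barycentre; negative when
  hydrophobic residues bury toward the core.

All functions accept either a :class:`~pcnkit.structure_io.StructureFrame`
or a raw (n, 3) coordinate array (unit masses assumed in the latter case).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, cKDTree
from scipy.stats import pearsonr

from .constants import HYDROPHOBIC, POLAR
from .structure_io import StructureFrame

__all__ = [
    "StructuralDescriptors",
    "StructConfig",
    "radius_of_gyration",
    "gyration_tensor_shape",
    "mass_fractal_dimension",
    "density_and_porosity",
    "hydrophobic_core_correlation",
    "compute_structural_descriptors",
]


def _coords_masses(obj, subset: str = "all") -> tuple[np.ndarray, np.ndarray]:
    if isinstance(obj, StructureFrame):
        coords, masses = obj.coords, obj.masses
        if subset != "all":
            want = HYDROPHOBIC if subset == "hydrophobic" else POLAR
            mask = obj.hp_classes == want
            coords, masses = coords[mask], masses[mask]
    else:
        coords = np.asarray(obj, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("expected an (n, 3) coordinate array")
        if subset != "all":
            raise ValueError("subsets require a StructureFrame")
        masses = np.ones(len(coords))
    return coords, masses


def radius_of_gyration(obj, subset: str = "all",
                       masses: np.ndarray | None = None) -> float:
    """Mass-weighted RG about the (subset) barycentre, in Å."""
    coords, m = _coords_masses(obj, subset)
    if masses is not None:
        m = np.asarray(masses, dtype=float)
    if len(coords) == 0:
        raise ValueError(f"empty subset {subset!r}")
    com = np.average(coords, axis=0, weights=m)
    r2 = ((coords - com) ** 2).sum(axis=1)
    return float(np.sqrt(np.average(r2, weights=m)))


def gyration_tensor_shape(obj, masses: np.ndarray | None = None) -> float:
    """Relative shape anisotropy kappa^2 of the gyration tensor.

    kappa^2 = 1 − 3 (l1 l2 + l2 l3 + l3 l1) / (l1 + l2 + l3)^2 over the
    gyration-tensor eigenvalues; bounded in [0, 1].
    """
    coords, m = _coords_masses(obj)
    if masses is not None:
        m = np.asarray(masses, dtype=float)
    if len(coords) < 3:
        raise ValueError("need at least 3 points")
    com = np.average(coords, axis=0, weights=m)
    x = coords - com
    S = (m[:, None, None] * x[:, :, None] * x[:, None, :]).sum(axis=0) / m.sum()
    lam = np.linalg.eigvalsh(S)
    tr = lam.sum()
    if tr <= 0:
        raise ValueError("degenerate (coincident) point set")
    pair = lam[0] * lam[1] + lam[1] * lam[2] + lam[2] * lam[0]
    return float(np.clip(1.0 - 3.0 * pair / tr**2, 0.0, 1.0))


def mass_fractal_dimension(
    obj,
    fit_range: tuple[float, float] | None = None,
    n_radii: int = 20,
    masses: np.ndarray | None = None,
) -> float:
    """Slope of log M(r) vs log r about the barycentre.

    ``fit_range`` defaults to (4 Å, RG); radii are log-spaced. Radii
    enclosing no mass are dropped; at least 3 usable radii are required.
    """
    coords, m = _coords_masses(obj)
    if masses is not None:
        m = np.asarray(masses, dtype=float)
    com = np.average(coords, axis=0, weights=m)
    r = np.linalg.norm(coords - com, axis=1)
    if fit_range is None:
        fit_range = (4.0, radius_of_gyration(obj, masses=masses))
    r_lo, r_hi = fit_range
    if not 0 < r_lo < r_hi:
        raise ValueError("invalid fit range")
    radii = np.geomspace(r_lo, r_hi, n_radii)
    order = np.argsort(r)
    cum_mass = np.cumsum(m[order])
    # mass enclosed at each radius via sorted distances
    idx = np.searchsorted(r[order], radii, side="right")
    M = np.where(idx > 0, cum_mass[np.clip(idx - 1, 0, None)], 0.0)
    # a radius is usable when it encloses some but not all of the mass;
    # saturated radii carry no scaling information
    ok = (M > 0) & (M < m.sum())
    if ok.sum() < 3:
        raise ValueError("fewer than 3 usable radii in fit range")
    slope = np.polyfit(np.log(radii[ok]), np.log(M[ok]), 1)[0]
    return float(slope)


@dataclass
class StructConfig:
    """Settings for the structure-descriptor block."""

    probe_radius: float = 3.0       # Å, residue sphere for porosity
    mc_samples: int = 100_000       # Monte-Carlo points inside the hull
    mc_seed: int = 0                # fixed so eps is reproducible
    mfd_fit_range: tuple[float, float] | None = None  # None -> (4 Å, RG)
    mfd_n_radii: int = 20


def density_and_porosity(
    obj,
    probe_radius: float = 3.0,
    mc_samples: int = 100_000,
    seed: int = 0,
    masses: np.ndarray | None = None,
) -> tuple[float, float]:
    """(rho, eps): mass density over the hull and void fraction.

    Monte-Carlo points are drawn uniformly in the hull's bounding box and
    rejected outside the hull; a point counts as occupied when it lies
    within ``probe_radius`` of any Cα. The seed fixes the estimate.
    """
    coords, m = _coords_masses(obj)
    if masses is not None:
        m = np.asarray(masses, dtype=float)
    if len(coords) < 4:
        raise ValueError("need at least 4 points for a 3-D hull")
    try:
        hull = ConvexHull(coords)
    except Exception as exc:  # qhull degenerate input
        raise ValueError(f"degenerate convex hull: {exc}") from exc
    rho = float(m.sum() / hull.volume)

    rng = np.random.default_rng(seed)
    delaunay = Delaunay(coords[hull.vertices])
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    tree = cKDTree(coords)
    inside_total = 0
    covered = 0
    batch = 50_000
    while inside_total < mc_samples:
        pts = rng.uniform(lo, hi, size=(batch, 3))
        pts = pts[delaunay.find_simplex(pts) >= 0]
        if len(pts) == 0:
            continue
        take = pts[: mc_samples - inside_total]
        d, _ = tree.query(take, k=1)
        covered += int((d <= probe_radius).sum())
        inside_total += len(take)
    eps = 1.0 - covered / inside_total
    return rho, float(eps)


def hydrophobic_core_correlation(frame: StructureFrame) -> float:
    """Pearson correlation of Kyte-Doolittle value with radial distance."""
    if len(frame) < 3:
        raise ValueError("need at least 3 residues")
    coords, m, kd = frame.coords, frame.masses, frame.kd_values
    com = np.average(coords, axis=0, weights=m)
    r = np.linalg.norm(coords - com, axis=1)
    if np.std(kd) == 0 or np.std(r) == 0:
        raise ValueError("zero variance in hydropathy or radial distance")
    return float(pearsonr(kd, r).statistic)


@dataclass
class StructuralDescriptors:
    """The eight structure-block descriptors of one frame."""

    RG: float
    RGh: float
    RGp: float
    rho: float
    MFD: float
    eps: float
    AS: float
    corrHBKD: float

    def as_dict(self) -> dict[str, float]:
        return {
            "RG": self.RG, "RGh": self.RGh, "RGp": self.RGp,
            "corrHBKD": self.corrHBKD, "rho": self.rho,
            "MFD": self.MFD, "eps": self.eps, "AS": self.AS,
        }


def compute_structural_descriptors(
    frame: StructureFrame, config: StructConfig | None = None
) -> StructuralDescriptors:
    """All eight descriptors for one frame under one configuration."""
    cfg = config or StructConfig()
    rho, eps = density_and_porosity(
        frame, cfg.probe_radius, cfg.mc_samples, cfg.mc_seed
    )
    return StructuralDescriptors(
        RG=radius_of_gyration(frame),
        RGh=radius_of_gyration(frame, "hydrophobic"),
        RGp=radius_of_gyration(frame, "polar"),
        rho=rho,
        MFD=mass_fractal_dimension(frame, cfg.mfd_fit_range, cfg.mfd_n_radii),
        eps=eps,
        AS=gyration_tensor_shape(frame),
        corrHBKD=hydrophobic_core_correlation(frame),
    )
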