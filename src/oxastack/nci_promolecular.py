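"""Promolecular electron density, reduced density gradient and sign(lambda2)rho.

The promolecular density is the sum of unrelaxed spherical free-atom
densities, each modelled as a short sum of exponential shells,

    rho_A(r) = sum_i c_i * exp(-r / zeta_i)        (c in a.u., zeta in bohr),

which admits fully analytic gradients and Hessians.  The reduced density
gradient

    s = |grad rho| / (2 (3 pi^2)^{1/3} rho^{4/3})

is small where weak interactions flatten the density between molecules; the
sign of the middle Hessian eigenvalue lambda2 distinguishes attraction
(lambda2 < 0) from steric repulsion (lambda2 > 0), so the pair
(sign(lambda2) rho, s) is the standard 2-D NCI diagnostic.

Everything internal is in atomic units (bohr, a.u. density); the public API
takes coordinates and grid geometry in angstroms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import BOHR_PER_ANGSTROM, VolumetricGrid, write_cube
from .structure_io import AtomSite

__all__ = [
    "AtomicDensityModel", "NCIResult", "PROMOLECULAR_MODEL",
    "promolecular_field", "rdg", "signed_lambda2", "compute_nci",
    "default_grid", "nci_outputs", "symmetric_eigenvalues_3x3",
]

RDG_PREFACTOR = 2.0 * (3.0 * np.pi ** 2) ** (1.0 / 3.0)
DENSITY_FLOOR = 1e-30   # a.u., applied before the 4/3 power

# Three-term exponential fits (c_i, zeta_i) of spherically averaged free-atom
# densities, H..Ar; version 1 of the shipped table.  zeta in bohr, c in a.u.
_SHELLS_V1: dict[str, tuple[tuple[float, float], ...]] = {
    "H":  ((0.2815, 0.5288),),
    "He": ((2.437, 0.3379),),
    "Li": ((11.84, 0.1912), (0.06332, 0.9992)),
    "Be": ((31.34, 0.1390), (0.3694, 0.6945)),
    "B":  ((67.82, 0.1059), (0.8527, 0.5300)),
    "C":  ((120.2, 0.0884), (1.172, 0.5480)),
    "N":  ((190.9, 0.0767), (2.247, 0.4532)),
    "O":  ((289.5, 0.0669), (2.879, 0.3974)),
    "F":  ((406.3, 0.0608), (3.049, 0.3994)),
    "Ne": ((561.3, 0.0549), (6.984, 0.3447)),
    "Na": ((760.8, 0.0496), (22.42, 0.2511), (0.06358, 1.0236)),
    "Mg": ((1016.0, 0.0449), (37.17, 0.2150), (0.3331, 0.8371)),
    "Al": ((1319.0, 0.0411), (57.95, 0.1874), (0.8878, 0.6613)),
    "Si": ((1658.0, 0.0382), (87.16, 0.1654), (0.7888, 0.5819)),
    "P":  ((2042.0, 0.0358), (115.7, 0.1509), (1.465, 0.5256)),
    "S":  ((2501.0, 0.0335), (158.0, 0.1369), (2.170, 0.4738)),
    "Cl": ((3024.0, 0.0315), (205.5, 0.1259), (3.369, 0.4285)),
    "Ar": ((3625.0, 0.0296), (260.0, 0.1168), (5.211, 0.3944)),
}


@dataclass
class AtomicDensityModel:
    """Per-element exponential shells; all coefficients and decays positive."""

    shells: dict[str, tuple[tuple[float, float], ...]]
    version: str = "v1"

    def __post_init__(self) -> None:
        for el, terms in self.shells.items():
            for c, z in terms:
                if c <= 0 or z <= 0:
                    raise ValueError(f"non-positive shell parameter for {el}")

    def __contains__(self, element: str) -> bool:
        return element in self.shells

    def atom_density(self, element: str, r_bohr) -> np.ndarray:
        """Spherical free-atom density rho_A(r), r in bohr."""
        terms = self.shells[element]
        r = np.asarray(r_bohr, dtype=float)
        rho = np.zeros_like(r)
        for c, z in terms:
            rho += c * np.exp(-r / z)
        return rho


PROMOLECULAR_MODEL = AtomicDensityModel(_SHELLS_V1)


def _check_elements(atoms: list[AtomSite], model: AtomicDensityModel) -> None:
    missing = sorted({a.element for a in atoms} - set(model.shells))
    if missing:
        raise ValueError(
            f"no promolecular shell parameters for element(s): {', '.join(missing)}")


def promolecular_field(atoms: list[AtomSite], points_ang: np.ndarray,
                       model: AtomicDensityModel = PROMOLECULAR_MODEL,
                       chunk: int = 200_000
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """rho, grad rho and Hessian of the promolecular density at given points.

    ``points_ang``: (N, 3) in angstroms.  Returns ``rho`` (N,), ``grad``
    (N, 3) and ``hess`` (N, 3, 3), all in atomic units, computed analytically
    shell by shell (no finite differences).
    """
    _check_elements(atoms, model)
    pts = np.asarray(points_ang, dtype=float).reshape(-1, 3) * BOHR_PER_ANGSTROM
    centers = np.array([a.cart for a in atoms], dtype=float) * BOHR_PER_ANGSTROM
    n = pts.shape[0]
    rho = np.zeros(n)
    grad = np.zeros((n, 3))
    hess = np.zeros((n, 3, 3))
    eye = np.eye(3)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        p = pts[lo:hi]
        for a, center in zip(atoms, centers):
            dvec = p - center                     # (m, 3)
            r = np.linalg.norm(dvec, axis=1)
            r = np.maximum(r, 1e-12)
            u = dvec / r[:, None]
            uu = u[:, :, None] * u[:, None, :]    # (m, 3, 3)
            for c, z in model.shells[a.element]:
                e = c * np.exp(-r / z)
                f1 = -e / z                       # d rho / d r
                f2 = e / z ** 2
                rho[lo:hi] += e
                grad[lo:hi] += f1[:, None] * u
                hess[lo:hi] += (f2[:, None, None] * uu
                                + (f1 / r)[:, None, None] * (eye[None] - uu))
    return rho, grad, hess


def rdg(rho: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """Reduced density gradient s = |grad rho| / (2 (3 pi^2)^(1/3) rho^(4/3))."""
    rho_f = np.maximum(np.asarray(rho, dtype=float), DENSITY_FLOOR)
    gnorm = np.linalg.norm(np.asarray(grad, dtype=float), axis=-1)
    return gnorm / (RDG_PREFACTOR * rho_f ** (4.0 / 3.0))


def symmetric_eigenvalues_3x3(h: np.ndarray) -> np.ndarray:
    """Closed-form (trigonometric) eigenvalues of symmetric 3x3 matrices.

    ``h``: (..., 3, 3).  Returns eigenvalues sorted ascending, shape (..., 3).
    """
    h = np.asarray(h, dtype=float)
    q = np.trace(h, axis1=-2, axis2=-1) / 3.0
    ident = np.broadcast_to(np.eye(3), h.shape)
    b = h - q[..., None, None] * ident
    p2 = np.einsum("...ij,...ij->...", b, b) / 6.0
    p = np.sqrt(np.maximum(p2, 0.0))
    # det(B) / (2 p^3), clipped into arccos domain; p == 0 => triple eigenvalue
    safe_p = np.where(p > 0, p, 1.0)
    detb = np.linalg.det(b)
    rarg = np.clip(detb / (2.0 * safe_p ** 3), -1.0, 1.0)
    phi = np.arccos(rarg) / 3.0
    lam1 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    lam3 = q + 2.0 * p * np.cos(phi)
    lam2 = 3.0 * q - lam1 - lam3
    lams = np.stack([lam1, lam2, lam3], axis=-1)
    degenerate = p == 0
    if np.any(degenerate):
        lams[degenerate] = q[degenerate][..., None]
    return np.sort(lams, axis=-1)


def signed_lambda2(rho: np.ndarray, hess: np.ndarray,
                   tie_tol: float = 1e-30) -> np.ndarray:
    """sign(lambda2) * rho, with lambda2 the middle Hessian eigenvalue.

    |lambda2| below ``tie_tol`` counts as degenerate and maps to 0.
    """
    lam2 = symmetric_eigenvalues_3x3(hess)[..., 1]
    sign = np.sign(lam2)
    sign[np.abs(lam2) < tie_tol] = 0.0
    return sign * np.asarray(rho, dtype=float)


@dataclass
class NCIResult:
    """Grids of rho, s and sign(lambda2) rho plus the 2-D scatter pairs."""

    rho: VolumetricGrid
    rdg: VolumetricGrid
    signed: VolumetricGrid
    rho_cutoff: float
    scatter: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.scatter is None:
            mask = self.rho.values.ravel() <= self.rho_cutoff
            self.scatter = pd.DataFrame({
                "signed_rho": self.signed.values.ravel()[mask],
                "rdg": self.rdg.values.ravel()[mask],
            })


def default_grid(atoms: list[AtomSite], margin: float = 3.0,
                 spacing: float = 0.15) -> VolumetricGrid:
    """Bounding box of ``atoms`` + ``margin`` A, regular ``spacing`` A grid."""
    coords = np.array([a.cart for a in atoms], dtype=float)
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    dims = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
    axes = np.eye(3) * spacing
    return VolumetricGrid(lo, axes, np.zeros(dims))


def compute_nci(atoms: list[AtomSite], grid: VolumetricGrid | None = None,
                model: AtomicDensityModel = PROMOLECULAR_MODEL,
                rho_cutoff: float = 0.05, margin: float = 3.0,
                spacing: float = 0.15) -> NCIResult:
    """Full promolecular NCI evaluation on a grid (default: auto box)."""
    grid = grid or default_grid(atoms, margin=margin, spacing=spacing)
    rho, grad, hess = promolecular_field(atoms, grid.points(), model)
    s = rdg(rho, grad)
    signed = signed_lambda2(rho, hess)
    return NCIResult(rho=grid.like(rho), rdg=grid.like(s),
                     signed=grid.like(signed), rho_cutoff=rho_cutoff)


def nci_outputs(result: NCIResult, prefix, atoms: list[AtomSite] | None = None) -> dict:
    """Write rho/rdg/signed cube files and the scatter CSV; returns paths."""
    from pathlib import Path

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}
    for tag, grid in (("rho", result.rho), ("rdg", result.rdg),
                      ("signed", result.signed)):
        path = prefix.with_name(prefix.name + f"_{tag}.cube")
        write_cube(grid, path, atoms=atoms, comment=f"promolecular {tag}")
        paths[tag] = path
    scatter_path = prefix.with_name(prefix.name + "_scatter.csv")
    result.scatter.to_csv(scatter_path, index=False)
    paths["scatter"] = scatter_path
    return paths
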