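"""Regular volumetric grids and Gaussian-cube-format I/O.

The cube layout is the de-facto standard for volumetric scalar fields in
molecular work: two comment lines, atom count + origin, three axis records,
one line per atom (Z, charge, position), then values with the last (z) index
varying fastest. Positions and axis vectors are stored in bohr; this module
keeps grid geometry in angstroms in memory and converts on write/read.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._elements import atomic_number

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903
ANGSTROM_PER_BOHR = 0.529177210903


@dataclass
class VolumetricGrid:
    """A regular 3-D grid: ``origin`` (A), row-wise ``axes`` (A per step), values.

    ``values[i, j, k]`` sits at ``origin + i*axes[0] + j*axes[1] + k*axes[2]``.
    """

    origin: np.ndarray
    axes: np.ndarray
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("grid values must be a 3-D array")
        if min(self.values.shape) < 2:
            raise ValueError("grid needs at least 2 points along each axis")
        if abs(np.linalg.det(self.axes)) < 1e-12:
            raise ValueError("degenerate grid axes")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def points(self) -> np.ndarray:
        """All grid points as an (N, 3) array in angstroms (C order)."""
        nx, ny, nz = self.dims
        i, j, k = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([i.ravel(), j.ravel(), k.ravel()], axis=1).astype(float)
        return self.origin + idx @ self.axes

    def like(self, values: np.ndarray) -> "VolumetricGrid":
        """A grid with identical geometry but different values."""
        values = np.asarray(values, dtype=float).reshape(self.dims)
        return VolumetricGrid(self.origin.copy(), self.axes.copy(), values)


def _open_text(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_cube(grid: VolumetricGrid, path, atoms=None, comment: str = "oxastack field") -> None:
    """Write ``grid`` to ``path`` in cube format.

    ``atoms`` is an optional sequence with ``element`` and ``cart`` attributes
    (angstroms); cube viewers want at least one atom line, so an empty list is
    written with natoms = 0, which most readers accept.
    """
    atoms = list(atoms or [])
    nx, ny, nz = grid.dims
    b = BOHR_PER_ANGSTROM
    with _open_text(path, "w") as fh:
        fh.write(comment + "\n")
        fh.write("volumetric scalar field\n")
        fh.write(f"{len(atoms):5d} {grid.origin[0]*b:12.6f} {grid.origin[1]*b:12.6f} {grid.origin[2]*b:12.6f}\n")
        for n, axis in zip((nx, ny, nz), grid.axes):
            fh.write(f"{n:5d} {axis[0]*b:12.6f} {axis[1]*b:12.6f} {axis[2]*b:12.6f}\n")
        for a in atoms:
            z = atomic_number(a.element)
            x, y, zc = (np.asarray(a.cart, dtype=float) * b).tolist()
            fh.write(f"{z:5d} {float(z):12.6f} {x:12.6f} {y:12.6f} {zc:12.6f}\n")
        flat = grid.values.reshape(nx * ny, nz)
        for row in flat:
            for start in range(0, nz, 6):
                chunk = row[start:start + 6]
                fh.write("".join(f"{v:14.5E}" for v in chunk) + "\n")


def read_cube(path) -> tuple[VolumetricGrid, list[tuple[int, np.ndarray]]]:
    """Read a cube file back into a :class:`VolumetricGrid`.

    Returns the grid (geometry in angstroms) and a list of
    ``(atomic_number, cart)`` pairs.
    """
    with _open_text(path, "r") as fh:
        fh.readline()
        fh.readline()
        first = fh.readline().split()
        natoms = int(first[0])
        origin = np.array(first[1:4], dtype=float) * ANGSTROM_PER_BOHR
        dims = []
        axes = []
        for _ in range(3):
            parts = fh.readline().split()
            dims.append(int(parts[0]))
            axes.append([float(v) * ANGSTROM_PER_BOHR for v in parts[1:4]])
        atoms = []
        for _ in range(abs(natoms)):
            parts = fh.readline().split()
            atoms.append((int(parts[0]), np.array(parts[2:5], dtype=float) * ANGSTROM_PER_BOHR))
        values = np.array(fh.read().split(), dtype=float)
    nx, ny, nz = dims
    grid = VolumetricGrid(origin, np.array(axes), values.reshape(nx, ny, nz))
    return grid, atoms
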