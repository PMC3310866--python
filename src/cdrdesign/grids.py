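"""Regular 3-D grids and OpenDX scalar I/O.

All maps in this package (occupancy masks, probability density maps) live on
axis-aligned regular grids described by a :class:`GridSpec`.  Grids are written
and read in the OpenDX "regular positions, regular connections" scalar format
understood by PyMOL, VMD and Chimera.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec", "write_dx", "read_dx"]


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned regular grid: origin of the first cell center, uniform
    spacing (Å) and shape (nx, ny, nz)."""

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        if any(n < 1 for n in self.shape):
            raise ValueError(f"grid shape must be positive, got {self.shape}")

    @property
    def n_cells(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 3) array of cell-center coordinates, C-order."""
        ax = [self.origin[d] + self.spacing * np.arange(self.shape[d]) for d in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def index_of(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-cell indices for ``points`` (n, 3).

        Returns (flat_indices, inside_mask); indices are only valid where the
        mask is true.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ijk = np.rint((pts - np.asarray(self.origin)) / self.spacing).astype(int)
        inside = np.all((ijk >= 0) & (ijk < np.asarray(self.shape)), axis=1)
        ijk_c = np.clip(ijk, 0, np.asarray(self.shape) - 1)
        flat = np.ravel_multi_index(tuple(ijk_c.T), self.shape)
        return flat, inside

    @classmethod
    def around(cls, coords: np.ndarray, spacing: float, margin: float) -> "GridSpec":
        """Grid covering the bounding box of ``coords`` plus ``margin`` Å."""
        coords = np.atleast_2d(coords)
        lo = coords.min(axis=0) - margin
        hi = coords.max(axis=0) + margin
        shape = tuple(int(np.ceil((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
        return cls(origin=tuple(float(x) for x in lo), spacing=spacing, shape=shape)


def write_dx(path: str, grid: GridSpec, values: np.ndarray, comment: str = "") -> None:
    """Write a scalar field as an OpenDX file (3 values per line)."""
    vals = np.asarray(values, dtype=float).reshape(grid.shape).ravel()
    nx, ny, nz = grid.shape
    d = grid.spacing
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6f} {:.6f} {:.6f}\n".format(*grid.origin))
        fh.write(f"delta {d:.6f} 0.000000 0.000000\n")
        fh.write(f"delta 0.000000 {d:.6f} 0.000000\n")
        fh.write(f"delta 0.000000 0.000000 {d:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {vals.size} data follows\n")
        for i in range(0, vals.size, 3):
            fh.write(" ".join(f"{v:.10e}" for v in vals[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')


def read_dx(path: str) -> tuple[GridSpec, np.ndarray]:
    """Read a scalar OpenDX file written by :func:`write_dx` (or compatible)."""
    shape = origin = None
    deltas: list[float] = []
    data: list[float] = []
    n_items = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("object 1"):
                shape = tuple(int(x) for x in line.split()[-3:])
            elif line.startswith("origin"):
                origin = tuple(float(x) for x in line.split()[1:4])
            elif line.startswith("delta"):
                deltas.append(max(float(x) for x in line.split()[1:4]))
            elif "data follows" in line:
                n_items = int(line.split()[-3])
            elif line[0] in "-+0123456789" and n_items:
                data.extend(float(x) for x in line.split())
    if shape is None or origin is None or len(deltas) != 3:
        raise ValueError(f"{path}: not a regular-grid DX file")
    if not np.allclose(deltas, deltas[0]):
        raise ValueError(f"{path}: anisotropic spacing unsupported")
    if len(data) != int(np.prod(shape)):
        raise ValueError(f"{path}: expected {np.prod(shape)} values, got {len(data)}")
    grid = GridSpec(origin=origin, spacing=deltas[0], shape=shape)
    return grid, np.asarray(data).reshape(shape)
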