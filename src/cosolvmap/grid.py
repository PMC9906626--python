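"""Axis-aligned voxel lattices and OpenDX scalar-grid I/O.

The analysis discretises the space around the receptor into cubic volume
elements (voxels).  All coordinates are in Angstrom, all energies in
kcal/mol.  Voxel assignment uses half-open intervals ``[lower, upper)``
along each axis so that a point lying exactly on a voxel face belongs to
exactly one voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OUT_OF_BOUNDS",
    "GridSpec",
    "ScalarGrid",
    "read_dx",
    "write_dx",
]


class _OutOfBounds:
    """Sentinel returned by :func:`GridSpec.voxel_index` for points outside the lattice."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "OUT_OF_BOUNDS"

    def __bool__(self) -> bool:
        return False


#: Singleton sentinel for points that fall outside the grid.
OUT_OF_BOUNDS = _OutOfBounds()


@dataclass(frozen=True)
class GridSpec:
    """Geometry of an isotropic, axis-aligned voxel lattice.

    Parameters
    ----------
    origin : array-like of 3 floats
        Cartesian position (Å) of the lower corner of voxel ``(0, 0, 0)``.
    spacing : float
        Edge length (Å) of every cubic voxel.  Default 0.5 Å.
    shape : tuple of 3 ints
        Number of voxels along x, y, z.
    """

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        origin = tuple(float(x) for x in self.origin)
        shape = tuple(int(n) for n in self.shape)
        if len(origin) != 3 or not all(np.isfinite(origin)):
            raise ValueError(f"origin must be 3 finite floats, got {self.origin!r}")
        if len(shape) != 3 or any(n < 1 for n in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape!r}")
        if not (np.isfinite(self.spacing) and self.spacing > 0):
            raise ValueError(f"spacing must be > 0, got {self.spacing!r}")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "spacing", float(self.spacing))
        object.__setattr__(self, "shape", shape)

    # -- geometry -----------------------------------------------------------

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in Å³."""
        return self.spacing**3

    @property
    def upper(self) -> np.ndarray:
        """Upper (exclusive) corner of the lattice in Å."""
        return np.asarray(self.origin) + np.asarray(self.shape) * self.spacing

    @classmethod
    def from_bounds(cls, lower, upper, spacing: float = 0.5) -> "GridSpec":
        """Smallest grid with the given spacing covering ``[lower, upper]``."""
        lower = np.asarray(lower, dtype=float)
        upper = np.asarray(upper, dtype=float)
        if np.any(upper <= lower):
            raise ValueError("upper bound must exceed lower bound on every axis")
        shape = np.ceil((upper - lower) / spacing - 1e-9).astype(int)
        return cls(tuple(lower), spacing, tuple(np.maximum(shape, 1)))

    # -- point <-> voxel ----------------------------------------------------

    def voxel_index(self, point):
        """Voxel containing ``point`` (Å), or :data:`OUT_OF_BOUNDS`.

        Index along axis *a* is ``floor((point_a - origin_a)/spacing)``;
        intervals are half-open, so a point on the upper face of the last
        voxel is out of bounds.
        """
        p = np.asarray(point, dtype=float)
        if p.shape != (3,) or not np.all(np.isfinite(p)):
            raise ValueError(f"point must be 3 finite coordinates, got {point!r}")
        idx = np.floor((p - np.asarray(self.origin)) / self.spacing).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.shape)):
            return OUT_OF_BOUNDS
        return tuple(int(i) for i in idx)

    def voxel_indices(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised voxel assignment.

        Parameters
        ----------
        points : (n, 3) array of finite coordinates in Å.

        Returns
        -------
        idx : (n, 3) int array
            Voxel indices (meaningless rows where ``inside`` is False).
        inside : (n,) bool array
            True where the point lies inside the lattice.
        """
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must have shape (n, 3)")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points contain non-finite coordinates")
        idx = np.floor((pts - np.asarray(self.origin)) / self.spacing).astype(int)
        inside = np.all((idx >= 0) & (idx < np.asarray(self.shape)), axis=1)
        return idx, inside

    def voxel_center(self, index) -> np.ndarray:
        """Cartesian center (Å) of the voxel at ``index``."""
        idx = np.asarray(index, dtype=int)
        if idx.shape != (3,):
            raise ValueError(f"index must be 3 integers, got {index!r}")
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.shape)):
            raise IndexError(f"voxel index {tuple(idx)} outside shape {self.shape}")
        return np.asarray(self.origin) + (idx + 0.5) * self.spacing

    def ravel(self, idx: np.ndarray) -> np.ndarray:
        """Flatten (n, 3) voxel indices to flat C-order indices."""
        idx = np.asarray(idx)
        return np.ravel_multi_index((idx[..., 0], idx[..., 1], idx[..., 2]), self.shape)

    def unravel(self, flat) -> np.ndarray:
        """Inverse of :meth:`ravel`; returns (n, 3) or (3,) indices."""
        return np.stack(np.unravel_index(flat, self.shape), axis=-1)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GridSpec):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, rtol=0, atol=1e-9)
            and abs(self.spacing - other.spacing) < 1e-9
        )

    __hash__ = None  # mutable-ish equality semantics


@dataclass
class ScalarGrid:
    """A scalar field on a :class:`GridSpec` with an explicit defined-mask.

    ``values`` holds one number per voxel (counts or kcal/mol);
    ``defined_mask`` is False where no estimate is available (e.g. a
    zero-count voxel under the masking policy).  Undefined voxels must
    never be read as numbers by downstream operations.
    """

    spec: GridSpec
    values: np.ndarray
    defined_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.spec.shape}"
            )
        if self.defined_mask is None:
            self.defined_mask = np.ones(self.spec.shape, dtype=bool)
        else:
            self.defined_mask = np.asarray(self.defined_mask, dtype=bool)
            if self.defined_mask.shape != self.spec.shape:
                raise ValueError("defined_mask shape does not match grid shape")

    @classmethod
    def full(cls, spec: GridSpec, fill: float = 0.0, defined: bool = True) -> "ScalarGrid":
        return cls(
            spec,
            np.full(spec.shape, fill, dtype=float),
            np.full(spec.shape, defined, dtype=bool),
        )

    @property
    def n_defined(self) -> int:
        return int(self.defined_mask.sum())

    def defined_values(self) -> np.ndarray:
        """Values at defined voxels only (1-D)."""
        return self.values[self.defined_mask]

    def min_defined(self) -> float:
        """Minimum over defined voxels; raises if none are defined."""
        if not self.defined_mask.any():
            raise ValueError("grid has no defined voxels")
        return float(self.values[self.defined_mask].min())

    def value_at(self, index) -> float:
        """Value at a voxel index; raises if the voxel is undefined."""
        idx = tuple(int(i) for i in np.asarray(index).reshape(3))
        if not self.defined_mask[idx]:
            raise ValueError(f"voxel {idx} is undefined")
        return float(self.values[idx])


# ---------------------------------------------------------------------------
# OpenDX scalar-field I/O
#
# Dialect: "object 1 class gridpositions counts nx ny nz", an origin line,
# three delta lines with the spacing on the diagonal, "object 2 class
# gridconnections", then the data in C order (z varies fastest), three
# values per line.  DX has no NaN convention that is portable across
# viewers, so undefined voxels are written as a sentinel value.
# ---------------------------------------------------------------------------

_DX_HEADER_COMMENT = (
    "# OpenDX scalar field written by cosolvmap\n"
    "# data order: x slowest, z fastest (C order); 3 values per line\n"
)


def write_dx(grid: ScalarGrid, path, sentinel_for_undefined: float = 999.0) -> None:
    """Write a :class:`ScalarGrid` as an OpenDX scalar field.

    Undefined voxels are written as ``sentinel_for_undefined`` (default
    999.0); declare the same sentinel on :func:`read_dx` to recover the
    mask.
    """
    spec = grid.spec
    nx, ny, nz = spec.shape
    data = np.where(grid.defined_mask, grid.values, sentinel_for_undefined)
    flat = data.reshape(-1)  # C order: z fastest
    with open(path, "w") as fh:
        fh.write(_DX_HEADER_COMMENT)
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6f} {:.6f} {:.6f}\n".format(*spec.origin))
        fh.write(f"delta {spec.spacing:.6f} 0.000000 0.000000\n")
        fh.write(f"delta 0.000000 {spec.spacing:.6f} 0.000000\n")
        fh.write(f"delta 0.000000 0.000000 {spec.spacing:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {flat.size} data follows\n"
        )
        for i in range(0, flat.size, 3):
            chunk = flat[i : i + 3]
            fh.write(" ".join(f"{v:.8g}" for v in chunk) + "\n")
        fh.write('attribute "dep" string "positions"\n')


class DXParseError(ValueError):
    """Malformed OpenDX file; the message names the offending line."""


def read_dx(path, sentinel_for_undefined: float | None = None) -> ScalarGrid:
    """Parse an OpenDX scalar field written by :func:`write_dx`.

    If ``sentinel_for_undefined`` is given, voxels exactly equal to it are
    re-masked as undefined.
    """
    shape = None
    origin = None
    deltas = []
    data: list[float] = []
    n_items = None
    with open(path) as fh:
        lines = fh.readlines()
    in_data = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if in_data:
            if line.startswith(("attribute", "object", "component", "end")):
                in_data = False
                continue
            try:
                data.extend(float(tok) for tok in line.split())
            except ValueError as exc:
                raise DXParseError(f"line {lineno}: bad data value in {line!r}") from exc
            continue
        if line.startswith("object 1"):
            toks = line.split()
            try:
                shape = tuple(int(t) for t in toks[-3:])
            except ValueError as exc:
                raise DXParseError(f"line {lineno}: bad counts in {line!r}") from exc
        elif line.startswith("origin"):
            toks = line.split()
            if len(toks) != 4:
                raise DXParseError(f"line {lineno}: origin needs 3 coordinates: {line!r}")
            origin = tuple(float(t) for t in toks[1:])
        elif line.startswith("delta"):
            toks = line.split()
            if len(toks) != 4:
                raise DXParseError(f"line {lineno}: delta needs 3 components: {line!r}")
            deltas.append([float(t) for t in toks[1:]])
        elif "data follows" in line:
            toks = line.split()
            try:
                n_items = int(toks[toks.index("items") + 1])
            except (ValueError, IndexError) as exc:
                raise DXParseError(f"line {lineno}: bad items count in {line!r}") from exc
            in_data = True
    if shape is None:
        raise DXParseError("missing 'object 1 class gridpositions' header line")
    if origin is None:
        raise DXParseError("missing 'origin' line")
    if len(deltas) != 3:
        raise DXParseError(f"expected 3 delta lines, found {len(deltas)}")
    d = np.asarray(deltas)
    off = d - np.diag(np.diag(d))
    if np.any(np.abs(off) > 1e-9):
        raise DXParseError("non-diagonal delta lines: only orthogonal isotropic grids supported")
    diag = np.diag(d)
    if not np.allclose(diag, diag[0], rtol=1e-6, atol=0):
        raise DXParseError("anisotropic spacing not supported")
    expected = int(np.prod(shape))
    if n_items is not None and n_items != expected:
        raise DXParseError(
            f"'items {n_items}' disagrees with counts {shape} (= {expected} voxels)"
        )
    if len(data) != expected:
        raise DXParseError(f"found {len(data)} data values, expected {expected}")
    values = np.asarray(data, dtype=float).reshape(shape)
    spec = GridSpec(origin, float(diag[0]), shape)
    mask = None
    if sentinel_for_undefined is not None:
        mask = values != sentinel_for_undefined
    return ScalarGrid(spec, values, mask)
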