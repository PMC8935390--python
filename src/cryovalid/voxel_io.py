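"""Reading and writing density maps (MRC2014) and atomic coordinates.

This module owns the grid-geometry contract used throughout the package:
``VoxelMap.data`` is indexed ``[ix, iy, iz]`` with voxel ``(0, 0, 0)``
centred at ``origin`` (in Å) and neighbouring voxel centres separated by
``pixel_size`` Å along each axis.  Files whose axis order differs from
(x, y, z) are permuted on read; writes always emit MAPC/MAPR/MAPS = (1,2,3)
and mode 2 (float32).

File parsing is delegated to :mod:`gemmi`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelMap",
    "AtomRecord",
    "MapFormatError",
    "MapValidationError",
    "read_map",
    "write_map",
    "read_atoms",
]


class MapFormatError(ValueError):
    """Raised when a map file is malformed (bad header, unsupported mode)."""


class MapValidationError(ValueError):
    """Raised when a map parses but violates a data invariant (NaN/Inf voxels)."""


@dataclass
class VoxelMap:
    """A real-valued density map on a regular orthogonal 3-D grid.

    Attributes
    ----------
    data : ndarray
        Density values, shape ``(nx, ny, nz)``, floating dtype.
    pixel_size : ndarray, shape (3,)
        Voxel spacing in Å along x, y, z.  All components > 0.
    origin : ndarray, shape (3,)
        Position in Å of the centre of voxel (0, 0, 0).
    """

    data: np.ndarray
    pixel_size: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.pixel_size = np.broadcast_to(
            np.asarray(self.pixel_size, dtype=float), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3).copy()
        if self.data.ndim != 3:
            raise ValueError(f"map data must be 3-D, got shape {self.data.shape}")
        if not np.all(self.pixel_size > 0):
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def cell(self) -> np.ndarray:
        """Unit-cell edge lengths in Å (grid length × pixel size per axis)."""
        return np.asarray(self.shape) * self.pixel_size

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.pixel_size))

    def grid_center(self) -> np.ndarray:
        """Geometric centre of the grid in Å (used as default rotation centre)."""
        return self.origin + (np.asarray(self.shape) - 1) / 2.0 * self.pixel_size

    def position_to_index(self, pos: np.ndarray) -> np.ndarray:
        """Map Cartesian positions (Å) to fractional voxel indices."""
        pos = np.asarray(pos, dtype=float)
        return (pos - self.origin) / self.pixel_size

    def copy(self) -> "VoxelMap":
        return VoxelMap(self.data.copy(), self.pixel_size.copy(), self.origin.copy())


@dataclass(frozen=True)
class AtomRecord:
    """One atom: position (Å), occupancy [0,1], isotropic B (Å²), element."""

    position: tuple[float, float, float]
    occupancy: float = 1.0
    b_value: float = 0.0
    element: str = "C"

    def __post_init__(self) -> None:
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy must be in [0,1], got {self.occupancy}")
        if self.b_value < 0:
            raise ValueError(f"b_value must be >= 0, got {self.b_value}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


def read_map(path: str | Path) -> VoxelMap:
    """Read an MRC2014 map, normalizing axis order to (x, y, z).

    Integer modes are promoted to float32.  If the header cell disagrees with
    sampling × pixel size by more than 1e-3 Å the cell is recomputed from the
    pixel size and a warning is logged.  The ORIGIN record takes precedence
    over NXSTART/NYSTART/NZSTART; a disagreement between the two is logged.

    Raises
    ------
    MapFormatError
        On malformed headers or unsupported modes.
    MapValidationError
        If the data block contains NaN or Inf.
    """
    path = Path(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"{path}: not a readable MRC2014 map: {exc}") from None
    mode = m.header_i32(4)
    if mode not in (0, 1, 2, 6):
        raise MapFormatError(f"{path}: unsupported MRC mode {mode}")
    # Normalize file axis order (MAPC/MAPR/MAPS) to (1,2,3) without any
    # symmetry expansion.
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    data = np.array(m.grid, copy=True)
    if not np.isfinite(data).all():
        raise MapValidationError(f"{path}: map contains NaN/Inf voxels")

    cell = np.array([m.grid.unit_cell.a, m.grid.unit_cell.b, m.grid.unit_cell.c])
    angles = (m.grid.unit_cell.alpha, m.grid.unit_cell.beta, m.grid.unit_cell.gamma)
    if not np.allclose(angles, 90.0, atol=1e-3):
        raise MapFormatError(
            f"{path}: non-orthogonal cell angles {angles} are not supported"
        )
    sampling = np.array([m.header_i32(i) for i in (8, 9, 10)], dtype=float)
    sampling[sampling == 0] = np.asarray(data.shape)[sampling == 0]
    pixel_size = cell / sampling
    expected_cell = np.asarray(data.shape) * pixel_size
    if np.any(np.abs(cell - expected_cell) > 1e-3):
        logger.warning(
            "%s: header cell %s != grid extent %s; recomputing cell from pixel size",
            path, cell, expected_cell,
        )

    origin = np.array([m.header_float(i) for i in (50, 51, 52)], dtype=float)
    nstart = np.array([m.header_i32(i) for i in (5, 6, 7)], dtype=float)
    nstart_origin = nstart * pixel_size
    if np.allclose(origin, 0.0) and np.any(nstart != 0):
        origin = nstart_origin
    elif np.any(nstart != 0) and not np.allclose(origin, nstart_origin, atol=1e-3):
        logger.warning(
            "%s: ORIGIN %s disagrees with nstart-derived origin %s; using ORIGIN",
            path, origin, nstart_origin,
        )
    return VoxelMap(np.ascontiguousarray(data, dtype=np.float32), pixel_size, origin)


def write_map(vmap: VoxelMap, path: str | Path) -> None:
    """Write a VoxelMap as MRC2014 mode 2 (float32), P1, axis order (x,y,z)."""
    if not np.isfinite(vmap.data).all():
        raise MapValidationError("refusing to write map with NaN/Inf voxels")
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(vmap.data, dtype=np.float32))
    c = vmap.cell
    m.grid.unit_cell = gemmi.UnitCell(c[0], c[1], c[2], 90.0, 90.0, 90.0)
    m.grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    m.update_ccp4_header()
    for word, val in zip((50, 51, 52), vmap.origin):
        m.set_header_float(word, float(val))
    m.write_ccp4_map(str(path))


def _promote_altlocs(atoms: list[tuple[str, AtomRecord]]) -> list[AtomRecord]:
    """Collapse altloc groups, keeping the highest-occupancy conformer."""
    best: dict[str, AtomRecord] = {}
    order: list[str] = []
    for key, rec in atoms:
        if key not in best:
            best[key] = rec
            order.append(key)
        elif rec.occupancy > best[key].occupancy:
            best[key] = rec
    return [best[k] for k in order]


def read_atoms(path: str | Path) -> list[AtomRecord]:
    """Read ATOM/HETATM records from a PDB or mmCIF file.

    Alternate locations are collapsed to the highest-occupancy conformer.
    Hydrogens are kept if present.  Returns an empty list for a file with no
    atoms.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"{path}: cannot parse coordinates: {exc}") from None
    keyed: list[tuple[str, AtomRecord]] = []
    if len(st) == 0:
        return []
    model = st[0]
    for chain in model:
        for residue in chain:
            for atom in residue:
                rec = AtomRecord(
                    position=(atom.pos.x, atom.pos.y, atom.pos.z),
                    occupancy=float(min(max(atom.occ, 0.0), 1.0)),
                    b_value=float(max(atom.b_iso, 0.0)),
                    element=atom.element.name or "C",
                )
                key = f"{chain.name}/{residue.seqid.num}{residue.name}/{atom.name}"
                keyed.append((key, rec))
    return _promote_altlocs(keyed)


def write_atoms(atoms: list[AtomRecord], path: str | Path,
                b_values: np.ndarray | None = None) -> None:
    """Write atoms as a minimal single-chain PDB file.

    ``b_values`` optionally overrides the B column (e.g. to carry per-atom
    correlation values for visualisation).
    """
    atoms = list(atoms)
    if b_values is None:
        bvals = [a.b_value for a in atoms]
    else:
        bvals = [float(b) for b in np.asarray(b_values)]
    st = gemmi.Structure()
    st.name = "cryovalid"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, (a, b) in enumerate(zip(atoms, bvals), start=1):
        res = gemmi.Residue()
        res.name = "DUM"
        res.seqid = gemmi.SeqId(i, " ")
        at = gemmi.Atom()
        at.name = a.element
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.position)
        at.occ = a.occupancy
        at.b_iso = b if np.isfinite(b) else 0.0
        res.add_atom(at)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
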