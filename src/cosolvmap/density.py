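"""Voxel occupancy counting for chemotype groups and the molecular CoM.

``accumulate`` tallies, for every frame and probe instance, which voxel
each group atom (or the molecular centre of mass) falls in.  The counts
feed the Boltzmann inversion (``free_energy``); the per-observation
atom-voxel/CoM-voxel trace feeds the atomic repartition
(``correction``).  Out-of-bounds observations are never silently
dropped: they are tallied separately.

``N_o`` — the count expected in a voxel if the receptor exerted no
influence — is computed from the bulk probe number density, either
supplied (known v/v concentration) or estimated from a designated bulk
region of the count grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridSpec
from .snapshots import SnapshotSet, compute_com
from .topology import ProbeTopology

__all__ = ["COM", "CountGrid", "ObservationTrace", "accumulate", "expected_count"]

#: Pseudo-group selecting the molecular centre of mass instead of a chemotype.
COM = "COM"

#: Flat-voxel code for an out-of-bounds CoM in a trace record.
TRACE_OOB = -1


@dataclass
class CountGrid:
    """Occupancy counts on a voxel lattice for one chemotype (or the CoM).

    ``multiplicity`` is the number of equivalent atoms pooled into the
    map (e.g. 2 for the two methyl carbons of isopropanol); it scales
    the expected bulk count.
    """

    spec: GridSpec
    counts: np.ndarray
    n_frames: int
    n_instances: int
    multiplicity: int
    group: str
    out_of_bounds: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != self.spec.shape:
            raise ValueError("counts shape does not match grid spec")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        """In-bounds observations (sum over voxels)."""
        return int(self.counts.sum())

    @property
    def n_observations_total(self) -> int:
        """All observations, in and out of bounds."""
        return self.total + self.out_of_bounds


@dataclass
class ObservationTrace:
    """One record per in-bounds atom observation.

    Columns (parallel int arrays): frame index, probe instance index,
    atom index within the topology, flat atom voxel index, flat CoM
    voxel index (:data:`TRACE_OOB` if the CoM left the grid).
    """

    spec: GridSpec
    frame: np.ndarray
    instance: np.ndarray
    atom: np.ndarray
    atom_voxel: np.ndarray
    com_voxel: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.frame)
        for name in ("instance", "atom", "atom_voxel", "com_voxel"):
            if len(getattr(self, name)) != n:
                raise ValueError("trace columns have unequal lengths")

    def __len__(self) -> int:
        return len(self.frame)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frame,
                "instance": self.instance,
                "atom": self.atom,
                "atom_voxel": self.atom_voxel,
                "com_voxel": self.com_voxel,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, spec: GridSpec) -> "ObservationTrace":
        df = pd.read_csv(path)
        return cls(
            spec,
            df["frame"].to_numpy(np.int64),
            df["instance"].to_numpy(np.int64),
            df["atom"].to_numpy(np.int64),
            df["atom_voxel"].to_numpy(np.int64),
            df["com_voxel"].to_numpy(np.int64),
        )


def accumulate(
    snapshots: SnapshotSet,
    topology: ProbeTopology | None,
    group: str,
    spec: GridSpec,
    atoms: list[str] | None = None,
) -> tuple[CountGrid, ObservationTrace]:
    """Count voxel occupancies for a chemotype group or the molecular CoM.

    Parameters
    ----------
    snapshots, topology
        ``topology`` defaults to ``snapshots.topology``.
    group : str
        A chemotype defined in the topology, or :data:`COM` for the
        centre-of-mass map.
    spec : GridSpec
        Analysis lattice.
    atoms : list of atom names, optional
        Restrict a chemotype map to a subset of its member atoms (e.g. a
        single representative atom of a symmetric probe); the
        multiplicity of the returned grid equals the number of atoms
        actually counted.

    Returns
    -------
    (CountGrid, ObservationTrace)
        The trace carries, for every in-bounds observation, the atom's
        voxel and the voxel of the *same instance's* CoM at that frame.
    """
    topology = topology or snapshots.topology
    if snapshots.n_frames < 1 or snapshots.coords.size == 0:
        raise ValueError("empty SnapshotSet")

    F, I = snapshots.n_frames, snapshots.n_instances
    com = compute_com(snapshots.coords, topology)  # (F, I, 3)
    com_idx, com_in = spec.voxel_indices(com.reshape(-1, 3))
    com_flat = np.where(com_in, spec.ravel(np.clip(com_idx, 0, np.array(spec.shape) - 1)), TRACE_OOB)
    com_flat = com_flat.reshape(F, I)

    if group == COM:
        atom_indices = None
    else:
        members = topology.group_atoms(group)
        if atoms is not None:
            bad = [a for a in atoms if a not in members]
            if bad:
                raise KeyError(f"atoms {bad} are not members of chemotype {group!r}")
            members = atoms
        atom_indices = [topology.atom_index(a) for a in members]

    counts = np.zeros(spec.shape, dtype=np.int64)
    frames_col, inst_col, atom_col, avox_col, cvox_col = [], [], [], [], []
    frame_grid, inst_grid = np.meshgrid(np.arange(F), np.arange(I), indexing="ij")

    def _tally(points: np.ndarray, atom_id: int) -> int:
        """points: (F, I, 3) positions of one tracked atom (or the CoM)."""
        idx, inside = spec.voxel_indices(points.reshape(-1, 3))
        flat = spec.ravel(np.clip(idx, 0, np.array(spec.shape) - 1))
        np.add.at(counts.reshape(-1), flat[inside], 1)
        frames_col.append(frame_grid.reshape(-1)[inside])
        inst_col.append(inst_grid.reshape(-1)[inside])
        atom_col.append(np.full(int(inside.sum()), atom_id, dtype=np.int64))
        avox_col.append(flat[inside])
        cvox_col.append(com_flat.reshape(-1)[inside])
        return int((~inside).sum())

    oob = 0
    if atom_indices is None:
        oob += _tally(com, -1)
        multiplicity = 1
    else:
        for ai in atom_indices:
            oob += _tally(snapshots.coords[:, :, ai, :], ai)
        multiplicity = len(atom_indices)

    grid = CountGrid(
        spec=spec,
        counts=counts,
        n_frames=F,
        n_instances=I,
        multiplicity=multiplicity,
        group=group,
        out_of_bounds=oob,
    )
    trace = ObservationTrace(
        spec,
        np.concatenate(frames_col),
        np.concatenate(inst_col),
        np.concatenate(atom_col),
        np.concatenate(avox_col),
        np.concatenate(cvox_col),
    )
    return grid, trace


def expected_count(
    spec: GridSpec,
    n_frames: int,
    multiplicity: int = 1,
    bulk_number_density: float | None = None,
    counts: CountGrid | None = None,
    bulk_region: np.ndarray | None = None,
) -> tuple[float, dict]:
    """Expected per-voxel count N_o in the absence of the receptor.

    Two modes:

    * supplied density — ``N_o = rho_bulk * spacing^3 * n_frames *
      multiplicity`` with ``bulk_number_density`` in probe molecules/Å³
      (from the known v/v concentration, or exactly known for synthetic
      systems);
    * estimated — mean per-voxel count over a user-designated
      ``bulk_region`` (boolean voxel mask of ``counts``), which already
      carries the frame and multiplicity factors.

    Returns ``(N_o, metadata)`` where metadata records the mode used.
    """
    if n_frames <= 0 or multiplicity <= 0:
        raise ValueError("n_frames and multiplicity must be positive")
    if bulk_number_density is not None:
        if bulk_number_density <= 0:
            raise ValueError("bulk_number_density must be > 0")
        n0 = bulk_number_density * spec.voxel_volume * n_frames * multiplicity
        meta = {
            "mode": "supplied_density",
            "bulk_number_density": float(bulk_number_density),
        }
        return float(n0), meta
    if counts is None or bulk_region is None:
        raise ValueError(
            "either bulk_number_density or (counts, bulk_region) must be given"
        )
    region = np.asarray(bulk_region, dtype=bool)
    if region.shape != spec.shape:
        raise ValueError("bulk_region shape does not match grid spec")
    if not region.any():
        raise ValueError("bulk region is empty")
    n0 = float(counts.counts[region].mean())
    if n0 <= 0:
        raise ValueError("bulk region contains no observations; cannot estimate N_o")
    rho = n0 / (spec.voxel_volume * n_frames * multiplicity)
    meta = {
        "mode": "estimated_from_region",
        "n_region_voxels": int(region.sum()),
        "implied_bulk_number_density": rho,
    }
    return n0, meta
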