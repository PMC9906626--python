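"""Snapshot sets: probe coordinates per trajectory frame, and PDB I/O.

Snapshots are frames of a (receptor-frame-aligned) trajectory carrying
some number of probe molecule instances.  The required on-disk dialect
is multi-model PDB (``MODEL``/``ENDMDL`` delimited), read and written
through biotite.  Alignment to the receptor frame is assumed done
upstream; no superposition is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .topology import MASS_WEIGHTED, ProbeTopology

__all__ = ["SnapshotSet", "read_multimodel_pdb", "write_multimodel_pdb", "compute_com"]


@dataclass
class SnapshotSet:
    """Ordered frames of probe-instance coordinates.

    ``coords`` has shape ``(n_frames, n_instances, n_atoms, 3)`` in Å,
    with the atom axis ordered as in ``topology.atoms``.  The same probe
    instances are assumed present in every frame (the usual case for a
    solvated simulation box); replicas are concatenated along the frame
    axis.
    """

    topology: ProbeTopology
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 4 or self.coords.shape[-1] != 3:
            raise ValueError(
                f"coords must have shape (n_frames, n_instances, n_atoms, 3), "
                f"got {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise ValueError("SnapshotSet must contain at least one frame")
        if self.coords.shape[2] != self.topology.n_atoms:
            raise ValueError(
                f"coords carry {self.coords.shape[2]} atoms per instance but "
                f"topology {self.topology.probe_name} defines {self.topology.n_atoms}"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_instances(self) -> int:
        return self.coords.shape[1]

    def concat(self, other: "SnapshotSet") -> "SnapshotSet":
        """Append another replica's frames (same probe, same instance count)."""
        if other.topology.probe_name != self.topology.probe_name:
            raise ValueError("cannot concatenate snapshot sets of different probes")
        if other.n_instances != self.n_instances:
            raise ValueError(
                f"instance count mismatch: {self.n_instances} vs {other.n_instances}"
            )
        return SnapshotSet(self.topology, np.concatenate([self.coords, other.coords]))

    def com(self) -> np.ndarray:
        """Per-frame, per-instance centre of mass, shape (n_frames, n_instances, 3)."""
        return compute_com(self.coords, self.topology)


def compute_com(coords: np.ndarray, topology: ProbeTopology) -> np.ndarray:
    """Centre of mass of probe instances.

    ``coords`` is ``(..., n_atoms, 3)``.  Mass-weighted mean for
    ``com_mode == "mass"``; the proxy atom's coordinates verbatim
    otherwise.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[-2] != topology.n_atoms:
        raise ValueError(
            f"expected {topology.n_atoms} atoms per instance, got {coords.shape[-2]}"
        )
    if topology.com_mode == MASS_WEIGHTED:
        m = topology.masses
        return np.einsum("...aj,a->...j", coords, m) / m.sum()
    return coords[..., topology.atom_index(topology.com_mode), :]


def read_multimodel_pdb(
    path, topology: ProbeTopology, probe_resname: str
) -> SnapshotSet:
    """Read probe snapshots from a multi-model PDB file.

    Probe instances are identified by residue name and grouped by
    (chain id, residue id) within each model; frames follow MODEL order.
    Every instance must carry exactly the topology's atoms.

    Raises
    ------
    ValueError
        If the file has no frames, no probe residues, or an instance is
        missing atoms (the message names the residue).
    """
    pdb = PDBFile.read(path)
    if pdb.get_model_count() == 0:
        raise ValueError(f"{path}: no models (frames) found")
    stack = pdb.get_structure(model=None)  # AtomArrayStack, all models
    sel = stack.res_name == probe_resname
    if not np.any(sel):
        raise ValueError(f"{path}: no residues named {probe_resname!r}")
    probe = stack[..., sel]

    # group atoms into instances by (chain, resid), preserving file order
    keys = list(zip(probe.chain_id, probe.res_id))
    order: dict[tuple, list[int]] = {}
    for i, k in enumerate(keys):
        order.setdefault(k, []).append(i)

    want = topology.atom_names
    n_frames = probe.stack_depth()
    instances = []
    for (chain, resid), idxs in order.items():
        names = list(probe.atom_name[idxs])
        missing = [n for n in want if n not in names]
        if missing:
            raise ValueError(
                f"{path}: probe residue {probe_resname} {chain}/{resid} is missing "
                f"atom(s) {missing}"
            )
        # topology order, ignoring extras (e.g. hydrogens not in the topology)
        sel_idx = [idxs[names.index(n)] for n in want]
        instances.append(probe.coord[:, sel_idx, :])  # (n_frames, n_atoms, 3)

    coords = np.stack(instances, axis=1)  # (n_frames, n_instances, n_atoms, 3)
    del n_frames
    return SnapshotSet(topology, coords)


def write_multimodel_pdb(path, snapshots: SnapshotSet, probe_resname: str = "PRB") -> None:
    """Write a :class:`SnapshotSet` as a multi-model PDB of HETATM probe records."""
    top = snapshots.topology
    n_inst, n_atoms = snapshots.n_instances, top.n_atoms
    n_total = n_inst * n_atoms

    template = struc.AtomArray(n_total)
    template.chain_id[:] = "A"
    template.res_name[:] = probe_resname
    template.hetero[:] = True
    for i in range(n_inst):
        s = slice(i * n_atoms, (i + 1) * n_atoms)
        template.res_id[s] = i + 1
        template.atom_name[s] = top.atom_names
        template.element[s] = [n[0] for n in top.atom_names]

    stack = struc.AtomArrayStack(snapshots.n_frames, n_total)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = snapshots.coords.reshape(snapshots.n_frames, n_total, 3)

    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)
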