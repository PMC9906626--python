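"""Hotspot extraction and pharmacophore export from free-energy grids.

A hotspot is a spatially contiguous (26-connected) cluster of defined
voxels at or below an energy threshold — a preferred binding site for
the probe group.  Hotspot centres can be exported as labelled
pharmacophore points (e.g. hydrogen-bond acceptor, hydrophobic) for use
as docking restraints.

Typical isocontour thresholds: around -1.5 kcal/mol on raw atomic
maps, -0.7 to -1.0 kcal/mol on corrected maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import ScalarGrid

__all__ = ["Hotspot", "find_hotspots", "export_pharmacophore", "write_pseudoatoms_pdb"]

#: 26-connectivity (face + edge + corner neighbours).
_STRUCTURE = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Hotspot:
    """One connected cluster of below-threshold voxels."""

    chemotype: str
    representative_point: np.ndarray  # Å
    min_value: float  # kcal/mol
    n_voxels: int
    member_voxels: np.ndarray  # (n, 3) int indices

    def __post_init__(self) -> None:
        self.representative_point = np.asarray(self.representative_point, dtype=float)
        self.member_voxels = np.asarray(self.member_voxels, dtype=int)


def find_hotspots(
    grid: ScalarGrid,
    threshold: float,
    min_voxels: int = 1,
    chemotype: str = "",
    mode: str = "min",
) -> list[Hotspot]:
    """Threshold and cluster a free-energy grid into hotspots.

    Defined voxels with ``value <= threshold`` are partitioned into
    26-connected components; components smaller than ``min_voxels`` are
    dropped.  The representative point is the centre of the component's
    minimum-value voxel (``mode="min"``; ties resolved to the
    lexicographically lowest voxel index) or the unweighted centroid of
    the member voxel centres (``mode="centroid"``).  Hotspots are
    returned sorted by minimum value, most favourable first.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if mode not in ("min", "centroid"):
        raise ValueError(f"unknown representative mode {mode!r}")
    selected = grid.defined_mask & (grid.values <= threshold)
    labels, n_comp = ndimage.label(selected, structure=_STRUCTURE)
    spec = grid.spec
    out: list[Hotspot] = []
    for comp in range(1, n_comp + 1):
        members = np.argwhere(labels == comp)  # lexicographic order
        if len(members) < min_voxels:
            continue
        vals = grid.values[members[:, 0], members[:, 1], members[:, 2]]
        best = int(np.argmin(vals))  # argmin returns first == lexicographically lowest
        if mode == "min":
            rep = spec.voxel_center(members[best])
        else:
            rep = np.mean([spec.voxel_center(m) for m in members], axis=0)
        out.append(
            Hotspot(
                chemotype=chemotype,
                representative_point=rep,
                min_value=float(vals[best]),
                n_voxels=len(members),
                member_voxels=members,
            )
        )
    out.sort(key=lambda h: h.min_value)
    return out


_PHARMACOPHORE_COLUMNS = ["feature_type", "x", "y", "z", "value_kcal_mol", "n_voxels"]


def export_pharmacophore(
    hotspots: list[Hotspot], feature_map: dict[str, str], path=None
) -> pd.DataFrame:
    """Map hotspots to labelled pharmacophore points.

    ``feature_map`` maps each chemotype present in ``hotspots`` to a
    feature type (e.g. ``{"polar": "acceptor", "hydrophobic":
    "hydrophobic"}``).  Input order is preserved; duplicates are kept.
    Writes CSV when ``path`` is given.
    """
    rows = []
    for h in hotspots:
        if h.chemotype not in feature_map:
            raise KeyError(
                f"chemotype {h.chemotype!r} has no feature mapping "
                f"(known: {sorted(feature_map)})"
            )
        x, y, z = h.representative_point
        rows.append((feature_map[h.chemotype], x, y, z, h.min_value, h.n_voxels))
    df = pd.DataFrame(rows, columns=_PHARMACOPHORE_COLUMNS)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def write_pseudoatoms_pdb(hotspots: list[Hotspot], path) -> None:
    """One HETATM pseudo-atom per hotspot centre, for molecular viewers."""
    with open(path, "w") as fh:
        for i, h in enumerate(hotspots, start=1):
            x, y, z = h.representative_point
            fh.write(
                f"HETATM{i:5d}  X   HSP A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{h.min_value:6.2f}          "
                f" X\n"
            )
        fh.write("END\n")
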