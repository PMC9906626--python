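"""Model/Results facade over the full analysis pipeline.

``BindingFreeEnergyModel`` is built from a snapshot set (data) plus the
analysis configuration (lattice, thermodynamics, bulk density, alpha
fractions); ``fit()`` runs counting, Boltzmann inversion and the atomic
repartition and returns a ``BindingFreeEnergyResults`` carrying the
grids, their per-voxel statistical uncertainties, diagnostics and a
``summary()`` table.  Hotspot extraction and file export hang off the
results object.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from . import __version__ as _version
from .correction import CorrectionResult, correct_grid
from .density import COM, CountGrid, ObservationTrace, accumulate, expected_count
from .free_energy import ThermoParams, counts_to_dg
from .grid import GridSpec, ScalarGrid, write_dx
from .hotspots import Hotspot, export_pharmacophore, find_hotspots
from .sasa import AlphaFractions, probe_alpha
from .snapshots import SnapshotSet, read_multimodel_pdb
from .topology import ProbeTopology

__all__ = ["BindingFreeEnergyModel", "BindingFreeEnergyResults"]


class BindingFreeEnergyModel:
    """Voxel binding free-energy maps with atomic repartition.

    Parameters
    ----------
    snapshots : SnapshotSet
        Receptor-frame probe coordinates (observed data).
    grid : GridSpec
        Analysis lattice.
    thermo : ThermoParams
        Simulation temperature (default 300 K).
    bulk_density : float, optional
        Bulk probe number density in molecules/Å³.  Either this or
        ``bulk_region`` must be given.
    bulk_region : bool array, optional
        Voxel mask designating receptor-free bulk, used to estimate the
        expected count when the density is not known.
    alpha : AlphaFractions or dict, optional
        Per-atom partition fractions; computed from the topology's
        supplied table or reference-geometry SASA when omitted.
    chemotype_atoms : dict, optional
        Chemotype -> subset of member atom names to count.  Use a single
        representative atom for probes bound in a rigid fixed pose,
        where pooling symmetric atoms would add a spurious
        symmetry-number offset to site values.
    zero_policy : {"mask", "pseudocount"}
        Handling of zero-count voxels in the inversion.
    """

    def __init__(
        self,
        snapshots: SnapshotSet,
        grid: GridSpec,
        *,
        thermo: ThermoParams = ThermoParams(),
        bulk_density: float | None = None,
        bulk_region: np.ndarray | None = None,
        alpha: AlphaFractions | dict | None = None,
        chemotype_atoms: dict[str, list[str]] | None = None,
        zero_policy: str = "mask",
    ) -> None:
        if bulk_density is None and bulk_region is None:
            raise ValueError("provide bulk_density (molecules/Å³) or a bulk_region mask")
        self.snapshots = snapshots
        self.topology = snapshots.topology
        self.grid = grid
        self.thermo = thermo
        self.bulk_density = bulk_density
        self.bulk_region = bulk_region
        self.chemotype_atoms = chemotype_atoms or {}
        self.zero_policy = zero_policy
        if alpha is None:
            self.alpha = probe_alpha(self.topology)
        elif isinstance(alpha, AlphaFractions):
            self.alpha = alpha
        else:
            vec = np.array([alpha[n] for n in self.topology.atom_names])
            self.alpha = AlphaFractions(vec / vec.sum(), [])

    @classmethod
    def from_pdb(
        cls,
        paths,
        topology: ProbeTopology,
        probe_resname: str,
        grid: GridSpec,
        **kwargs,
    ) -> "BindingFreeEnergyModel":
        """Build the model from one or more multi-model PDB replicas."""
        if isinstance(paths, (str, os.PathLike)):
            paths = [paths]
        snaps = read_multimodel_pdb(paths[0], topology, probe_resname)
        for p in paths[1:]:
            snaps = snaps.concat(read_multimodel_pdb(p, topology, probe_resname))
        return cls(snaps, grid, **kwargs)

    # ------------------------------------------------------------------

    def _n_o(self, counts: CountGrid) -> tuple[float, dict]:
        if self.bulk_density is not None:
            return expected_count(
                self.grid,
                counts.n_frames,
                counts.multiplicity,
                bulk_number_density=self.bulk_density,
            )
        return expected_count(
            self.grid,
            counts.n_frames,
            counts.multiplicity,
            counts=counts,
            bulk_region=self.bulk_region,
        )

    def fit(self) -> "BindingFreeEnergyResults":
        """Run the full analysis and return the results object."""
        mol_counts, _ = accumulate(self.snapshots, self.topology, COM, self.grid)
        n_o_mol, n_o_meta = self._n_o(mol_counts)
        mol_dg = counts_to_dg(mol_counts, n_o_mol, self.thermo, self.zero_policy)

        counts: dict[str, CountGrid] = {COM: mol_counts}
        traces: dict[str, ObservationTrace] = {}
        raw_dg: dict[str, ScalarGrid] = {}
        corrected: dict[str, CorrectionResult] = {}
        n_o: dict[str, float] = {COM: n_o_mol}
        alpha_per_map: dict[str, float] = {}

        names = self.topology.atom_names
        for chemo, members in self.topology.groups.items():
            atoms = self.chemotype_atoms.get(chemo)
            cg, trace = accumulate(self.snapshots, self.topology, chemo, self.grid, atoms=atoms)
            n0, _ = self._n_o(cg)
            raw = counts_to_dg(cg, n0, self.thermo, self.zero_policy)
            counted = atoms if atoms is not None else members
            a_atom = self.alpha.group_mean([names.index(n) for n in counted])
            corr = correct_grid(
                raw,
                mol_dg,
                trace,
                a_atom,
                metadata={
                    "chemotype": chemo,
                    "atoms": list(counted),
                    "n_o_atomic": n0,
                    "n_o_molecular": n_o_mol,
                    "temperature": self.thermo.temperature,
                    "com_mode": self.topology.com_mode,
                },
            )
            counts[chemo] = cg
            traces[chemo] = trace
            raw_dg[chemo] = raw
            corrected[chemo] = corr
            n_o[chemo] = n0
            alpha_per_map[chemo] = a_atom

        return BindingFreeEnergyResults(
            model=self,
            molecular_dg=mol_dg,
            raw_dg=raw_dg,
            corrected=corrected,
            counts=counts,
            traces=traces,
            n_o=n_o,
            n_o_metadata=n_o_meta,
            alpha=self.alpha,
            alpha_per_map=alpha_per_map,
        )


@dataclass
class BindingFreeEnergyResults:
    """Fitted free-energy maps, uncertainties and diagnostics."""

    model: BindingFreeEnergyModel
    molecular_dg: ScalarGrid
    raw_dg: dict[str, ScalarGrid]
    corrected: dict[str, CorrectionResult]
    counts: dict[str, CountGrid]
    traces: dict[str, ObservationTrace]
    n_o: dict[str, float]
    n_o_metadata: dict
    alpha: AlphaFractions
    alpha_per_map: dict[str, float]

    @property
    def thermo(self) -> ThermoParams:
        return self.model.thermo

    @property
    def chemotypes(self) -> list[str]:
        return list(self.raw_dg)

    def std_error(self, group: str) -> ScalarGrid:
        """Per-voxel 1-sigma uncertainty of the raw dG estimate (kcal/mol).

        Counting noise is Poisson-like, so ``se(dG) ~ kT / sqrt(N_v)``
        at defined voxels.
        """
        cg = self.counts[group]
        n = cg.counts.astype(float)
        mask = n > 0
        se = np.where(mask, self.thermo.kT / np.sqrt(np.maximum(n, 1)), 0.0)
        return ScalarGrid(cg.spec, se, mask)

    def hotspots(
        self,
        group: str,
        threshold: float = -1.0,
        min_voxels: int = 1,
        corrected: bool = True,
        mode: str = "min",
    ) -> list[Hotspot]:
        """Extract hotspots from the corrected (default) or raw map of a chemotype."""
        grid = self.corrected[group].grid if corrected else self.raw_dg[group]
        return find_hotspots(grid, threshold, min_voxels, chemotype=group, mode=mode)

    def pharmacophore(
        self,
        feature_map: dict[str, str],
        threshold: float = -1.0,
        min_voxels: int = 1,
        path=None,
    ):
        """Hotspot centres of every chemotype as labelled pharmacophore points."""
        spots: list[Hotspot] = []
        for chemo in self.chemotypes:
            spots.extend(self.hotspots(chemo, threshold, min_voxels))
        return export_pharmacophore(spots, feature_map, path)

    def summary(self) -> str:
        """Plain-text fit summary in the style of statistical model results."""
        m = self.model
        lines = []
        w = 78
        lines.append("=" * w)
        lines.append("Binding Free-Energy Map Results".center(w))
        lines.append("=" * w)
        lines.append(f"Probe:            {m.topology.probe_name}   (CoM mode: {m.topology.com_mode})")
        lines.append(
            f"Snapshots:        {m.snapshots.n_frames} frames x "
            f"{m.snapshots.n_instances} instances"
        )
        gs = m.grid
        lines.append(
            f"Grid:             {gs.shape[0]}x{gs.shape[1]}x{gs.shape[2]} voxels, "
            f"spacing {gs.spacing:g} Å, origin ({gs.origin[0]:g}, {gs.origin[1]:g}, {gs.origin[2]:g})"
        )
        lines.append(
            f"Temperature:      {self.thermo.temperature:g} K   (kT = {self.thermo.kT:.4f} kcal/mol)"
        )
        lines.append(f"N_o mode:         {self.n_o_metadata.get('mode', 'supplied_density')}")
        lines.append("-" * w)
        hdr = (
            f"{'map':<14}{'atoms':<12}{'alpha':>7}{'N_o':>10}{'obs':>12}"
            f"{'oob':>9}{'min raw':>9}{'min corr':>9}"
        )
        lines.append(hdr)
        lines.append("-" * w)
        cg = self.counts[COM]
        mol_min = self.molecular_dg.min_defined() if self.molecular_dg.defined_mask.any() else float("nan")
        lines.append(
            f"{'molecular':<14}{'CoM':<12}{'':>7}{self.n_o[COM]:>10.3f}"
            f"{cg.total:>12d}{cg.out_of_bounds:>9d}{mol_min:>9.3f}{'':>9}"
        )
        for chemo in self.chemotypes:
            cg = self.counts[chemo]
            corr = self.corrected[chemo]
            raw_min = self.raw_dg[chemo].min_defined() if self.raw_dg[chemo].defined_mask.any() else float("nan")
            corr_min = corr.grid.min_defined() if corr.grid.defined_mask.any() else float("nan")
            atoms = ",".join(corr.metadata.get("atoms", []))
            lines.append(
                f"{chemo:<14}{atoms:<12}{self.alpha_per_map[chemo]:>7.3f}"
                f"{self.n_o[chemo]:>10.3f}{cg.total:>12d}{cg.out_of_bounds:>9d}"
                f"{raw_min:>9.3f}{corr_min:>9.3f}"
            )
        lines.append("-" * w)
        for chemo in self.chemotypes:
            corr = self.corrected[chemo]
            lines.append(
                f"{chemo}: correction used {corr.n_used} observations, skipped "
                f"{corr.skipped_oob_com} (CoM out of grid) + "
                f"{corr.skipped_undefined_com} (CoM voxel undefined)"
            )
        lines.append("=" * w)
        return "\n".join(lines)

    def to_dx(self, directory, sentinel: float = 999.0) -> list[str]:
        """Write all maps as OpenDX files into ``directory``; returns the paths."""
        os.makedirs(directory, exist_ok=True)
        written = []

        def _w(name: str, grid: ScalarGrid) -> None:
            path = os.path.join(directory, name)
            write_dx(grid, path, sentinel)
            written.append(path)

        _w("molecular_dg.dx", self.molecular_dg)
        for chemo in self.chemotypes:
            _w(f"{chemo}_raw_dg.dx", self.raw_dg[chemo])
            _w(f"{chemo}_corrected_dg.dx", self.corrected[chemo].grid)
        return written
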