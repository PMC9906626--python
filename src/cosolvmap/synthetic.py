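"""Synthetic snapshot generator with exact ground-truth energetics.

Generates Boltzmann-distributed probe placements over a set of discrete
binding sites plus uniform bulk, so that every stage of the analysis
(counting, inversion, repartition, hotspot extraction) can be validated
against closed-form expectations without running MD.

Sampling model
--------------
Each probe instance, independently per frame, is either bound to site
*s* or free in bulk.  The statistical weight of a site relative to bulk
is ``w_s = (V_site / V_box) exp(-U_s / kT)`` where ``U_s`` is the well
depth (negative = favourable) and ``V_site`` is one analysis voxel
volume; thus ``p_s = w_s / (1 + sum_t w_t)``.  The observed density
ratio between the site voxel and bulk is then exactly
``exp(-U_s/kT)``, so Boltzmann inversion recovers the well depth.
Instances do not interact (ideal probes): several may occupy one site
in the same frame, which keeps the closed form exact for deep wells.

When bound the molecule is placed rigidly: either in a fixed pose
(anchor point + fixed per-atom offsets, so each atom's density equals
the molecular density — the regime where the repartition algebra has
exact point values), or with a uniformly random orientation about the
anchor (modelling a group that binds while the rest of the molecule
swings freely).  The anchor is the molecule's tracked centre of mass by
default, or a designated atom.  Unbound instances are uniform in the
box with uniform random orientation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .free_energy import ThermoParams
from .grid import GridSpec, ScalarGrid
from .snapshots import SnapshotSet, compute_com
from .topology import ProbeAtom, ProbeTopology

__all__ = [
    "SiteSpec",
    "BulkSpec",
    "GroundTruth",
    "simulate_site_model",
    "ground_truth_maps",
    "benzene_probe",
    "ethane_probe",
    "amphiphile_probe",
    "idealized_case",
]

DEFAULT_SITE_VOLUME = 0.5**3  # one voxel at the default analysis spacing, Å³


@dataclass(frozen=True)
class SiteSpec:
    """A discrete binding site for the two-state sampling model.

    ``position`` (Å) is where the anchor (tracked CoM, or
    ``anchor_atom``) sits when bound; ``depth`` is the well free energy
    in kcal/mol (negative = favourable); ``orientation`` is ``"fixed"``
    (rigid pose, atoms at position + reference offsets) or ``"random"``
    (uniform rigid rotation about the anchor each time).
    """

    position: tuple[float, float, float]
    depth: float
    site_id: str = "site"
    orientation: str = "fixed"
    anchor_atom: str | None = None

    def __post_init__(self) -> None:
        if self.orientation not in ("fixed", "random"):
            raise ValueError(f"orientation must be 'fixed' or 'random', got {self.orientation!r}")
        if len(tuple(self.position)) != 3:
            raise ValueError("site position must be a 3-vector")


@dataclass(frozen=True)
class BulkSpec:
    """Simulation box bounds (Å) and probe count for the bulk phase."""

    box_lower: tuple[float, float, float]
    box_upper: tuple[float, float, float]
    n_instances: int
    thermo: ThermoParams = ThermoParams()

    def __post_init__(self) -> None:
        lo = np.asarray(self.box_lower, dtype=float)
        hi = np.asarray(self.box_upper, dtype=float)
        if np.any(hi <= lo):
            raise ValueError("box upper bound must exceed lower bound on every axis")
        if self.n_instances < 1:
            raise ValueError("need at least one probe instance")

    @property
    def volume(self) -> float:
        lo = np.asarray(self.box_lower)
        hi = np.asarray(self.box_upper)
        return float(np.prod(hi - lo))


@dataclass
class GroundTruth:
    """Exact sampling probabilities and densities behind a synthetic run."""

    seed: int
    site_volume: float
    p_sites: dict[str, float]
    p_bulk: float
    depths: dict[str, float]
    site_positions: dict[str, tuple[float, float, float]]
    bulk_number_density: float  # probe molecules / Å³, unbound fraction
    thermo: ThermoParams
    n_frames: int
    n_instances: int
    extra: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        d = {
            "seed": self.seed,
            "site_volume": self.site_volume,
            "p_sites": self.p_sites,
            "p_bulk": self.p_bulk,
            "depths": self.depths,
            "site_positions": {k: list(v) for k, v in self.site_positions.items()},
            "bulk_number_density": self.bulk_number_density,
            "temperature": self.thermo.temperature,
            "n_frames": self.n_frames,
            "n_instances": self.n_instances,
            "extra": self.extra,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


def _anchor_offsets(topology: ProbeTopology, anchor_atom: str | None) -> np.ndarray:
    """Per-atom offsets (Å) from the anchor point in the reference pose."""
    ref = topology.reference_coords
    if ref is None:
        raise ValueError(f"probe {topology.probe_name} has no reference coordinates")
    if anchor_atom is None:
        anchor = compute_com(ref, topology)
    else:
        anchor = ref[topology.atom_index(anchor_atom)]
    return ref - anchor


def simulate_site_model(
    sites: list[SiteSpec],
    bulk: BulkSpec,
    topology: ProbeTopology,
    n_frames: int,
    seed: int,
    site_volume: float = DEFAULT_SITE_VOLUME,
) -> tuple[SnapshotSet, GroundTruth]:
    """Sample a snapshot set from the discrete-site Boltzmann model.

    Deterministic for a fixed seed.  Returns the snapshots and the
    exact ground truth (per-site probabilities and the unbound bulk
    number density) needed to analyse them without estimation error.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    ids = [s.site_id for s in sites]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate site ids: {ids}")
    pos = np.array([s.position for s in sites], dtype=float)
    if len(sites) > 1:
        d = np.linalg.norm(pos[:, None] - pos[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        min_sep = site_volume ** (1 / 3)
        if np.any(d < min_sep):
            i, j = np.unravel_index(np.argmin(d), d.shape)
            raise ValueError(
                f"sites {ids[i]!r} and {ids[j]!r} overlap (separation {d[i, j]:.3f} Å "
                f"< site edge {min_sep:.3f} Å)"
            )

    kT = bulk.thermo.kT
    w = np.array(
        [site_volume / bulk.volume * np.exp(-s.depth / kT) for s in sites]
    )
    z = 1.0 + w.sum()
    p_sites = w / z
    p_bulk = 1.0 / z

    rng = np.random.default_rng(seed)
    n = n_frames * bulk.n_instances
    n_atoms = topology.n_atoms
    cat = np.searchsorted(np.cumsum(p_sites), rng.random(n))  # len(sites) => bulk

    coords = np.empty((n, n_atoms, 3))
    for s_idx, site in enumerate(sites):
        m = cat == s_idx
        k = int(m.sum())
        if k == 0:
            continue
        off = _anchor_offsets(topology, site.anchor_atom)
        p = np.asarray(site.position, dtype=float)
        if site.orientation == "fixed":
            coords[m] = p + off
        else:
            rot = Rotation.random(k, rng=rng).as_matrix()
            coords[m] = p + np.einsum("nij,aj->nai", rot, off)

    m = cat == len(sites)
    k = int(m.sum())
    if k:
        lo = np.asarray(bulk.box_lower)
        hi = np.asarray(bulk.box_upper)
        com = lo + rng.random((k, 3)) * (hi - lo)
        off = _anchor_offsets(topology, None)
        rot = Rotation.random(k, rng=rng).as_matrix()
        coords[m] = com[:, None, :] + np.einsum("nij,aj->nai", rot, off)

    snaps = SnapshotSet(
        topology, coords.reshape(n_frames, bulk.n_instances, n_atoms, 3)
    )
    truth = GroundTruth(
        seed=seed,
        site_volume=site_volume,
        p_sites={s.site_id: float(p) for s, p in zip(sites, p_sites)},
        p_bulk=float(p_bulk),
        depths={s.site_id: s.depth for s in sites},
        site_positions={s.site_id: tuple(float(x) for x in s.position) for s in sites},
        bulk_number_density=float(bulk.n_instances * p_bulk / bulk.volume),
        thermo=bulk.thermo,
        n_frames=n_frames,
        n_instances=bulk.n_instances,
    )
    return snaps, truth


def ground_truth_maps(
    sites: list[SiteSpec],
    bulk: BulkSpec,
    topology: ProbeTopology,
    spec: GridSpec,
    alpha: np.ndarray | None = None,
) -> dict:
    """Analytic expected free-energy maps for fixed-pose, CoM-anchored sites.

    Returns ``{"molecular": ScalarGrid, "atomic_raw": {atom: grid},
    "atomic_corrected": {atom: grid}}``: zero (bulk level) everywhere,
    the well depth at the CoM voxel of each site and at each pose-atom
    voxel, and ``alpha_i * depth`` on the corrected maps.  Sites with
    random orientation or a non-CoM anchor have no point-valued atomic
    expectation and are included only in the molecular map if
    CoM-anchored.
    """
    mol = ScalarGrid.full(spec, 0.0)
    raw = {a: ScalarGrid.full(spec, 0.0) for a in topology.atom_names}
    corr = {a: ScalarGrid.full(spec, 0.0) for a in topology.atom_names}
    for site in sites:
        if site.anchor_atom is None:
            u = spec.voxel_index(site.position)
            if u is not False and u:
                mol.values[u] = site.depth
        if site.orientation != "fixed" or site.anchor_atom is not None:
            continue
        off = _anchor_offsets(topology, None)
        for i, name in enumerate(topology.atom_names):
            v = spec.voxel_index(np.asarray(site.position) + off[i])
            if v:
                raw[name].values[v] = site.depth
                if alpha is not None:
                    corr[name].values[v] = float(alpha[i]) * site.depth
    return {"molecular": mol, "atomic_raw": raw, "atomic_corrected": corr}


# ---------------------------------------------------------------------------
# Idealised probe geometries
# ---------------------------------------------------------------------------

_C_MASS, _C_RADIUS = 12.011, 1.70


def benzene_probe() -> ProbeTopology:
    """Six identical carbons on a 1.39 Å ring; all one chemotype.

    By symmetry every atom's partition fraction is exactly 1/6, so the
    alpha table is supplied directly instead of being estimated from
    the finite SASA point set.
    """
    ang = np.arange(6) * np.pi / 3.0
    ring = np.stack([1.39 * np.cos(ang), 1.39 * np.sin(ang), np.zeros(6)], axis=1)
    return ProbeTopology(
        probe_name="benzene",
        atoms=[ProbeAtom(f"C{i+1}", _C_MASS, _C_RADIUS, "aromatic") for i in range(6)],
        com_mode="mass",
        reference_coords=ring,
        alpha={f"C{i+1}": 1.0 / 6.0 for i in range(6)},
    )


def ethane_probe() -> ProbeTopology:
    """Two identical carbons 1.54 Å apart; alpha = 1/2 each by symmetry."""
    coords = np.array([[-0.77, 0.0, 0.0], [0.77, 0.0, 0.0]])
    return ProbeTopology(
        probe_name="ethane",
        atoms=[
            ProbeAtom("C1", _C_MASS, _C_RADIUS, "hydrophobic"),
            ProbeAtom("C2", _C_MASS, _C_RADIUS, "hydrophobic"),
        ],
        com_mode="mass",
        reference_coords=coords,
        alpha={"C1": 0.5, "C2": 0.5},
    )


def amphiphile_probe() -> ProbeTopology:
    """Idealised linear 3-atom amphiphile: hydrophobic head, central atom, polar tail.

    Supplied alpha fractions (0.35, 0.30, 0.35); the central atom
    proxies the CoM, matching the proxy-atom convention for real
    probes.  Bond lengths 1.5 Å.
    """
    coords = np.array([[-1.5, 0.0, 0.0], [0.0, 0.0, 0.0], [1.5, 0.0, 0.0]])
    return ProbeTopology(
        probe_name="amphiphile3",
        atoms=[
            ProbeAtom("A", _C_MASS, _C_RADIUS, "hydrophobic"),
            ProbeAtom("X", _C_MASS, _C_RADIUS, None),
            ProbeAtom("B", 15.999, 1.52, "polar"),
        ],
        com_mode="X",
        reference_coords=coords,
        alpha={"A": 0.35, "X": 0.30, "B": 0.35},
    )


def idealized_case(
    case: str, position=(10.25, 10.25, 10.25), depth: float = -6.0
) -> tuple[list[SiteSpec], ProbeTopology]:
    """Named idealised amphiphile scenarios.

    ``"both_bind"``: the whole molecule is rigidly bound (every atom's
    raw map shows the full molecular depth).  ``"polar_only"``: only the
    polar tail is anchored; the rest of the molecule rotates freely, so
    the hydrophobic head has no intrinsic site.  ``"mixed"``: the polar
    tail is rigidly bound at one site while a second, shallower site
    binds the whole molecule.
    """
    probe = amphiphile_probe()
    p = np.asarray(position, dtype=float)
    if case == "both_bind":
        sites = [SiteSpec(tuple(p), depth, "site")]
    elif case == "polar_only":
        sites = [SiteSpec(tuple(p), depth, "polar_site", orientation="random", anchor_atom="B")]
    elif case == "mixed":
        sites = [
            SiteSpec(tuple(p), depth, "polar_site", orientation="random", anchor_atom="B"),
            SiteSpec(tuple(p + 6.0), depth / 2.0, "rigid_site"),
        ]
    else:
        raise ValueError(f"unknown case {case!r} (use both_bind, polar_only, mixed)")
    return sites, probe
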