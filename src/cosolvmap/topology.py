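"""Probe molecule definitions: atoms, chemotype groups, and CoM mode.

A probe is the small amphiphilic cosolvent molecule (ethanol,
isopropanol, ...) whose voxel occupancies report the receptor's
interaction preferences.  Atoms are grouped into *chemotypes*
(e.g. ``hydrophobic`` for the two methyl carbons of isopropanol,
``polar`` for the hydroxyl oxygen); each chemotype is mapped as one
pooled density with a multiplicity equal to the number of equivalent
atoms pooled.

The molecular map uses the probe's centre of mass, either mass-weighted
over all atoms (``com_mode="mass"``) or proxied by a designated central
atom (``com_mode="C2"`` style), the latter matching common practice for
isopropanol where the central carbon tracks the CoM closely.

By default only heavy atoms are defined (hydrogens contribute little to
either the density maps or the CoM and are rarely written to snapshot
files); radii are Bondi van der Waals radii.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["ProbeAtom", "ProbeTopology", "ethanol", "isopropanol"]

MASS_WEIGHTED = "mass"


@dataclass(frozen=True)
class ProbeAtom:
    name: str
    mass: float  # amu
    vdw_radius: float  # Å
    chemotype: str | None = None  # None: atom belongs to no pooled map

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.name}: mass must be > 0")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.name}: vdW radius must be > 0")


@dataclass
class ProbeTopology:
    """Atom list, chemotype groups and CoM convention for one probe.

    Parameters
    ----------
    probe_name : str
    atoms : list of :class:`ProbeAtom`
        Each atom belongs to at most one chemotype group.
    com_mode : str
        ``"mass"`` for the mass-weighted centre of mass, or the name of a
        proxy atom whose coordinates stand in for the CoM.
    reference_coords : (n_atoms, 3) array, optional
        A representative conformation (Å), used for SASA-based alpha
        fractions and as the rigid bound pose of synthetic systems.
    alpha : dict, optional
        Pre-computed per-atom alpha fractions (atom name -> fraction),
        bypassing the SASA calculation.  Must sum to 1.
    """

    probe_name: str
    atoms: list[ProbeAtom]
    com_mode: str = MASS_WEIGHTED
    reference_coords: np.ndarray | None = None
    alpha: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("topology needs at least one atom")
        names = [a.name for a in self.atoms]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate atom names in {self.probe_name}")
        if self.com_mode != MASS_WEIGHTED and self.com_mode not in names:
            raise ValueError(
                f"com_mode {self.com_mode!r} is neither 'mass' nor an atom of "
                f"{self.probe_name} ({names})"
            )
        if self.reference_coords is not None:
            self.reference_coords = np.asarray(self.reference_coords, dtype=float)
            if self.reference_coords.shape != (len(self.atoms), 3):
                raise ValueError(
                    f"reference_coords shape {self.reference_coords.shape} != "
                    f"({len(self.atoms)}, 3)"
                )
        if self.alpha is not None:
            unknown = set(self.alpha) - set(names)
            if unknown:
                raise ValueError(f"alpha given for unknown atoms {sorted(unknown)}")
            total = sum(self.alpha.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"supplied alpha fractions sum to {total}, not 1")

    # -- derived views ------------------------------------------------------

    @property
    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    @property
    def groups(self) -> dict[str, list[str]]:
        """Chemotype -> member atom names (insertion order of `atoms`)."""
        out: dict[str, list[str]] = {}
        for a in self.atoms:
            if a.chemotype is not None:
                out.setdefault(a.chemotype, []).append(a.name)
        return out

    def multiplicity(self, chemotype: str) -> int:
        """Number of equivalent atoms pooled into the chemotype's map."""
        return len(self.group_atoms(chemotype))

    def group_atoms(self, chemotype: str) -> list[str]:
        groups = self.groups
        if chemotype not in groups:
            raise KeyError(
                f"chemotype {chemotype!r} not in {self.probe_name} "
                f"(has {sorted(groups)})"
            )
        return groups[chemotype]

    def atom_index(self, name: str) -> int:
        try:
            return self.atom_names.index(name)
        except ValueError:
            raise KeyError(f"atom {name!r} not in {self.probe_name}") from None

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "probe_name": self.probe_name,
            "com_mode": self.com_mode,
            "atoms": [
                {
                    "name": a.name,
                    "mass": a.mass,
                    "vdw_radius": a.vdw_radius,
                    "chemotype": a.chemotype,
                }
                for a in self.atoms
            ],
        }
        if self.reference_coords is not None:
            d["reference_coords"] = self.reference_coords.tolist()
        if self.alpha is not None:
            d["alpha"] = dict(self.alpha)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProbeTopology":
        try:
            atoms = [
                ProbeAtom(
                    name=a["name"],
                    mass=float(a["mass"]),
                    vdw_radius=float(a["vdw_radius"]),
                    chemotype=a.get("chemotype"),
                )
                for a in d["atoms"]
            ]
            return cls(
                probe_name=d["probe_name"],
                atoms=atoms,
                com_mode=d.get("com_mode", MASS_WEIGHTED),
                reference_coords=d.get("reference_coords"),
                alpha=d.get("alpha"),
            )
        except KeyError as exc:
            raise ValueError(f"probe topology missing required key {exc}") from exc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ProbeTopology":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Shipped probe definitions (heavy atoms, Bondi radii, standard masses).
# Reference geometries are idealised gas-phase-like conformations with the
# CoM near the origin; bond lengths: C-C 1.53 Å, C-O 1.43 Å.
# ---------------------------------------------------------------------------

_C_MASS, _O_MASS = 12.011, 15.999
_C_RADIUS, _O_RADIUS = 1.70, 1.52


def ethanol() -> ProbeTopology:
    """Ethanol (heavy atoms): methyl carbon = hydrophobic, hydroxyl O = polar."""
    # C1(methyl)-C2-O chain, tetrahedral angle at C2.
    c2 = np.zeros(3)
    c1 = np.array([1.53, 0.0, 0.0])
    o = np.array([-0.478, 1.348, 0.0])  # 1.43 Å from C2, 109.5 deg to C1
    return ProbeTopology(
        probe_name="ethanol",
        atoms=[
            ProbeAtom("C1", _C_MASS, _C_RADIUS, "hydrophobic"),
            ProbeAtom("C2", _C_MASS, _C_RADIUS, None),
            ProbeAtom("O", _O_MASS, _O_RADIUS, "polar"),
        ],
        com_mode=MASS_WEIGHTED,
        reference_coords=np.stack([c1, c2, o]),
    )


def isopropanol() -> ProbeTopology:
    """Isopropanol (heavy atoms): two methyls pooled as hydrophobic, O polar.

    The central carbon C2 is used as a CoM proxy, the common convention
    for this probe.
    """
    c2 = np.zeros(3)
    # two methyls and the O in a tetrahedral arrangement around C2
    c1 = np.array([1.442, 0.510, 0.0])
    c3 = np.array([-1.442, 0.510, 0.0])
    o = np.array([0.0, -0.476, 1.349])
    return ProbeTopology(
        probe_name="isopropanol",
        atoms=[
            ProbeAtom("C1", _C_MASS, _C_RADIUS, "hydrophobic"),
            ProbeAtom("C2", _C_MASS, _C_RADIUS, None),
            ProbeAtom("C3", _C_MASS, _C_RADIUS, "hydrophobic"),
            ProbeAtom("O", _O_MASS, _O_RADIUS, "polar"),
        ],
        com_mode="C2",
        reference_coords=np.stack([c1, c2, c3, o]),
    )
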