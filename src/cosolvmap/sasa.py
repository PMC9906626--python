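"""Per-atom solvent-accessible surface area and alpha partition fractions.

The molecular binding free energy is repartitioned among atoms in
proportion to their share of the molecule's solvent-accessible surface
area: ``alpha_i = SASA_i / SASA_M`` (conformer-population weighted for
flexible molecules).  For N identical, equally exposed atoms this
reduces to ``alpha_i = 1/N``.

SASA is computed with the Shrake-Rupley method on a deterministic
golden-spiral point set: each atom's sphere is inflated by the solvent
probe radius (default 1.4 Å, a water-sized probe), quasi-uniform
surface points are generated, and the accessible fraction is the share
of points not buried inside any other inflated sphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AtomSphere", "AlphaFractions", "golden_spiral", "shrake_rupley", "alpha_fractions"]

DEFAULT_PROBE_RADIUS = 1.4  # Å, water-sized solvent probe
DEFAULT_N_POINTS = 960


@dataclass(frozen=True)
class AtomSphere:
    """A van der Waals sphere: center (Å) and radius (Å)."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")


@dataclass
class AlphaFractions:
    """Per-atom partition fractions, summing to 1."""

    alpha: np.ndarray
    conformer_weights: list[tuple[int, float]]

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if np.any(self.alpha < 0):
            raise ValueError("alpha fractions must be >= 0")
        if abs(self.alpha.sum() - 1.0) > 1e-9:
            raise ValueError(f"alpha fractions sum to {self.alpha.sum()}, not 1")

    def __len__(self) -> int:
        return len(self.alpha)

    def group_mean(self, indices) -> float:
        """Mean alpha over a set of (equivalent) atoms."""
        return float(self.alpha[list(indices)].mean())


def golden_spiral(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit-sphere points (deterministic golden-angle spiral)."""
    if n < 1:
        raise ValueError("need at least one point")
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def _as_arrays(spheres) -> tuple[np.ndarray, np.ndarray]:
    centers = np.asarray([np.asarray(s.center, dtype=float) for s in spheres])
    radii = np.asarray([s.radius for s in spheres], dtype=float)
    return centers, radii


def shrake_rupley(
    spheres: list[AtomSphere],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area in Å².

    Each atom contributes ``4 pi (r + probe)^2`` times the fraction of
    its surface points outside every other atom's inflated sphere.
    Deterministic for fixed ``n_points``.
    """
    if n_points < 64:
        raise ValueError("n_points must be >= 64 for a meaningful estimate")
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    centers, radii = _as_arrays(spheres)
    n = len(centers)
    ext = radii + probe_radius
    # coincident centers with equal radii have no defined surface partition
    if n > 1:
        d2 = np.sum((centers[:, None] - centers[None]) ** 2, axis=-1)
        same = (d2 < 1e-12) & (np.abs(radii[:, None] - radii[None]) < 1e-12)
        np.fill_diagonal(same, False)
        if same.any():
            i, j = np.argwhere(same)[0]
            raise ValueError(
                f"atoms {i} and {j} are coincident with equal radii; surface undefined"
            )
    unit = golden_spiral(n_points)
    sasa = np.empty(n)
    for i in range(n):
        pts = centers[i] + ext[i] * unit  # (n_points, 3)
        buried = np.zeros(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d2 = np.sum((pts - centers[j]) ** 2, axis=1)
            buried |= d2 < ext[j] ** 2
        frac = 1.0 - buried.mean()
        sasa[i] = 4.0 * np.pi * ext[i] ** 2 * frac
    return sasa


def alpha_fractions(
    conformers: list[list[AtomSphere]],
    weights=None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> AlphaFractions:
    """Conformer-weighted SASA partition fractions.

    ``alpha_i = sum_c w_c SASA_i(c) / sum_c w_c SASA_M(c)`` with
    ``SASA_M(c) = sum_i SASA_i(c)``.  Weights (conformer populations)
    are normalised internally; a single conformer needs no weights.
    """
    if not conformers:
        raise ValueError("need at least one conformer")
    n_atoms = len(conformers[0])
    for c, conf in enumerate(conformers):
        if len(conf) != n_atoms:
            raise ValueError(
                f"conformer {c} has {len(conf)} atoms, expected {n_atoms}"
            )
    if weights is None:
        weights = np.ones(len(conformers))
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(conformers),):
        raise ValueError("one weight per conformer required")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be >= 0 with a positive sum")
    w = w / w.sum()

    num = np.zeros(n_atoms)
    den = 0.0
    used = []
    for c, (conf, wc) in enumerate(zip(conformers, w)):
        if wc == 0.0:
            used.append((c, 0.0))
            continue
        s = shrake_rupley(conf, probe_radius, n_points)
        num += wc * s
        den += wc * s.sum()
        used.append((c, float(wc)))
    if den <= 0:
        raise ValueError("total SASA is zero; cannot define fractions")
    a = num / den
    # guard against point-set round-off so the sum-to-one invariant is exact
    a = a / a.sum()
    return AlphaFractions(a, used)


def probe_alpha(topology, probe_radius: float = DEFAULT_PROBE_RADIUS,
                n_points: int = DEFAULT_N_POINTS) -> AlphaFractions:
    """Alpha fractions for a probe topology.

    Uses the topology's supplied ``alpha`` table when present, otherwise
    computes single-conformer SASA fractions from its reference
    coordinates and vdW radii.
    """
    if topology.alpha is not None:
        a = np.array([topology.alpha.get(n, 0.0) for n in topology.atom_names])
        return AlphaFractions(a / a.sum(), [])
    if topology.reference_coords is None:
        raise ValueError(
            f"probe {topology.probe_name} has neither supplied alpha nor "
            "reference coordinates for a SASA calculation"
        )
    spheres = [
        AtomSphere(tuple(xyz), r)
        for xyz, r in zip(topology.reference_coords, topology.radii)
    ]
    return alpha_fractions([spheres], None, probe_radius, n_points)
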