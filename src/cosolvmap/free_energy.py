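"""Boltzmann inversion: voxel occupancy counts to binding free energies.

The binding free energy of a probe group at voxel *v* follows from the
ratio of its observed occupancy to the occupancy expected in bulk:

    dG(v) = -k_B T ln(N_v / N_o)

A voxel visited exactly as often as bulk scores 0; enrichment gives
negative (favourable) values.  Zero-count voxels carry no information
about how unfavourable the voxel is beyond the sampling floor; by
default they are masked as undefined rather than set to +infinity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density import CountGrid
from .grid import ScalarGrid

__all__ = ["ThermoParams", "counts_to_dg", "dg_to_expected_counts"]

#: Boltzmann constant in kcal/(mol K); energies are kcal/mol throughout.
K_B = 1.987204e-3


@dataclass(frozen=True)
class ThermoParams:
    """Simulation temperature and Boltzmann constant.

    Default 300 K; set this to the temperature the snapshots were
    generated at.
    """

    temperature: float = 300.0
    k_B: float = K_B

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")

    @property
    def kT(self) -> float:
        """Thermal energy k_B*T in kcal/mol."""
        return self.k_B * self.temperature


def counts_to_dg(
    counts: CountGrid | np.ndarray,
    n_o: float,
    thermo: ThermoParams = ThermoParams(),
    zero_policy: str = "mask",
) -> ScalarGrid:
    """Invert occupancy counts to a free-energy grid (kcal/mol).

    Parameters
    ----------
    counts : CountGrid
    n_o : float
        Expected per-voxel bulk count (> 0), on the same frame/
        multiplicity footing as ``counts``.
    zero_policy : {"mask", "pseudocount"}
        ``mask``: zero-count voxels become undefined.  ``pseudocount``:
        they are evaluated at N=1, i.e. capped at the sampling floor
        ``-kT ln(1/N_o)``.
    """
    if n_o <= 0:
        raise ValueError(f"N_o must be > 0, got {n_o}")
    if zero_policy not in ("mask", "pseudocount"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    if isinstance(counts, CountGrid):
        spec, n = counts.spec, counts.counts
    else:
        raise TypeError("counts must be a CountGrid")
    n = np.asarray(n, dtype=float)
    zero = n == 0
    if zero_policy == "pseudocount":
        n = np.where(zero, 1.0, n)
        mask = np.ones(spec.shape, dtype=bool)
    else:
        n = np.where(zero, np.nan, n)
        mask = ~zero
    with np.errstate(invalid="ignore"):
        dg = -thermo.kT * np.log(n / n_o)
    dg = np.where(mask, dg, 0.0)
    return ScalarGrid(spec, dg, mask)


def dg_to_expected_counts(
    grid: ScalarGrid, n_o: float, thermo: ThermoParams = ThermoParams()
) -> np.ndarray:
    """Exact inverse of :func:`counts_to_dg` on defined voxels.

    Returns the expected (real-valued) counts ``N = N_o exp(-dG/kT)``;
    undefined voxels yield NaN.
    """
    if n_o <= 0:
        raise ValueError(f"N_o must be > 0, got {n_o}")
    n = n_o * np.exp(-grid.values / thermo.kT)
    return np.where(grid.defined_mask, n, np.nan)
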