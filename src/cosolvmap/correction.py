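"""Atomic repartition of the molecular binding free energy.

The raw per-atom map ``dG_i(v)`` overstates an atom's intrinsic
affinity because the atom's density at *v* is driven by the whole
molecule's binding.  Given the molecular map ``dG_M`` (from the CoM
density) and the atom's partition fraction ``alpha_i``, the expected
contribution of the *rest* of the molecule is ``(1 - alpha_i) dG_M``,
and the corrected, transferable atomic contribution is

    dG_i_corr = dG_i - (1 - alpha_i) * dG_M .

Because the CoM explores a range of positions while atom *i* sits in a
given voxel, ``dG_M`` is evaluated at the CoM's voxel of each snapshot
and the correction is averaged over the N_v observations that fell in
the voxel:

    <dG_i_corr>(v) = (1/N_v) sum_k [ dG_i(v) - (1 - alpha_i) dG_M(u_k) ]

where ``u_k`` is the CoM voxel of observation *k*.  Observations whose
CoM left the grid, or whose CoM voxel has no molecular estimate, are
skipped and tallied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .density import ObservationTrace, TRACE_OOB
from .grid import ScalarGrid

__all__ = [
    "CorrectionResult",
    "expected_atomic_contribution",
    "correct_single",
    "correct_grid",
]


def expected_atomic_contribution(dg_molecular: float, alpha_i: float) -> float:
    """Expected share of the molecular dG carried by atom *i*: ``dG_M * alpha_i``."""
    if not 0.0 <= alpha_i <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha_i}")
    return dg_molecular * alpha_i


def correct_single(dg_i: float, dg_molecular: float, alpha_i: float) -> float:
    """Corrected atomic contribution for one (atom voxel, CoM voxel) pair.

    ``dG_i - (dG_M - dG_M alpha_i) = dG_i - (1 - alpha_i) dG_M``.
    """
    if not 0.0 <= alpha_i <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha_i}")
    if not (np.isfinite(dg_i) and np.isfinite(dg_molecular)):
        raise ValueError("dG values must be finite")
    return dg_i - (1.0 - alpha_i) * dg_molecular


@dataclass
class CorrectionResult:
    """Corrected per-atom free-energy grid with observation bookkeeping.

    ``grid`` is defined only where the raw atomic map is defined and at
    least one observation with a usable CoM landed; ``n_observations``
    counts the usable observations per voxel.
    """

    grid: ScalarGrid
    n_observations: np.ndarray
    alpha: float
    skipped_oob_com: int = 0
    skipped_undefined_com: int = 0
    metadata: dict = field(default_factory=dict)

    @property
    def n_used(self) -> int:
        return int(self.n_observations.sum())


def correct_grid(
    raw_atomic_dg: ScalarGrid,
    molecular_dg: ScalarGrid,
    trace: ObservationTrace,
    alpha: float,
    metadata: dict | None = None,
) -> CorrectionResult:
    """Apply the atomic repartition over an observation trace.

    Parameters
    ----------
    raw_atomic_dg, molecular_dg : ScalarGrid
        Per-atom and CoM free-energy maps on the same lattice.
    trace : ObservationTrace
        Atom-voxel / CoM-voxel pairs from ``density.accumulate`` for the
        same chemotype map.
    alpha : float
        Partition fraction of the observed atom (for a chemotype of
        equivalent atoms, their common per-atom alpha).
    """
    if raw_atomic_dg.spec != molecular_dg.spec:
        raise ValueError("atomic and molecular grids are on different lattices")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    spec = raw_atomic_dg.spec

    avox = np.asarray(trace.atom_voxel, dtype=np.int64)
    cvox = np.asarray(trace.com_voxel, dtype=np.int64)
    mol_flat = molecular_dg.values.reshape(-1)
    mol_mask = molecular_dg.defined_mask.reshape(-1)

    oob = cvox == TRACE_OOB
    safe_c = np.where(oob, 0, cvox)
    undefined = ~oob & ~mol_mask[safe_c]
    usable = ~oob & ~undefined

    sums = np.zeros(spec.n_voxels)
    nobs = np.zeros(spec.n_voxels, dtype=np.int64)
    np.add.at(sums, avox[usable], mol_flat[cvox[usable]])
    np.add.at(nobs, avox[usable], 1)

    raw_flat = raw_atomic_dg.values.reshape(-1)
    raw_mask = raw_atomic_dg.defined_mask.reshape(-1)
    defined = raw_mask & (nobs > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_mol = np.where(nobs > 0, sums / np.maximum(nobs, 1), 0.0)
    corrected = np.where(defined, raw_flat - (1.0 - alpha) * mean_mol, 0.0)

    grid = ScalarGrid(spec, corrected.reshape(spec.shape), defined.reshape(spec.shape))
    return CorrectionResult(
        grid=grid,
        n_observations=nobs.reshape(spec.shape),
        alpha=float(alpha),
        skipped_oob_com=int(oob.sum()),
        skipped_undefined_com=int(undefined.sum()),
        metadata=metadata or {},
    )
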