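"""Shared fixtures: hand-authored multi-model PDB text and small grids."""

from __future__ import annotations

import numpy as np
import pytest

from cosolvmap import GridSpec


def format_pdb(frames, resname="ETH", atom_names=("C1", "C2", "O"), chain="A"):
    """Render frames of probe instances as fixed-width multi-model PDB text.

    ``frames`` is a list (models) of lists (instances) of (n_atoms, 3)
    coordinate arrays.  Written by hand, independent of any PDB library,
    so it doubles as a format oracle for the reader.
    """
    lines = []
    serial = 1
    for m, instances in enumerate(frames, start=1):
        lines.append(f"MODEL     {m:4d}")
        for res_id, coords in enumerate(instances, start=1):
            for name, (x, y, z) in zip(atom_names, np.atleast_2d(coords)):
                element = name[0]
                # columns: name 13-16, altLoc 17, resName 18-20, chain 22, resSeq 23-26
                lines.append(
                    f"HETATM{serial:5d} {name:<4s} {resname:>3s} {chain}{res_id:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                    f"{element:>2s}"
                )
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def small_spec():
    return GridSpec((0.0, 0.0, 0.0), 0.5, (10, 10, 10))


@pytest.fixture
def pdb_file(tmp_path):
    """Factory writing PDB text to a temp file and returning its path."""

    def _write(frames, resname="ETH", atom_names=("C1", "C2", "O"), name="snap.pdb"):
        path = tmp_path / name
        path.write_text(format_pdb(frames, resname, atom_names))
        return str(path)

    return _write
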