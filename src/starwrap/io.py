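"""Text trajectory output: LAMMPS-dump-dialect frames plus bond tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .membrane_builder import SystemState

__all__ = ["append_dump_frame", "write_bond_table"]


def append_dump_frame(state: SystemState, path, step: int) -> None:
    """Append one frame in LAMMPS dump format (id, type, x, y, z)."""
    with open(path, "a") as fh:
        fh.write("ITEM: TIMESTEP\n")
        fh.write(f"{step}\n")
        fh.write("ITEM: NUMBER OF ATOMS\n")
        fh.write(f"{state.n_beads}\n")
        fh.write("ITEM: BOX BOUNDS pp pp ff\n")
        fh.write(f"0.0 {state.box[0]:.8f}\n")
        fh.write(f"0.0 {state.box[1]:.8f}\n")
        fh.write(f"{-state.box[2] / 2:.8f} {state.box[2] / 2:.8f}\n")
        fh.write("ITEM: ATOMS id type x y z\n")
        for i in range(state.n_beads):
            x, y, z = state.pos[i]
            fh.write(f"{i + 1} {state.kind[i] + 1} {x:.6f} {y:.6f} {z:.6f}\n")


def write_bond_table(state: SystemState, path) -> None:
    """Current ligand-receptor bonds as a two-column text table."""
    with open(path, "w") as fh:
        fh.write("# ligand_id receptor_id\n")
        for lig, rec in sorted(state.lr_bonds.items()):
            fh.write(f"{lig} {rec}\n")
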