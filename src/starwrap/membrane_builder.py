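"""Bilayer construction, receptor assignment, and particle insertion.

The membrane is the synthetic input generator for the whole pipeline: a
square two-leaflet lattice of 3-bead lipids (head, tail1, tail2), each
lipid carrying two FENE bonds and one harmonic angle.  Lipid beads are
stored first (lipid ``i`` occupies beads ``3i .. 3i+2``), nanoparticle
beads are appended by :func:`assemble_system`.

The box is periodic in X and Y and open in Z (implicit solvent).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .forcefield import (
    LIPID_HEAD,
    LIPID_TAIL,
    RECEPTOR_HEAD,
    NP_SURFACE,
    LIGAND,
    KIND_NAMES,
)
from .np_geometry import SurfaceBeads, KIND_LIGAND

__all__ = ["SystemState", "build_bilayer", "assign_receptors", "assemble_system",
           "save_checkpoint", "load_checkpoint", "write_lammps_data"]

#: FENE + WCA rest bond length used for initial lattice construction.
BOND_REST = 0.96


@dataclass
class SystemState:
    """Complete simulation state; the single source of truth.

    Dynamic ligand-receptor bonds live in ``lr_partner``: for a ligand
    bead it holds the index of its bonded receptor (and vice versa),
    -1 when unbound.  ``rigid`` lists the nanoparticle bead indices; the
    particle pose is ``com``/``rot`` applied to ``body_coords``.
    """

    pos: np.ndarray                     # (N, 3)
    vel: np.ndarray                     # (N, 3)
    kind: np.ndarray                    # (N,) int64, forcefield kind codes
    fene_bonds: np.ndarray              # (B, 2) int64
    bond_b: np.ndarray                  # (B,) WCA diameter of each bond pair
    angles: np.ndarray                  # (A, 3) int64
    box: np.ndarray                     # (3,) Lx, Ly, Lz
    time: float = 0.0
    n_lipids: int = 0
    rigid: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    body_coords: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    com: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rot: np.ndarray = field(default_factory=lambda: np.eye(3))
    lr_partner: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    images: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))

    def __post_init__(self):
        n = len(self.pos)
        if len(self.lr_partner) != n:
            self.lr_partner = np.full(n, -1, dtype=np.int64)
        if len(self.images) != n:
            self.images = np.zeros((n, 2), dtype=np.int64)

    # -- derived views ----------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.pos)

    @property
    def head_indices(self) -> np.ndarray:
        """Lipid head beads (receptors included)."""
        return 3 * np.arange(self.n_lipids, dtype=np.int64)

    @property
    def tail2_indices(self) -> np.ndarray:
        return 3 * np.arange(self.n_lipids, dtype=np.int64) + 2

    @property
    def receptor_indices(self) -> np.ndarray:
        return np.flatnonzero(self.kind == RECEPTOR_HEAD)

    @property
    def ligand_indices(self) -> np.ndarray:
        return np.flatnonzero(self.kind == LIGAND)

    @property
    def lr_bonds(self) -> dict:
        """Current ligand -> receptor bond map."""
        out = {}
        for i in self.ligand_indices:
            if self.lr_partner[i] >= 0:
                out[int(i)] = int(self.lr_partner[i])
        return out

    def leaflet_of(self) -> np.ndarray:
        """+1 for upper-leaflet lipids, -1 for lower.

        Leaflet is the sign of the z component of the tail2 -> head
        vector (the lipid's outward normal).
        """
        h = self.pos[self.head_indices]
        t2 = self.pos[self.tail2_indices]
        return np.where(h[:, 2] >= t2[:, 2], 1, -1)

    def exclusions(self) -> np.ndarray:
        """Per-bead bonded-pair exclusions (N, 2), padded with -1."""
        n = self.n_beads
        excl = np.full((n, 2), -1, dtype=np.int64)
        count = np.zeros(n, dtype=np.int64)
        for a, b in self.fene_bonds:
            excl[a, count[a]] = b
            count[a] += 1
            excl[b, count[b]] = a
            count[b] += 1
        return excl

    def body_id(self) -> np.ndarray:
        """-1 for free beads, 0 for the rigid particle."""
        body = np.full(self.n_beads, -1, dtype=np.int64)
        body[self.rigid] = 0
        return body

    def unwrapped_pos(self) -> np.ndarray:
        out = self.pos.copy()
        out[:, 0] += self.images[:, 0] * self.box[0]
        out[:, 1] += self.images[:, 1] * self.box[1]
        return out

    def copy(self) -> "SystemState":
        return SystemState(
            pos=self.pos.copy(), vel=self.vel.copy(), kind=self.kind.copy(),
            fene_bonds=self.fene_bonds.copy(), bond_b=self.bond_b.copy(),
            angles=self.angles.copy(), box=self.box.copy(), time=self.time,
            n_lipids=self.n_lipids, rigid=self.rigid.copy(),
            body_coords=self.body_coords.copy(), com=self.com.copy(),
            rot=self.rot.copy(), lr_partner=self.lr_partner.copy(),
            images=self.images.copy(),
        )


def build_bilayer(
    n_lipids_x: int,
    n_lipids_y: int,
    area_per_lipid: float = 1.13,
    box_xy: tuple[float, float] | None = None,
    inner_gap: float = 1.0,
) -> SystemState:
    """Construct a flat two-leaflet bilayer on a lattice.

    Each leaflet holds ``n_lipids_x * n_lipids_y`` lipids; tails point
    inward, head-tail1-tail2 collinear along z at the rest bond length.
    The box is ``n * sqrt(area_per_lipid)`` per side unless ``box_xy``
    pins it explicitly (lattice spacing then follows the box).
    """
    if n_lipids_x < 1 or n_lipids_y < 1:
        raise ValueError("lattice dimensions must be positive")
    if area_per_lipid <= 0:
        raise ValueError("area_per_lipid must be positive")
    if box_xy is None:
        lx = n_lipids_x * np.sqrt(area_per_lipid)
        ly = n_lipids_y * np.sqrt(area_per_lipid)
    else:
        lx, ly = map(float, box_xy)
    ax, ay = lx / n_lipids_x, ly / n_lipids_y

    n_leaf = n_lipids_x * n_lipids_y
    n_lip = 2 * n_leaf
    pos = np.zeros((3 * n_lip, 3))
    kind = np.empty(3 * n_lip, dtype=np.int64)
    d0 = BOND_REST
    half = inner_gap / 2.0

    lip = 0
    for leaf, zsign, off in ((0, 1.0, 0.25), (1, -1.0, 0.75)):
        for i in range(n_lipids_x):
            for j in range(n_lipids_y):
                x = (i + off) * ax
                y = (j + off) * ay
                b = 3 * lip
                # tail2 innermost, head outermost
                pos[b + 2] = (x, y, zsign * half)
                pos[b + 1] = (x, y, zsign * (half + d0))
                pos[b + 0] = (x, y, zsign * (half + 2 * d0))
                kind[b] = LIPID_HEAD
                kind[b + 1] = LIPID_TAIL
                kind[b + 2] = LIPID_TAIL
                lip += 1

    bonds = np.empty((2 * n_lip, 2), dtype=np.int64)
    bond_b = np.empty(2 * n_lip)
    angles = np.empty((n_lip, 3), dtype=np.int64)
    for l in range(n_lip):
        b = 3 * l
        bonds[2 * l] = (b, b + 1)
        bond_b[2 * l] = 0.95      # head-tail excluded volume
        bonds[2 * l + 1] = (b + 1, b + 2)
        bond_b[2 * l + 1] = 1.0   # tail-tail excluded volume
        angles[l] = (b, b + 1, b + 2)

    lz = 40.0 + 6.0 * d0
    return SystemState(
        pos=pos, vel=np.zeros_like(pos), kind=kind,
        fene_bonds=bonds, bond_b=bond_b, angles=angles,
        box=np.array([lx, ly, lz]), n_lipids=n_lip,
    )


def assign_receptors(state: SystemState, fraction: float, seed: int | None = 0) -> SystemState:
    """Relabel a uniform random subset of lipid heads as receptors."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("receptor fraction must lie in [0, 1]")
    heads = state.head_indices
    n_pick = int(round(fraction * len(heads)))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(heads, size=n_pick, replace=False)
    out = state.copy()
    out.kind[state.head_indices] = LIPID_HEAD
    out.kind[chosen] = RECEPTOR_HEAD
    return out


def assemble_system(
    membrane: SystemState,
    particle: SurfaceBeads | None,
    standoff: float = 1.0,
    contact: float = 1.0,
) -> SystemState:
    """Insert a rigid particle above the upper leaflet, centered in XY.

    The lowest particle bead sits at ``contact + standoff`` above the
    mean upper-leaflet head plane (``contact`` is the WCA contact
    diameter of nanoparticle beads against lipids).
    """
    if particle is None or len(particle) == 0:
        return membrane.copy()
    coords = particle.coordinates - particle.coordinates.mean(axis=0)
    extent = 2.0 * np.abs(coords[:, :2]).max()
    if extent >= min(membrane.box[0], membrane.box[1]):
        raise ValueError("particle does not fit laterally in the box")

    leaf = membrane.leaflet_of()
    heads = membrane.pos[membrane.head_indices]
    z_head = heads[leaf == 1, 2].mean()
    z_target = z_head + contact + standoff - coords[:, 2].min()
    com = np.array([membrane.box[0] / 2.0, membrane.box[1] / 2.0, z_target])

    n0 = membrane.n_beads
    npart = len(coords)
    out = membrane.copy()
    out.pos = np.vstack([membrane.pos, coords + com])
    out.vel = np.vstack([membrane.vel, np.zeros((npart, 3))])
    pk = np.where(particle.kind == KIND_LIGAND, LIGAND, NP_SURFACE)
    out.kind = np.concatenate([membrane.kind, pk.astype(np.int64)])
    out.rigid = n0 + np.arange(npart, dtype=np.int64)
    out.body_coords = coords
    out.com = com
    out.rot = np.eye(3)
    out.lr_partner = np.full(out.n_beads, -1, dtype=np.int64)
    out.images = np.vstack([membrane.images, np.zeros((npart, 2), dtype=np.int64)])

    # overlap audit: the placement above the head plane must leave every
    # particle-membrane gap at or beyond 0.9 of the contact diameter
    from scipy.spatial import cKDTree

    d, _ = cKDTree(out.pos[:n0]).query(out.pos[n0:], k=1)
    if d.min() < 0.9 * contact:
        raise ValueError(f"particle overlaps membrane: min gap {d.min():.3f}")
    if out.box[2] < z_target + coords[:, 2].max() + 10.0:
        out.box[2] = z_target + coords[:, 2].max() + 10.0
    return out


# ---------------------------------------------------------------------------
# checkpoints and LAMMPS-dialect export
# ---------------------------------------------------------------------------

def save_checkpoint(state: SystemState, path) -> None:
    np.savez_compressed(
        path, pos=state.pos, vel=state.vel, kind=state.kind,
        fene_bonds=state.fene_bonds, bond_b=state.bond_b,
        angles=state.angles, box=state.box, time=state.time,
        n_lipids=state.n_lipids, rigid=state.rigid,
        body_coords=state.body_coords, com=state.com, rot=state.rot,
        lr_partner=state.lr_partner, images=state.images,
    )


def load_checkpoint(path) -> SystemState:
    z = np.load(path)
    return SystemState(
        pos=z["pos"], vel=z["vel"], kind=z["kind"],
        fene_bonds=z["fene_bonds"], bond_b=z["bond_b"], angles=z["angles"],
        box=z["box"], time=float(z["time"]), n_lipids=int(z["n_lipids"]),
        rigid=z["rigid"], body_coords=z["body_coords"], com=z["com"],
        rot=z["rot"], lr_partner=z["lr_partner"], images=z["images"],
    )


def write_lammps_data(state: SystemState, path) -> None:
    """Export as a LAMMPS data file (atom_style angle dialect)."""
    n = state.n_beads
    ntypes = len(KIND_NAMES)
    with open(path, "w") as fh:
        fh.write("starwrap system\n\n")
        fh.write(f"{n} atoms\n{len(state.fene_bonds)} bonds\n"
                 f"{len(state.angles)} angles\n\n")
        fh.write(f"{ntypes} atom types\n2 bond types\n1 angle types\n\n")
        fh.write(f"0.0 {state.box[0]:.8f} xlo xhi\n")
        fh.write(f"0.0 {state.box[1]:.8f} ylo yhi\n")
        fh.write(f"{-state.box[2] / 2:.8f} {state.box[2] / 2:.8f} zlo zhi\n\n")
        fh.write("Masses\n\n")
        for k in range(ntypes):
            fh.write(f"{k + 1} 1.0\n")
        fh.write("\nAtoms # angle\n\n")
        for i in range(n):
            mol = i // 3 + 1 if i < 3 * state.n_lipids else state.n_lipids + 1
            x, y, z = state.pos[i]
            fh.write(f"{i + 1} {mol} {state.kind[i] + 1} "
                     f"{x:.8f} {y:.8f} {z:.8f}\n")
        fh.write("\nBonds\n\n")
        for bi, (a, b) in enumerate(state.fene_bonds):
            btype = 1 if state.bond_b[bi] < 1.0 else 2
            fh.write(f"{bi + 1} {btype} {a + 1} {b + 1}\n")
        fh.write("\nAngles\n\n")
        for ai, (a, b, c) in enumerate(state.angles):
            fh.write(f"{ai + 1} 1 {a + 1} {b + 1} {c + 1}\n")
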