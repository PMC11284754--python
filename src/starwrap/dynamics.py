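"""Time integration: Langevin dynamics, zero-tension barostat, rigid
nanoparticle motion, and stochastic ligand-receptor bond kinetics.

The fast path is :func:`simulate`, which hands the whole stepping loop to
a compiled kernel.  The single-step operations (:func:`langevin_step`,
:func:`barostat_xy`, :func:`update_lr_bonds`, :func:`rigid_particle_step`)
wrap the same kernels so both routes share one implementation; a pure
NumPy all-pairs force oracle (:func:`reference_forces`) stays independent
for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels as K
from .forcefield import (
    ForceField, LIGAND, RECEPTOR_HEAD,
    fene_energy, fene_force, wca_energy, wca_force,
    cos_attraction_energy, cos_attraction_force,
    morse_energy, morse_force,
    POT_NONE, POT_WCA, POT_COS,
)
from .membrane_builder import SystemState, build_bilayer, assign_receptors, assemble_system
from .np_geometry import generate_particle
from .observables import WrappingTrace, wrapping_fraction

__all__ = [
    "IntegratorConfig",
    "BondKinetics",
    "IntegrationError",
    "simulate",
    "langevin_step",
    "barostat_xy",
    "update_lr_bonds",
    "rigid_particle_step",
    "run_wrapping",
    "reference_forces",
    "measure_tension",
]


class IntegrationError(RuntimeError):
    """Raised when the integrator fails (overstretch, blow-up, collapse)."""

    def __init__(self, message: str, step: int):
        super().__init__(f"{message} (step {step})")
        self.step = step


@dataclass(frozen=True)
class IntegratorConfig:
    dt: float = 0.01                 # tau
    temperature: float = 1.0         # eps / k_B
    gamma: float = 1.0               # 1 / tau, Langevin damping
    barostat_damp: float = 1.0       # tau, pressure coupling time
    barostat_modulus: float = 20.0   # eps / sigma^2, area-rescale stiffness
    target_tension: float = 0.0
    steps: int = 0
    seed: int = 0
    bond_check_interval: int = 10    # steps between kinetics sweeps
    nlist_every: int = 10
    skin: float = 0.4
    frozen_particle: bool = False

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")


@dataclass(frozen=True)
class BondKinetics:
    r_form: float = 1.3
    p_form: float = 0.5
    r_break: float = 4.0

    def __post_init__(self):
        if not self.r_form < self.r_break:
            raise ValueError("require r_form < r_break")
        if not 0.0 <= self.p_form <= 1.0:
            raise ValueError("p_form must be a probability")


@dataclass
class SimResult:
    times: np.ndarray
    morse_energy: np.ndarray
    bond_count: np.ndarray
    area: np.ndarray
    temperature: np.ndarray
    head_times: np.ndarray
    head_positions: np.ndarray       # (n_frames, n_heads, 3), unwrapped


_STATUS_MSG = {
    K.STATUS_FENE: "FENE bond overstretched",
    K.STATUS_NONFINITE: "non-finite coordinate",
    K.STATUS_COLLAPSE: "box collapsed below 4 sigma",
}


def simulate(
    state: SystemState,
    ff: ForceField,
    cfg: IntegratorConfig,
    n_steps: int | None = None,
    kinetics: BondKinetics | None = None,
    barostat: bool = True,
    sample_every: int = 100,
    traj_every: int = 0,
    seed: int | None = None,
) -> SimResult:
    """Advance ``state`` in place by ``n_steps`` and record observables.

    ``kinetics=None`` disables bond formation/breaking;
    ``traj_every > 0`` records unwrapped lipid head positions at that
    step stride.
    """
    n_steps = cfg.steps if n_steps is None else int(n_steps)
    seed = cfg.seed if seed is None else int(seed)
    pot, btab, wctab = ff.pot_arrays()
    excl = state.exclusions()
    body = state.body_id()
    lig_idx = state.ligand_indices

    kin = kinetics or BondKinetics()
    bond_every = cfg.bond_check_interval if kinetics is not None else 0

    n_samples_max = n_steps // max(1, sample_every) + 1
    out_time = np.zeros(n_samples_max)
    out_wrape = np.zeros(n_samples_max)
    out_nbonds = np.zeros(n_samples_max, dtype=np.int64)
    out_area = np.zeros(n_samples_max)
    out_temp = np.zeros(n_samples_max)
    head_idx = state.head_indices
    if traj_every > 0:
        n_frames_max = n_steps // traj_every + 1
        out_heads = np.zeros((n_frames_max, len(head_idx), 3))
    else:
        out_heads = np.zeros((1, 0, 3))
        head_idx = np.empty(0, dtype=np.int64)

    rigid_vel = np.zeros(3)
    rigid_angvel = np.zeros(3)
    status, last_step, n_samples, n_frames = K.run_md(
        state.pos, state.vel, state.images, state.kind, body, excl,
        state.fene_bonds, state.bond_b, state.angles,
        state.rigid, state.body_coords, state.com, state.rot,
        rigid_vel, rigid_angvel,
        state.lr_partner, lig_idx,
        pot, btab, wctab,
        ff.k_fene, ff.fene_rmax, ff.k_angle, ff.theta0,
        ff.morse.eps_lr, ff.morse.r0, ff.morse.alpha,
        kin.r_form, kin.p_form, kin.r_break, bond_every,
        state.box, cfg.dt, cfg.temperature, cfg.gamma,
        barostat, cfg.barostat_damp, cfg.barostat_modulus,
        cfg.frozen_particle,
        n_steps, cfg.nlist_every, cfg.skin, seed,
        sample_every, out_time, out_wrape, out_nbonds, out_area, out_temp,
        traj_every, head_idx, out_heads,
        state.time,
    )
    if status != K.STATUS_OK:
        raise IntegrationError(_STATUS_MSG[status], last_step)
    state.time += n_steps * cfg.dt
    traj_times = state.time - n_steps * cfg.dt + cfg.dt * traj_every * (
        1 + np.arange(n_frames)
    ) if traj_every > 0 else np.empty(0)
    return SimResult(
        times=out_time[:n_samples],
        morse_energy=out_wrape[:n_samples],
        bond_count=out_nbonds[:n_samples],
        area=out_area[:n_samples],
        temperature=out_temp[:n_samples],
        head_times=traj_times,
        head_positions=out_heads[:n_frames],
    )


def langevin_step(
    state: SystemState, ff: ForceField, cfg: IntegratorConfig,
    seed: int | None = None,
) -> SystemState:
    """One velocity-Verlet Langevin update of all non-rigid beads."""
    simulate(state, ff, cfg, n_steps=1, kinetics=None, barostat=False,
             sample_every=0, seed=seed)
    return state


def rigid_particle_step(
    state: SystemState, ff: ForceField, cfg: IntegratorConfig,
    seed: int | None = None,
) -> SystemState:
    """One integrator step; the particle moves as a thermostatted rigid body."""
    if len(state.rigid) == 0:
        raise ValueError("state has no rigid particle")
    simulate(state, ff, cfg, n_steps=1, kinetics=None, barostat=False,
             sample_every=0, seed=seed)
    return state


def measure_tension(state: SystemState, ff: ForceField) -> float:
    """Instantaneous 2D lateral pressure (energy / area); zero at rest."""
    _, _, vir = reference_forces(state, ff)
    free = np.ones(state.n_beads, dtype=bool)
    free[state.rigid] = False
    ke_xy = float(np.sum(state.vel[free, 0] ** 2 + state.vel[free, 1] ** 2))
    area = state.box[0] * state.box[1]
    return 0.5 * (ke_xy + vir) / area


def barostat_xy(state: SystemState, cfg: IntegratorConfig, ff: ForceField | None = None) -> SystemState:
    """One zero-tension Berendsen rescale of the XY box (Lz untouched)."""
    ff = ff or ForceField()
    tension = measure_tension(state, ff) - cfg.target_tension
    mu = 1.0 + cfg.dt * tension / (2.0 * cfg.barostat_damp * cfg.barostat_modulus)
    mu = float(np.clip(mu, 0.9995, 1.0005))
    state.box[0] *= mu
    state.box[1] *= mu
    if state.box[0] < 4.0:
        raise IntegrationError("box collapsed below 4 sigma", 0)
    free = np.ones(state.n_beads, dtype=bool)
    free[state.rigid] = False
    state.pos[free, 0] *= mu
    state.pos[free, 1] *= mu
    state.com[:2] *= mu
    if len(state.rigid):
        state.pos[state.rigid] = state.com + state.body_coords @ state.rot.T
    return state


def update_lr_bonds(
    state: SystemState,
    kinetics: BondKinetics,
    rng: np.random.Generator | int | None = None,
) -> SystemState:
    """Break overstretched bonds, then form new ones stochastically.

    Unbound ligand-receptor pairs within ``r_form`` bond with probability
    ``p_form``, processed in randomized order; valence (one bond per
    ligand and per receptor) is preserved by construction.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    lx, ly = state.box[0], state.box[1]

    def dist(i, j):
        d = state.pos[i] - state.pos[j]
        d[0] -= lx * np.round(d[0] / lx)
        d[1] -= ly * np.round(d[1] / ly)
        return float(np.linalg.norm(d))

    for i in state.ligand_indices:
        j = state.lr_partner[i]
        if j >= 0 and dist(i, j) > kinetics.r_break:
            state.lr_partner[i] = -1
            state.lr_partner[j] = -1

    ligands = state.ligand_indices
    receptors = state.receptor_indices
    if len(ligands) == 0 or len(receptors) == 0:
        return state

    def shifted(idx):
        p = state.pos[idx].copy()
        p[:, 0] = np.mod(p[:, 0], lx)
        p[:, 1] = np.mod(p[:, 1], ly)
        return p

    lp = shifted(ligands)
    rp = shifted(receptors)
    zmin = min(lp[:, 2].min(), rp[:, 2].min()) - 1.0
    lp[:, 2] -= zmin
    rp[:, 2] -= zmin
    tree = cKDTree(rp, boxsize=[lx, ly, 1e9])
    cand = []
    for li, neigh in enumerate(tree.query_ball_point(lp, kinetics.r_form)):
        for ri in neigh:
            cand.append((int(ligands[li]), int(receptors[ri])))
    order = rng.permutation(len(cand))
    for k in order:
        lig, rec = cand[k]
        if state.lr_partner[lig] >= 0 or state.lr_partner[rec] >= 0:
            continue
        if rng.random() < kinetics.p_form:
            state.lr_partner[lig] = rec
            state.lr_partner[rec] = lig
    return state


# ---------------------------------------------------------------------------
# all-pairs reference oracle
# ---------------------------------------------------------------------------

def reference_forces(state: SystemState, ff: ForceField):
    """O(N^2) force/energy/virial evaluation built from the scalar potentials.

    Independent of the neighbor-list kernels; intended for small systems.
    Returns (forces, total_energy, virial_xy).
    """
    n = state.n_beads
    pos = state.pos
    lx, ly = state.box[0], state.box[1]
    forces = np.zeros((n, 3))
    energy = 0.0
    vir = 0.0
    excl = {tuple(sorted(b)) for b in map(tuple, state.fene_bonds)}
    body = state.body_id()
    pot_tab, b_tab, wc_tab = ff.pot_arrays()

    def mi(d):
        d = d.copy()
        d[0] -= lx * np.round(d[0] / lx)
        d[1] -= ly * np.round(d[1] / ly)
        return d

    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excl:
                continue
            if body[i] >= 0 and body[i] == body[j]:
                continue
            p = pot_tab[state.kind[i], state.kind[j]]
            if p == POT_NONE:
                continue
            if state.lr_partner[i] == j:
                continue
            d = mi(pos[i] - pos[j])
            r = float(np.linalg.norm(d))
            b = b_tab[state.kind[i], state.kind[j]]
            e = wca_energy(r, b)
            f = wca_force(r, b)
            if p == POT_COS:
                e += cos_attraction_energy(r, b, wc_tab[state.kind[i], state.kind[j]])
                f += cos_attraction_force(r, b, wc_tab[state.kind[i], state.kind[j]])
            energy += e
            fv = f * d / r
            forces[i] += fv
            forces[j] -= fv
            vir += fv[0] * d[0] + fv[1] * d[1]

    for bi, (i, j) in enumerate(state.fene_bonds):
        d = mi(pos[i] - pos[j])
        r = float(np.linalg.norm(d))
        energy += fene_energy(r, ff) + wca_energy(r, state.bond_b[bi])
        f = fene_force(r, ff) + wca_force(r, state.bond_b[bi])
        fv = f * d / r
        forces[i] += fv
        forces[j] -= fv
        vir += fv[0] * d[0] + fv[1] * d[1]

    for (a, b_, c) in state.angles:
        u = mi(pos[a] - pos[b_])
        v = mi(pos[c] - pos[b_])
        ru, rv = np.linalg.norm(u), np.linalg.norm(v)
        ct = float(np.clip(u @ v / (ru * rv), -1.0, 1.0))
        th = np.arccos(ct)
        energy += ff.k_angle * (th - ff.theta0) ** 2
        st = max(np.sqrt(1.0 - ct * ct), 1e-8)
        coef = 2.0 * ff.k_angle * (th - ff.theta0) / st
        fa = coef * (v / rv - ct * u / ru) / ru
        fc = coef * (u / ru - ct * v / rv) / rv
        forces[a] += fa
        forces[c] += fc
        forces[b_] -= fa + fc
        vir += fa[0] * u[0] + fa[1] * u[1] + fc[0] * v[0] + fc[1] * v[1]

    for i in state.ligand_indices:
        j = state.lr_partner[i]
        if j < 0:
            continue
        d = mi(pos[i] - pos[j])
        r = float(np.linalg.norm(d))
        energy += morse_energy(r, ff.morse)
        fv = morse_force(r, ff.morse) * d / r
        forces[i] += fv
        forces[j] -= fv
        vir += fv[0] * d[0] + fv[1] * d[1]

    return forces, energy, vir


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_wrapping(config, replica_id: int = 0, progress: bool = False) -> WrappingTrace:
    """Build -> equilibrate -> insert particle -> wrap, for one replica.

    ``config`` is a :class:`starwrap.config.RunConfig`; the replica seed
    is derived deterministically from the master seed.
    """
    seed = int(np.random.SeedSequence([config.master_seed, replica_id]).generate_state(1)[0])
    ff = config.forcefield
    cfg = replace(config.integrator, seed=seed)
    mem = config.membrane

    state = build_bilayer(mem.n_lipids_x, mem.n_lipids_y, mem.area_per_lipid,
                          box_xy=mem.box_xy)
    eq_steps = int(round(mem.equilibration_tau / cfg.dt))
    if eq_steps > 0:
        simulate(state, ff, cfg, n_steps=eq_steps, kinetics=None,
                 barostat=True, sample_every=max(1, eq_steps // 50), seed=seed)
    state = assign_receptors(state, mem.receptor_fraction, seed=seed + 1)

    particle = generate_particle(config.particle, seed=seed + 2)
    state = assemble_system(state, particle, standoff=config.standoff)

    horizon_steps = int(round(config.horizon_tau / cfg.dt))
    res = simulate(
        state, ff, cfg, n_steps=horizon_steps,
        kinetics=config.kinetics, barostat=config.barostat_during_wrapping,
        sample_every=config.sample_every, traj_every=config.traj_every,
        seed=seed + 3,
    )
    n_lig = max(1, len(state.ligand_indices))
    frac = np.clip(np.abs(res.morse_energy) / (n_lig * ff.morse.eps_lr), 0.0, 1.0)
    return WrappingTrace(
        times=res.times,
        wrap_fraction=frac,
        bond_count=res.bond_count,
        head_positions=res.head_positions,
        head_times=res.head_times,
        replica_id=replica_id,
        seed=seed,
        meta={
            "box_xy": (float(state.box[0]), float(state.box[1])),
            "final_state": state,
            "bond_check_interval": cfg.bond_check_interval,
            "area": res.area,
            "temperature": res.temperature,
        },
    )
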