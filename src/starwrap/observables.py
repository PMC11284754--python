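"""Analysis observables: wrapping fraction/time, thickness, displacement.

All functions are pure: they consume a :class:`SystemState` or a
:class:`WrappingTrace` and return plain numbers/arrays, so each can be
cross-checked against brute-force recomputations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import griddata
from scipy.spatial import cKDTree

from .forcefield import ForceField, morse_energy
from .membrane_builder import SystemState

__all__ = [
    "WrappingTrace",
    "ThicknessMap",
    "PermeabilityInputs",
    "wrapping_fraction",
    "wrapping_time",
    "membrane_thickness",
    "vesicle_lipids",
    "lipid_displacement",
    "relative_wrapping_time",
    "transwell_papp",
]

_WCA_CUT = 2.0 ** (1.0 / 6.0)


@dataclass
class WrappingTrace:
    """Time series from one wrapping replica."""

    times: np.ndarray                   # (n,) tau, strictly increasing
    wrap_fraction: np.ndarray           # (n,) in [0, 1], energy-based
    bond_count: np.ndarray              # (n,) int
    head_positions: np.ndarray = field(default_factory=lambda: np.empty((0, 0, 3)))
    head_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    replica_id: int = 0
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.wrap_fraction = np.asarray(self.wrap_fraction, dtype=float)
        self.bond_count = np.asarray(self.bond_count)
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("trace times must be strictly increasing")
        if len(self.wrap_fraction) and (
            self.wrap_fraction.min() < -1e-12 or self.wrap_fraction.max() > 1 + 1e-12
        ):
            raise ValueError("wrap_fraction must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times,
            "wrap_fraction": self.wrap_fraction,
            "bond_count": self.bond_count,
        })


@dataclass
class ThicknessMap:
    """Per-bin leaflet separation over the XY box."""

    grid: np.ndarray                # (nx, ny) thickness in sigma
    bin_width: float
    mean: float
    sd: float
    interpolated_mask: np.ndarray   # True where a leaflet bin was filled in


@dataclass
class PermeabilityInputs:
    """Transwell permeability assay constants (lab units)."""

    V_ul: float = 750.0       # basolateral volume, microliters
    A_cm2: float = 0.3        # insert membrane area, cm^2
    C0_mg_ml: float = 0.5     # initial apical concentration, mg/mL
    dC_mg_ml: float = 0.0     # basolateral concentration change, mg/mL
    dt_h: float = 4.0         # diffusion time, hours

    def __post_init__(self):
        if min(self.V_ul, self.A_cm2, self.C0_mg_ml, self.dt_h) <= 0:
            raise ValueError("V, A, C0 and dt must be positive")
        if self.dC_mg_ml < 0:
            raise ValueError("dC must be non-negative")


def wrapping_fraction(state: SystemState, ff: ForceField) -> float:
    """|sum of Morse bond energies| / (N_ligands * eps_LR), clamped to [0,1].

    Equals 1 exactly when every ligand is bonded at the Morse minimum.
    """
    ligands = state.ligand_indices
    if len(ligands) == 0:
        raise ValueError("system has no ligands")
    total = 0.0
    lx, ly = state.box[0], state.box[1]
    for i in ligands:
        j = state.lr_partner[i]
        if j < 0:
            continue
        d = state.pos[i] - state.pos[j]
        d[0] -= lx * np.round(d[0] / lx)
        d[1] -= ly * np.round(d[1] / ly)
        total += morse_energy(float(np.linalg.norm(d)), ff.morse)
    return float(np.clip(abs(total) / (len(ligands) * ff.morse.eps_lr), 0.0, 1.0))


def wrapping_time(
    trace: WrappingTrace,
    threshold: float = 0.9,
    hold: float = 100.0,
    smooth_window: int = 5,
) -> float | None:
    """First time the smoothed wrapping fraction reaches and holds ``threshold``.

    Returns None if wrapping never completes within the trace (the "not
    fully taken up" outcome).  A crossing counts only if the fraction
    stays at or above threshold for at least ``hold`` tau.
    """
    t = trace.times
    if len(t) == 0:
        raise ValueError("empty trace")
    w = trace.wrap_fraction
    if smooth_window > 1 and len(w) >= smooth_window:
        kern = np.ones(smooth_window) / smooth_window
        w = np.convolve(w, kern, mode="same")
        # edges of the centered moving average are biased; use raw values
        h = smooth_window // 2
        w[:h] = trace.wrap_fraction[:h]
        w[-h:] = trace.wrap_fraction[-h:]
    above = w >= threshold
    n = len(t)
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        sustained = (t[j] - t[i] >= hold) or (j == n - 1 and t[-1] - t[i] >= hold)
        if sustained:
            return float(t[i])
        i = j + 1
    return None


def membrane_thickness(
    state: SystemState,
    bin_width: float = 0.5,
    exclude_lipids: np.ndarray | None = None,
) -> ThicknessMap:
    """Binned leaflet-projection thickness map.

    Heads are assigned to leaflets by the sign of the z component of the
    tail2 -> head vector, binned on a ``bin_width`` XY grid; per-bin mean
    head z is computed for each leaflet, empty bins are filled by linear
    interpolation (nearest-neighbor fallback at the hull edge), and the
    thickness is the upper-lower difference per bin.
    """
    heads = state.head_indices
    if exclude_lipids is not None and len(exclude_lipids):
        keep = np.ones(state.n_lipids, dtype=bool)
        keep[np.asarray(list(exclude_lipids), dtype=int)] = False
        heads = heads[keep]
    if len(heads) == 0:
        raise ValueError("no lipids to analyze")
    h = state.pos[heads]
    t2 = state.pos[heads + 2]
    upper = h[:, 2] >= t2[:, 2]
    lx, ly = float(state.box[0]), float(state.box[1])
    nx = max(1, int(round(lx / bin_width)))
    ny = max(1, int(round(ly / bin_width)))

    def leaflet_grid(sel):
        if not np.any(sel):
            raise ValueError("a leaflet is empty everywhere")
        x = np.mod(h[sel, 0], lx)
        y = np.mod(h[sel, 1], ly)
        ix = np.minimum((x / lx * nx).astype(int), nx - 1)
        iy = np.minimum((y / ly * ny).astype(int), ny - 1)
        acc = np.zeros((nx, ny))
        cnt = np.zeros((nx, ny))
        np.add.at(acc, (ix, iy), h[sel, 2])
        np.add.at(cnt, (ix, iy), 1.0)
        grid = np.full((nx, ny), np.nan)
        filled = cnt > 0
        grid[filled] = acc[filled] / cnt[filled]
        return grid, filled

    gu, fu = leaflet_grid(upper)
    gl, fl = leaflet_grid(~upper)

    def interpolate(grid, filled):
        if filled.all():
            return grid
        gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        pts = np.column_stack([gx[filled], gy[filled]])
        vals = grid[filled]
        miss = np.column_stack([gx[~filled], gy[~filled]])
        est = griddata(pts, vals, miss, method="linear")
        bad = np.isnan(est)
        if bad.any():
            est[bad] = griddata(pts, vals, miss[bad], method="nearest")
        out = grid.copy()
        out[~filled] = est
        return out

    gu = interpolate(gu, fu)
    gl = interpolate(gl, fl)
    thick = gu - gl
    return ThicknessMap(
        grid=thick,
        bin_width=bin_width,
        mean=float(thick.mean()),
        sd=float(thick.std()),
        interpolated_mask=~(fu & fl),
    )


def vesicle_lipids(state: SystemState, ff: ForceField) -> set[int]:
    """Lipids wrapped around the particle in the final frame.

    Seeds are lipids with any bead within the attraction cutoff
    (2^(1/6) b + wc) of a particle bead; the set is closed under
    tail-tail contact clustering (single linkage at the same cutoff).
    """
    if len(state.rigid) == 0:
        return set()
    cutoff = _WCA_CUT * 1.0 + ff.wc
    lx, ly = state.box[0], state.box[1]

    def wrapped(p):
        q = p.copy()
        q[:, 0] = np.mod(q[:, 0], lx)
        q[:, 1] = np.mod(q[:, 1], ly)
        return q

    np_pos = wrapped(state.pos[state.rigid])
    lip_beads = wrapped(state.pos[: 3 * state.n_lipids])
    boxsize = [lx, ly, 1e9]
    # shift z to positive for the periodic KD-tree
    zmin = min(np_pos[:, 2].min(), lip_beads[:, 2].min()) - 1.0
    np_pos[:, 2] -= zmin
    lb = lip_beads.copy()
    lb[:, 2] -= zmin
    tree = cKDTree(np_pos, boxsize=boxsize)
    d, _ = tree.query(lb, distance_upper_bound=cutoff)
    seed_lipids = set(np.flatnonzero(np.isfinite(d)) // 3)
    if not seed_lipids:
        return set()

    # closure under tail-tail contact
    tails = np.concatenate([
        3 * np.arange(state.n_lipids) + 1,
        3 * np.arange(state.n_lipids) + 2,
    ])
    tp = lb[tails]
    ttree = cKDTree(tp, boxsize=boxsize)
    pairs = ttree.query_pairs(cutoff, output_type="ndarray")
    import networkx as nx  # local: only needed for the closure

    g = nx.Graph()
    g.add_nodes_from(range(state.n_lipids))
    g.add_edges_from(
        np.column_stack([tails[pairs[:, 0]] // 3, tails[pairs[:, 1]] // 3])
    )
    out = set()
    for comp in nx.connected_components(g):
        if comp & seed_lipids:
            out |= comp
    return out


def lipid_displacement(
    trace: WrappingTrace,
    window: float = 100.0,
    lipids: set[int] | np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean per-window head displacement |x(t+window) - x(t)|.

    Uses the unwrapped head positions stored in the trace; raises if a
    single-frame jump larger than half a box length is detected (a sign
    of wrapped coordinates).
    """
    if trace.head_positions.size == 0:
        raise ValueError("trace carries no head positions")
    t = trace.head_times
    pos = trace.head_positions
    if lipids is not None:
        idx = np.asarray(sorted(lipids), dtype=int)
        pos = pos[:, idx, :]
    box = trace.meta.get("box_xy")
    if box is not None and len(t) > 1:
        jumps = np.abs(np.diff(pos[:, :, :2], axis=0))
        if jumps.size and jumps.max() > 0.5 * min(box):
            raise ValueError("periodic jump detected: positions are not unwrapped")
    stride = t[1] - t[0] if len(t) > 1 else window
    k = max(1, int(round(window / stride)))
    rows = []
    for s in range(0, len(t) - k, k):
        disp = np.linalg.norm(pos[s + k] - pos[s], axis=1)
        rows.append((t[s], float(disp.mean())))
    return pd.DataFrame(rows, columns=["window_start", "mean_displacement"])


def relative_wrapping_time(sphere_times: list, star_times: list) -> float | None:
    """Mean sphere wrapping time over mean star wrapping time.

    ``None`` entries mark replicas that never completed.  Returns None if
    no sphere replica completed; raises if the star baseline group never
    completed (no baseline to normalize by).
    """
    star = [t for t in star_times if t is not None]
    if not star:
        raise ValueError("star baseline group has no completed replica")
    sphere = [t for t in sphere_times if t is not None]
    if not sphere:
        return None
    return float(np.mean(sphere) / np.mean(star))


def transwell_papp(inputs: PermeabilityInputs) -> float:
    """Apparent permeability coefficient (V / (A C0)) dC/dt, in cm/s."""
    v_cm3 = inputs.V_ul * 1e-3           # uL -> cm^3
    dt_s = inputs.dt_h * 3600.0
    return (v_cm3 / (inputs.A_cm2 * inputs.C0_mg_ml)) * (inputs.dC_mg_ml / dt_s)
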