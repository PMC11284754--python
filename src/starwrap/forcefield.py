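"""Interaction potentials and the bead-kind pair dispatch table.

All quantities are in reduced units: lengths in sigma, energies in epsilon,
times in tau.  The bead kinds are encoded as small integers (see
:data:`KIND_NAMES`); the pair table maps ordered kind pairs onto a potential
family and its length parameters.

Note on the Morse range parameter: the source parameterization prints the
range constant with units of length, but the exponent ``alpha * (r - r0)``
is only dimensionless if alpha carries inverse length.  ``alpha`` is
therefore interpreted as 1/sigma throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LIPID_HEAD",
    "LIPID_TAIL",
    "RECEPTOR_HEAD",
    "NP_SURFACE",
    "LIGAND",
    "KIND_NAMES",
    "POT_NONE",
    "POT_WCA",
    "POT_COS",
    "MorseParams",
    "ForceField",
    "fene_energy",
    "fene_force",
    "angle_energy",
    "wca_energy",
    "wca_force",
    "cos_attraction_energy",
    "cos_attraction_force",
    "morse_energy",
    "morse_force",
    "pair_dispatch",
]

# Bead kind codes (order matters: indexes the pair tables).
LIPID_HEAD = 0
LIPID_TAIL = 1
RECEPTOR_HEAD = 2
NP_SURFACE = 3
LIGAND = 4

KIND_NAMES = {
    LIPID_HEAD: "lipid_head",
    LIPID_TAIL: "lipid_tail",
    RECEPTOR_HEAD: "receptor_head",
    NP_SURFACE: "np_surface",
    LIGAND: "ligand",
}
_NAME_TO_KIND = {v: k for k, v in KIND_NAMES.items()}

# Potential family codes used in the dispatch table.
POT_NONE = 0
POT_WCA = 1          # purely repulsive excluded volume
POT_COS = 2          # WCA core + cosine-squared attractive tail

_WCA_CUT = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class MorseParams:
    """Ligand-receptor bond potential parameters."""

    eps_lr: float = 30.0   # dissociation energy (epsilon)
    r0: float = 1.0        # equilibrium length (sigma)
    alpha: float = 1.0     # range constant (1/sigma)
    cutoff: float = 4.0    # evaluation cutoff = bond break distance (sigma)


@dataclass(frozen=True)
class ForceField:
    """Full parameter set: bonds, angles, nonbonded pair table, Morse bonds.

    ``pair_table`` maps frozenset-like (kind, kind) tuples to
    ``(potential_code, b, wc)``; it is stored symmetrically so lookups with
    either ordering succeed.
    """

    epsilon: float = 1.0
    k_fene: float = 30.0       # FENE spring constant (epsilon)
    fene_rmax: float = 1.5     # FENE divergence radius (sigma)
    k_angle: float = 10.0      # harmonic angle constant (epsilon / rad^2)
    theta0: float = np.pi      # rest angle (radians)
    wc: float = 1.5            # tail-tail attraction width (sigma)
    morse: MorseParams = field(default_factory=MorseParams)
    pair_table: dict = field(default_factory=lambda: _default_pair_table())

    def with_wc(self, wc: float) -> "ForceField":
        table = {
            k: (p, b, wc if p == POT_COS else w)
            for k, (p, b, w) in self.pair_table.items()
        }
        return replace(self, wc=wc, pair_table=table)

    # -- array views consumed by the numba kernels ------------------------
    def pot_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (potential_code, b, wc) as dense 5x5 arrays."""
        n = len(KIND_NAMES)
        pot = np.zeros((n, n), dtype=np.int64)
        b = np.ones((n, n), dtype=np.float64)
        wc = np.zeros((n, n), dtype=np.float64)
        for (ka, kb), (p, bb, ww) in self.pair_table.items():
            pot[ka, kb] = pot[kb, ka] = p
            b[ka, kb] = b[kb, ka] = bb
            wc[ka, kb] = wc[kb, ka] = ww
        return pot, b, wc

    def to_flat_dict(self) -> dict:
        """Flat key-value serialization mirroring the parameter table."""
        out = {
            "epsilon": self.epsilon,
            "k_fene": self.k_fene,
            "fene_rmax": self.fene_rmax,
            "k_angle": self.k_angle,
            "theta0_deg": float(np.degrees(self.theta0)),
            "morse.eps_lr": self.morse.eps_lr,
            "morse.r0": self.morse.r0,
            "morse.alpha": self.morse.alpha,
            "morse.cutoff": self.morse.cutoff,
        }
        for (ka, kb), (p, b, w) in sorted(self.pair_table.items()):
            key = f"pair.{KIND_NAMES[ka]}.{KIND_NAMES[kb]}"
            name = {POT_NONE: "none", POT_WCA: "wca", POT_COS: "cos"}[p]
            out[key] = f"{name} b={b:g} wc={w:g}"
        return out


def _default_pair_table() -> dict:
    """Nonbonded parameters between bead kinds.

    Entries not listed (nanoparticle-ligand, and intra-particle pairs)
    carry no nonbonded interaction.
    """
    t = {}

    def put(a, b, pot, bb, ww=0.0):
        t[(min(a, b), max(a, b))] = (pot, bb, ww)

    put(LIPID_HEAD, LIPID_HEAD, POT_WCA, 0.95)
    put(LIPID_HEAD, LIPID_TAIL, POT_WCA, 0.95)
    put(LIPID_TAIL, LIPID_TAIL, POT_COS, 1.0, 1.5)
    put(NP_SURFACE, LIPID_HEAD, POT_WCA, 1.0)
    put(NP_SURFACE, LIPID_TAIL, POT_WCA, 1.0)
    put(LIGAND, LIPID_HEAD, POT_WCA, 1.0)
    put(LIGAND, LIPID_TAIL, POT_WCA, 1.0)
    put(NP_SURFACE, LIGAND, POT_NONE, 1.0)
    put(RECEPTOR_HEAD, LIGAND, POT_WCA, 1.0)
    put(RECEPTOR_HEAD, LIPID_HEAD, POT_WCA, 0.95)
    put(RECEPTOR_HEAD, LIPID_TAIL, POT_WCA, 0.95)
    put(RECEPTOR_HEAD, NP_SURFACE, POT_WCA, 1.0)
    # receptors are lipid heads: head-head excluded volume between them
    put(RECEPTOR_HEAD, RECEPTOR_HEAD, POT_WCA, 0.95)
    put(LIGAND, LIGAND, POT_NONE, 1.0)
    put(NP_SURFACE, NP_SURFACE, POT_NONE, 1.0)
    return t


# ---------------------------------------------------------------------------
# scalar potentials (reference implementations; the jitted kernels mirror
# these and are cross-checked against them in the test suite)
# ---------------------------------------------------------------------------

def fene_energy(r: float, ff: ForceField) -> float:
    """Finitely extensible nonlinear elastic bond energy.

    U(r) = -1/2 K rmax^2 ln(1 - (r/rmax)^2); diverges at ``fene_rmax``.

    Raises
    ------
    ValueError
        If ``r >= fene_rmax`` (bond overstretched -- the integration
        timestep is too large for the forces present).
    """
    r = float(r)
    if r < 0:
        raise ValueError("bond length must be non-negative")
    if r >= ff.fene_rmax:
        raise ValueError(
            f"FENE bond overstretched: r={r:g} >= rmax={ff.fene_rmax:g}"
        )
    x = (r / ff.fene_rmax) ** 2
    return -0.5 * ff.k_fene * ff.fene_rmax**2 * np.log1p(-x)


def fene_force(r: float, ff: ForceField) -> float:
    """Radial force -dU/dr of the FENE bond (negative = attractive)."""
    r = float(r)
    if r >= ff.fene_rmax:
        raise ValueError(
            f"FENE bond overstretched: r={r:g} >= rmax={ff.fene_rmax:g}"
        )
    x = (r / ff.fene_rmax) ** 2
    return -ff.k_fene * r / (1.0 - x)


def angle_energy(theta_deg: float, ff: ForceField) -> float:
    """Harmonic angle energy K2 (theta - theta0)^2, theta in degrees."""
    th = np.radians(float(theta_deg))
    return ff.k_angle * (th - ff.theta0) ** 2


def wca_energy(r: float, b: float) -> float:
    """Weeks-Chandler-Andersen repulsion, cut and shifted at 2^(1/6) b."""
    r = float(r)
    if r <= 0:
        raise ValueError("WCA potential is singular at r=0")
    if r >= _WCA_CUT * b:
        return 0.0
    s6 = (b / r) ** 6
    return 4.0 * (s6 * s6 - s6) + 1.0


def wca_force(r: float, b: float) -> float:
    """Radial force -dU/dr of the WCA potential."""
    r = float(r)
    if r <= 0:
        raise ValueError("WCA potential is singular at r=0")
    if r >= _WCA_CUT * b:
        return 0.0
    s6 = (b / r) ** 6
    return 24.0 * (2.0 * s6 * s6 - s6) / r


def cos_attraction_energy(r: float, b: float, wc: float) -> float:
    """Cosine-squared attractive tail: -eps plateau inside contact.

    rc = 2^(1/6) b; U = -1 for r < rc, -cos^2(pi (r - rc) / (2 wc)) for
    rc <= r < rc + wc, 0 beyond.
    """
    r = float(r)
    rc = _WCA_CUT * b
    if r < rc:
        return -1.0
    if r >= rc + wc:
        return 0.0
    return -np.cos(np.pi * (r - rc) / (2.0 * wc)) ** 2


def cos_attraction_force(r: float, b: float, wc: float) -> float:
    """Radial force -dU/dr of the cosine attraction."""
    r = float(r)
    rc = _WCA_CUT * b
    if r < rc or r >= rc + wc:
        return 0.0
    u = np.pi * (r - rc) / (2.0 * wc)
    return -np.pi / (2.0 * wc) * np.sin(2.0 * u)


def morse_energy(r: float, morse: MorseParams) -> float:
    """Morse bond energy eps_lr [(1 - e^{-alpha (r - r0)})^2 - 1]."""
    r = float(r)
    if r < 0:
        raise ValueError("distance must be non-negative")
    e = np.exp(-morse.alpha * (r - morse.r0))
    return morse.eps_lr * ((1.0 - e) ** 2 - 1.0)


def morse_force(r: float, morse: MorseParams) -> float:
    """Radial force -dU/dr of the Morse bond."""
    e = np.exp(-morse.alpha * (float(r) - morse.r0))
    return -2.0 * morse.eps_lr * morse.alpha * e * (1.0 - e)


def pair_dispatch(kind_a, kind_b, ff: ForceField) -> dict:
    """Look up the nonbonded interaction spec for a pair of bead kinds.

    Accepts kind codes or kind names; returns
    ``{"potential": "wca"|"cos"|"none", "b": float, "wc": float}``.
    """
    ka = _NAME_TO_KIND.get(kind_a, kind_a)
    kb = _NAME_TO_KIND.get(kind_b, kind_b)
    for k in (ka, kb):
        if k not in KIND_NAMES:
            raise KeyError(f"unknown bead kind: {k!r}")
    p, b, w = ff.pair_table[(min(ka, kb), max(ka, kb))]
    name = {POT_NONE: "none", POT_WCA: "wca", POT_COS: "cos"}[p]
    return {"potential": name, "b": b, "wc": w}
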