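import numpy as np
import pytest

import starwrap as sw


@pytest.fixture(scope="session")
def ff():
    return sw.ForceField()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_bilayer():
    """A 6x6-per-leaflet bilayer with receptors; session-scoped, copy before
    mutating."""
    st = sw.build_bilayer(6, 6)
    return sw.assign_receptors(st, 0.5, seed=3)


@pytest.fixture(scope="session")
def jostled_bilayer(small_bilayer):
    """Same bilayer with small random displacements (non-lattice geometry)."""
    st = small_bilayer.copy()
    st.pos += np.random.default_rng(7).normal(0.0, 0.05, st.pos.shape)
    return st


@pytest.fixture(scope="session")
def kernel_forces():
    """Fixture: function evaluating forces/energy through the
    neighbor-list kernel path."""
    return _kernel_forces


def _kernel_forces(state, ff, skin=0.4, r_form=1.3):
    from starwrap import _kernels as K

    pot, btab, wctab = ff.pot_arrays()
    nk = pot.shape[0]
    wca_cut = 2.0 ** (1.0 / 6.0)
    listcut2 = np.zeros((nk, nk))
    cmax = 0.0
    for a in range(nk):
        for b in range(nk):
            if pot[a, b] == 1:
                c = wca_cut * btab[a, b] + skin
            elif pot[a, b] == 2:
                c = wca_cut * btab[a, b] + wctab[a, b] + skin
            else:
                c = 0.0
            if {a, b} == {2, 4}:
                c = max(c, r_form + skin)
            listcut2[a, b] = c * c
            cmax = max(cmax, c)
    cap = 200 * state.n_beads + 1024
    pi = np.empty(cap, np.int64)
    pj = np.empty(cap, np.int64)
    npairs = K.build_pairs(
        state.pos, state.kind, state.box[0], state.box[1], cmax, listcut2,
        state.exclusions(), state.body_id(), pi, pj,
    )
    assert npairs >= 0
    forces = np.zeros((state.n_beads, 3))
    ep, eb, ea, em, vir, status = K.compute_forces(
        state.pos, state.kind, state.box[0], state.box[1],
        pi, pj, npairs, pot, btab, wctab,
        state.fene_bonds, state.bond_b, ff.k_fene, ff.fene_rmax,
        state.angles, ff.k_angle, ff.theta0,
        state.lr_partner, state.ligand_indices,
        ff.morse.eps_lr, ff.morse.r0, ff.morse.alpha, forces,
    )
    assert status == 0
    return forces, ep + eb + ea + em, vir
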