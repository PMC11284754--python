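"""Wrapping metrics, thickness mapping, displacement, permeability."""

import numpy as np
import pandas as pd
import pytest

import starwrap as sw
from starwrap.forcefield import LIPID_HEAD, LIPID_TAIL, RECEPTOR_HEAD, NP_SURFACE, LIGAND
from starwrap.membrane_builder import SystemState, build_bilayer
from starwrap.observables import (
    WrappingTrace, PermeabilityInputs,
    wrapping_fraction, wrapping_time, membrane_thickness, vesicle_lipids,
    lipid_displacement, relative_wrapping_time, transwell_papp,
)


def state_with_bonds(n_ligands, n_bonded, r=1.0):
    """Ligands above, receptors below, ``n_bonded`` pairs at distance r."""
    n = 2 * n_ligands
    pos = np.zeros((n, 3))
    kind = np.empty(n, dtype=np.int64)
    for k in range(n_ligands):
        pos[k] = (3.0 * k + 5, 10.0, 10.0 + r)
        pos[n_ligands + k] = (3.0 * k + 5, 10.0, 10.0)
        kind[k] = LIGAND
        kind[n_ligands + k] = RECEPTOR_HEAD
    st = SystemState(
        pos=pos, vel=np.zeros((n, 3)), kind=kind,
        fene_bonds=np.empty((0, 2), dtype=np.int64), bond_b=np.empty(0),
        angles=np.empty((0, 3), dtype=np.int64),
        box=np.array([1000.0, 1000.0, 100.0]),
    )
    for k in range(n_bonded):
        st.lr_partner[k] = n_ligands + k
        st.lr_partner[n_ligands + k] = k
    return st


class TestWrappingFraction:
    def test_no_bonds_zero(self, ff):
        st = state_with_bonds(10, 0)
        assert wrapping_fraction(st, ff) == 0.0

    def test_all_bonded_at_r0_is_one(self, ff):
        st = state_with_bonds(280, 280, r=1.0)
        assert wrapping_fraction(st, ff) == pytest.approx(1.0)

    def test_half_bonded_is_half(self, ff):
        st = state_with_bonds(280, 140, r=1.0)
        assert wrapping_fraction(st, ff) == pytest.approx(0.5)

    def test_no_ligands_raises(self, ff):
        st = build_bilayer(3, 3)
        with pytest.raises(ValueError):
            wrapping_fraction(st, ff)


class TestWrappingTime:
    def _trace(self, times, frac):
        return WrappingTrace(
            times=np.asarray(times, dtype=float),
            wrap_fraction=np.asarray(frac, dtype=float),
            bond_count=np.zeros(len(times), dtype=int),
        )

    def test_monotone_crossing(self):
        t = np.arange(0.0, 1000.0, 10.0)
        frac = np.clip(t / 500.0, 0, 1)
        tr = self._trace(t, frac)
        tw = wrapping_time(tr, threshold=0.9, hold=100.0, smooth_window=1)
        assert tw == pytest.approx(450.0)

    def test_flat_trace_absent(self):
        t = np.arange(0.0, 1000.0, 10.0)
        tr = self._trace(t, np.full(len(t), 0.3))
        assert wrapping_time(tr) is None

    def test_single_spike_not_counted(self):
        t = np.arange(0.0, 2000.0, 10.0)
        frac = np.full(len(t), 0.3)
        frac[50] = 0.99  # one-frame spike must not count as completion
        tr = self._trace(t, frac)
        assert wrapping_time(tr, threshold=0.9, hold=100.0, smooth_window=1) is None

    def test_sustained_crossing_with_noise(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 2000.0, 10.0)
        frac = np.clip(np.where(t < 800, t / 800 * 0.95, 0.95)
                       + rng.normal(0, 0.01, len(t)), 0, 1)
        tr = self._trace(t, frac)
        tw = wrapping_time(tr, threshold=0.9, hold=100.0)
        assert tw is not None and 700 <= tw <= 900

    def test_empty_trace_raises(self):
        tr = self._trace([], [])
        with pytest.raises(ValueError):
            wrapping_time(tr)


def two_sheet_state(separation=4.51, nx=12, ny=12, spacing=1.0, jitter=0.0, seed=0):
    """Ideal flat bilayer: heads at +/- separation/2, tails inward."""
    rng = np.random.default_rng(seed)
    n_lip = 2 * nx * ny
    pos = np.zeros((3 * n_lip, 3))
    kind = np.empty(3 * n_lip, dtype=np.int64)
    lip = 0
    for zsign in (1.0, -1.0):
        for i in range(nx):
            for j in range(ny):
                b = 3 * lip
                x, y = (i + 0.5) * spacing, (j + 0.5) * spacing
                z = zsign * separation / 2
                if jitter:
                    z += rng.normal(0, jitter)
                pos[b] = (x, y, z)
                pos[b + 1] = (x, y, z - zsign * 1.0)
                pos[b + 2] = (x, y, z - zsign * 2.0)
                kind[b] = LIPID_HEAD
                kind[b + 1] = LIPID_TAIL
                kind[b + 2] = LIPID_TAIL
                lip += 1
    return SystemState(
        pos=pos, vel=np.zeros_like(pos), kind=kind,
        fene_bonds=np.empty((0, 2), dtype=np.int64), bond_b=np.empty(0),
        angles=np.empty((0, 3), dtype=np.int64),
        box=np.array([nx * spacing, ny * spacing, 50.0]), n_lipids=n_lip,
    )


class TestMembraneThickness:
    def test_constructed_separation_recovered_exactly(self):
        st = two_sheet_state(4.51, spacing=0.5)
        tm = membrane_thickness(st, bin_width=0.5)
        assert tm.mean == pytest.approx(4.51, abs=1e-9)
        assert tm.sd == pytest.approx(0.0, abs=1e-9)
        assert not tm.interpolated_mask.any()

    def test_translation_invariance(self):
        st = two_sheet_state(4.51, jitter=0.3, seed=5)
        t0 = membrane_thickness(st).mean
        st.pos[:, 0] = np.mod(st.pos[:, 0] + 3.217, st.box[0])
        st.pos[:, 1] = np.mod(st.pos[:, 1] + 1.111, st.box[1])
        t1 = membrane_thickness(st).mean
        assert t1 == pytest.approx(t0, abs=0.05)

    def test_empty_bin_interpolated_and_flagged(self):
        st = two_sheet_state(4.0, nx=10, ny=10, spacing=1.0)
        # carve out the lipids covering one interior bin in both leaflets
        keep = np.ones(st.n_lipids, dtype=bool)
        heads = st.pos[st.head_indices]
        hole = (np.abs(heads[:, 0] - 5.5) < 0.5) & (np.abs(heads[:, 1] - 5.5) < 0.5)
        tm = membrane_thickness(st, bin_width=1.0,
                                exclude_lipids=np.flatnonzero(hole))
        assert tm.interpolated_mask.any()
        assert tm.grid[5, 5] == pytest.approx(4.0, abs=1e-6)

    def test_leaflet_assignment_by_tail_vector(self):
        st = two_sheet_state(5.0, spacing=0.5)
        tm = membrane_thickness(st)
        assert tm.mean == pytest.approx(5.0, abs=1e-9)

    def test_grid_covers_box(self):
        st = two_sheet_state(4.0, nx=8, ny=8)
        tm = membrane_thickness(st, bin_width=0.5)
        assert tm.grid.shape == (16, 16)

    def test_empty_leaflet_raises(self):
        st = two_sheet_state(4.0)
        # flip every lipid into the upper leaflet orientation
        half = st.n_lipids // 2
        for l in range(half, st.n_lipids):
            b = 3 * l
            st.pos[b + 1, 2] = st.pos[b, 2] - 1
            st.pos[b + 2, 2] = st.pos[b, 2] - 2
        with pytest.raises(ValueError, match="leaflet"):
            membrane_thickness(st)


class TestVesicleLipids:
    def _with_particle(self, particle_z):
        st = build_bilayer(10, 10)
        from starwrap.np_geometry import generate_sphere_surface
        from starwrap.membrane_builder import assemble_system

        part = generate_sphere_surface(2.0, 1.0)
        out = assemble_system(st, part, standoff=1.0)
        shift = particle_z - out.pos[out.rigid][:, 2].mean()
        out.pos[out.rigid, 2] += shift
        out.com[2] += shift
        return out

    def test_far_particle_empty_set(self, ff):
        st = self._with_particle(30.0)
        assert vesicle_lipids(st, ff) == set()

    def test_contacting_lipids_included(self, ff):
        st = self._with_particle(4.5)
        lips = vesicle_lipids(st, ff)
        assert len(lips) > 0
        # every returned lipid connects to the contact cluster by construction
        assert all(0 <= l < st.n_lipids for l in lips)

    def test_closure_includes_connected_neighbors(self, ff):
        # flat membrane all tail-connected: one contact lipid pulls in the
        # whole sheet
        st = self._with_particle(4.5)
        lips = vesicle_lipids(st, ff)
        assert len(lips) == st.n_lipids


class TestLipidDisplacement:
    def _trace(self, positions, stride=10.0):
        n_frames = positions.shape[0]
        return WrappingTrace(
            times=stride * (1 + np.arange(n_frames)),
            wrap_fraction=np.zeros(n_frames),
            bond_count=np.zeros(n_frames, dtype=int),
            head_positions=positions,
            head_times=stride * (1 + np.arange(n_frames)),
            meta={"box_xy": (100.0, 100.0)},
        )

    def test_static_lipids_zero(self):
        pos = np.zeros((50, 8, 3))
        df = lipid_displacement(self._trace(pos), window=100.0)
        assert np.allclose(df["mean_displacement"], 0.0)

    def test_uniform_drift(self):
        v = np.array([0.03, -0.01, 0.0])
        t = 10.0 * (1 + np.arange(50))
        pos = t[:, None, None] * v[None, None, :] * np.ones((1, 8, 1))
        df = lipid_displacement(self._trace(pos), window=100.0)
        expected = np.linalg.norm(v) * 100.0
        assert np.allclose(df["mean_displacement"], expected)

    def test_matches_bruteforce_on_random_walk(self):
        rng = np.random.default_rng(2)
        pos = np.cumsum(rng.normal(0, 0.2, (60, 10, 3)), axis=0)
        tr = self._trace(pos)
        df = lipid_displacement(tr, window=100.0)
        # independent recomputation
        k = 10  # window / stride
        for row_idx, s in enumerate(range(0, 60 - k, k)):
            d = np.linalg.norm(pos[s + k] - pos[s], axis=1).mean()
            assert df["mean_displacement"].iloc[row_idx] == pytest.approx(d)

    def test_subset_selection(self):
        rng = np.random.default_rng(3)
        pos = np.cumsum(rng.normal(0, 0.2, (30, 10, 3)), axis=0)
        df_all = lipid_displacement(self._trace(pos), window=100.0)
        df_sub = lipid_displacement(self._trace(pos), window=100.0, lipids={0, 1})
        assert not np.allclose(df_all["mean_displacement"], df_sub["mean_displacement"])

    def test_wrapped_coordinates_detected(self):
        pos = np.zeros((20, 4, 3))
        pos[10:, :, 0] = 70.0  # jump > Lx/2 between consecutive frames
        with pytest.raises(ValueError, match="unwrapped|jump"):
            lipid_displacement(self._trace(pos), window=100.0)

    def test_missing_positions_raise(self):
        tr = WrappingTrace(times=np.array([1.0]), wrap_fraction=np.array([0.0]),
                           bond_count=np.array([0]))
        with pytest.raises(ValueError):
            lipid_displacement(tr)


class TestRelativeWrappingTime:
    def test_identical_groups_unity(self):
        assert relative_wrapping_time([100.0, 200.0], [100.0, 200.0]) == 1.0

    def test_sphere_never_completes_absent(self):
        assert relative_wrapping_time([None, None], [100.0]) is None

    def test_synthetic_ratio_two(self):
        assert relative_wrapping_time([200.0] * 5, [100.0] * 5) == pytest.approx(2.0)

    def test_partial_completion_uses_completed_only(self):
        assert relative_wrapping_time([300.0, None], [100.0]) == pytest.approx(3.0)

    def test_star_never_completes_raises(self):
        with pytest.raises(ValueError):
            relative_wrapping_time([100.0], [None, None])


class TestTranswellPapp:
    def test_zero_dc_zero(self):
        assert transwell_papp(PermeabilityInputs(dC_mg_ml=0.0)) == 0.0

    def test_linear_in_dc(self):
        p1 = transwell_papp(PermeabilityInputs(dC_mg_ml=0.01))
        p2 = transwell_papp(PermeabilityInputs(dC_mg_ml=0.02))
        assert p2 == pytest.approx(2 * p1)

    def test_hand_unit_conversion(self):
        # frozen: (750e-3 cm3 / (0.3 cm2 * 0.5 mg/mL)) * (0.01 mg/mL / 14400 s)
        p = transwell_papp(PermeabilityInputs(dC_mg_ml=0.01))
        assert p == pytest.approx(3.4722222222222224e-06, rel=1e-12)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            PermeabilityInputs(A_cm2=0.0)
        with pytest.raises(ValueError):
            PermeabilityInputs(dC_mg_ml=-1.0)
        with pytest.raises(ValueError):
            PermeabilityInputs(dt_h=0.0)


class TestTraceInvariants:
    def test_nonmonotone_times_rejected(self):
        with pytest.raises(ValueError):
            WrappingTrace(times=np.array([1.0, 1.0]),
                          wrap_fraction=np.array([0.0, 0.0]),
                          bond_count=np.array([0, 0]))

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError):
            WrappingTrace(times=np.array([1.0, 2.0]),
                          wrap_fraction=np.array([0.0, 1.5]),
                          bond_count=np.array([0, 0]))

    def test_to_frame(self):
        tr = WrappingTrace(times=np.array([1.0, 2.0]),
                           wrap_fraction=np.array([0.1, 0.2]),
                           bond_count=np.array([1, 2]))
        df = tr.to_frame()
        assert list(df.columns) == ["time", "wrap_fraction", "bond_count"]
        assert len(df) == 2
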