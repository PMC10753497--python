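import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cleftsim as cs
from cleftsim.model import (
    SimulationState,
    cleft_mask,
    init_state,
    migration_response,
    run,
    sphere_mask,
    step,
    step_degradation,
    step_migration,
    step_proliferation,
)

from _scalar_reference import scalar_step


def _uniform_substrate_params(**kw):
    """Homogeneous-ECM parameters for hand-built migration states."""
    base = dict(
        nx=5, ny=5, nz=5, spheroid_radius=0.0, mu=0.6, guidance_g=1.0,
        ecm_crit=0.1, ecm_int=0.1, ecm_3d=0.1, delta=0.0,
    )
    base.update(kw)
    return cs.ModelParams(**base)


class TestInitState:
    def test_cleft_layer_and_bulk_density(self):
        p = cs.ModelParams(
            nx=21, ny=21, nz=11, ecm_int=0.1, ecm_3d=0.5,
            cleft_half_thickness=0, spheroid_radius=30.0,
        )
        st0 = init_state(p)
        mid = (p.nz - 1) // 2
        outside = ~sphere_mask(p)
        assert np.all(st0.ecm[:, :, mid][outside[:, :, mid]] == 0.1)
        off_plane = np.ones(p.nz, bool)
        off_plane[mid] = False
        assert np.all(st0.ecm[:, :, off_plane][outside[:, :, off_plane]] == 0.5)

    def test_cleft_channel_runs_through_spheroid(self):
        # the pre-existing cleft keeps its matrix inside the sphere footprint,
        # while bulk matrix is absent from the spheroid volume
        p = cs.ModelParams(nx=21, ny=21, nz=11, ecm_3d=0.5, spheroid_radius=30.0)
        st0 = init_state(p)
        sph = sphere_mask(p)
        slab = cleft_mask(p)
        assert np.all(st0.ecm[sph & slab] == p.ecm_int)
        assert np.all(st0.ecm[sph & ~slab] == 0.0)
        assert np.all(st0.cells[sph] == 1.0)
        assert np.all(st0.cells[~sph] == 0.0)

    def test_zero_radius_gives_cell_free_matrix(self):
        p = cs.ModelParams(nx=9, ny=9, nz=9, spheroid_radius=0.0)
        st0 = init_state(p)
        assert st0.cells.sum() == 0.0
        assert st0.step == 0

    def test_initial_cell_mass_matches_voxel_census(self):
        # brute-force oracle: count voxel centres within the radius
        p = cs.ModelParams(nx=21, ny=21, nz=21, spheroid_radius=50.0)
        expected = 0
        cx = cy = cz = (21 - 1) / 2 * p.dx
        for i in range(21):
            for j in range(21):
                for k in range(21):
                    d2 = (i * p.dx - cx) ** 2 + (j * p.dx - cy) ** 2 + (k * p.dx - cz) ** 2
                    if d2 <= p.spheroid_radius**2:
                        expected += 1
        assert init_state(p).cells.sum() == expected

    def test_sphere_larger_than_lattice_rejected(self):
        with pytest.raises(ValueError):
            cs.ModelParams(nx=9, ny=9, nz=9, spheroid_radius=50.0)


class TestMigrationResponse:
    def test_two_regime_shape(self):
        p = cs.ModelParams(ecm_crit=0.1, decay_k=10.0)
        assert migration_response(0.0, p) == 0.0
        assert migration_response(p.ecm_crit, p) == 1.0
        assert migration_response(0.05, p) == pytest.approx(0.5)
        assert migration_response(0.3, p) == pytest.approx(math.exp(-2.0))

    def test_maximum_is_unique_and_at_critical_density(self):
        p = cs.ModelParams(ecm_crit=0.1, decay_k=10.0)
        m = np.linspace(0, 1, 201)
        f = migration_response(m, p)
        assert np.argmax(f) == np.argmin(np.abs(m - p.ecm_crit))
        below = m < p.ecm_crit
        above = m > p.ecm_crit
        assert np.all(np.diff(f[below]) > 0)
        assert np.all(np.diff(f[above]) < 0)
        assert np.all(f[m != p.ecm_crit] < 1.0)

    def test_out_of_range_rejected(self):
        p = cs.ModelParams()
        for bad in (-0.1, 1.5):
            with pytest.raises(ValueError):
                migration_response(bad, p)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_bounded_and_nonnegative(self, m):
        p = cs.ModelParams(ecm_crit=0.2, decay_k=15.0)
        f = migration_response(m, p)
        assert 0.0 <= f <= 1.0


class TestProliferation:
    @pytest.mark.parametrize(
        "c0,expected", [(0.25, 0.5), (0.8, 1.0), (0.0, 0.0)]
    )
    def test_doubling_and_cap(self, c0, expected):
        p = _uniform_substrate_params(dt=24.0, t_d=24.0)
        st0 = SimulationState(
            cells=np.full((5, 5, 5), c0), ecm=np.full((5, 5, 5), 0.1)
        )
        out = step_proliferation(st0, p)
        assert np.allclose(out.cells, expected)
        assert np.array_equal(out.ecm, st0.ecm)


class TestDegradation:
    def test_no_cells_no_degradation(self, small_params, random_state):
        st0 = random_state(small_params)
        st0.cells[:] = 0.0
        out = step_degradation(st0, small_params.replace(delta=0.3))
        assert np.array_equal(out.ecm, st0.ecm)

    def test_fully_occupied_interior_rate(self):
        # with c = 1 everywhere the local load is 1, so m drops by delta
        p = _uniform_substrate_params(delta=0.1)
        st0 = SimulationState(cells=np.ones((5, 5, 5)), ecm=np.ones((5, 5, 5)))
        out = step_degradation(st0, p)
        assert out.ecm[2, 2, 2] == pytest.approx(0.9)
        assert np.array_equal(out.cells, st0.cells)

    def test_delta_zero_models_mmp_inhibition(self, small_params, random_state):
        st0 = random_state(small_params)
        out = step_degradation(st0, small_params.replace(delta=0.0))
        assert np.array_equal(out.ecm, st0.ecm)

    def test_ecm_never_increases(self, small_params, random_state):
        p = small_params.replace(delta=0.2)
        state = random_state(p, seed=3)
        for _ in range(5):
            new = step(state, p)
            assert np.all(new.ecm <= state.ecm + 1e-15)
            state = new


class TestMigration:
    def test_no_substrate_no_motion(self):
        p = _uniform_substrate_params()
        cells = np.zeros((5, 5, 5))
        cells[2, 2, 2] = 1.0
        st0 = SimulationState(cells=cells, ecm=np.zeros((5, 5, 5)))
        out = step_migration(st0, p)
        assert np.array_equal(out.cells, st0.cells)

    def test_uniform_substrate_hand_flux(self):
        # single full voxel on homogeneous critical-density substrate:
        # each of the six neighbours gains mu/6, the centre keeps the rest
        p = _uniform_substrate_params(mu=0.6)
        cells = np.zeros((5, 5, 5))
        cells[2, 2, 2] = 1.0
        st0 = SimulationState(cells=cells, ecm=np.full((5, 5, 5), p.ecm_crit))
        out = step_migration(st0, p)
        assert out.cells[2, 2, 2] == pytest.approx(0.4)
        for idx in [(1, 2, 2), (3, 2, 2), (2, 1, 2), (2, 3, 2), (2, 2, 1), (2, 2, 3)]:
            assert out.cells[idx] == pytest.approx(0.1)
        assert out.cells.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_mass_conserved_exactly(self, small_params, random_state, seed):
        st0 = random_state(small_params, seed)
        out = step_migration(st0, small_params)
        assert out.cells.sum() == pytest.approx(st0.cells.sum(), abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_fields_stay_bounded(self, small_params, random_state, seed):
        p = small_params.replace(delta=0.1)
        state = random_state(p, seed)
        # push some voxels to the boundary of the allowed range
        state.cells[state.cells > 0.7] = 1.0
        for _ in range(3):
            state = step(state, p)
            assert np.all(state.cells >= 0.0) and np.all(state.cells <= 1.0)
            assert np.all(state.ecm >= 0.0) and np.all(state.ecm <= 1.0)


class TestStep:
    def test_all_rules_off_is_identity(self):
        p = _uniform_substrate_params(delta=0.0, mu=0.0, t_d=1e15)
        st0 = SimulationState(
            cells=np.random.default_rng(0).random((5, 5, 5)),
            ecm=np.full((5, 5, 5), 0.1),
        )
        out = step(st0, p)
        assert np.allclose(out.cells, st0.cells, atol=1e-12)
        assert np.array_equal(out.ecm, st0.ecm)
        assert out.step == 1

    def test_deterministic(self):
        p = cs.ModelParams(nx=15, ny=15, nz=9, spheroid_radius=30.0, n_steps=5)
        a = run(p).final
        b = run(p).final
        assert np.array_equal(a.cells, b.cells)
        assert np.array_equal(a.ecm, b.ecm)

    def test_reflection_symmetry(self):
        # homogeneous ECM, centred spheroid: the cell field keeps the
        # lattice's mirror symmetries at every step
        p = cs.ModelParams(
            nx=15, ny=15, nz=15, ecm_int=0.5, ecm_3d=0.5, spheroid_radius=30.0,
            delta=0.05,
        )
        state = init_state(p)
        for _ in range(8):
            state = step(state, p)
            for axis in range(3):
                assert np.array_equal(state.cells, np.flip(state.cells, axis))
                assert np.array_equal(state.ecm, np.flip(state.ecm, axis))

    def test_invasion_concentrates_along_cleft(self):
        # the emigrated pattern is a contiguous sheet in the cleft plane with
        # density decaying away from the spheroid
        p = cs.high_density_params(delta=0.01)
        final = run(p).final
        mid = (p.nz - 1) // 2
        outside = ~sphere_mask(p)
        cleft_occ = final.cells[:, :, mid][outside[:, :, mid]].sum()
        off = final.cells[:, :, mid + 3][outside[:, :, mid + 3]].sum()
        assert cleft_occ > 10 * max(off, 1e-9)
        prof = cs.radial_profile(final, p, bin_width=50.0)["mass"].to_numpy()
        assert prof[0] > prof[2] > prof[4]

    def test_matches_scalar_reference(self):
        p = cs.ModelParams(
            nx=3, ny=3, nz=3, spheroid_radius=10.0, delta=0.1, mu=0.6,
            guidance_g=2.0, ecm_int=0.1, ecm_3d=0.6,
        )
        state = init_state(p)
        rng = np.random.default_rng(5)
        state.cells = rng.random((3, 3, 3))
        state.ecm = rng.random((3, 3, 3))
        ref_c, ref_m = scalar_step(state.cells, state.ecm, p)
        out = step(state, p)
        assert np.array_equal(out.cells, ref_c)
        assert np.array_equal(out.ecm, ref_m)


class TestRun:
    def test_zero_steps_returns_initial_state(self, small_params):
        res = run(small_params, n_steps=0)
        st0 = init_state(small_params)
        assert np.array_equal(res.final.cells, st0.cells)
        assert res.final.step == 0

    def test_snapshots_recorded_at_stride(self, small_params):
        res = run(small_params, n_steps=10, record_every=5)
        assert [s.step for s in res.snapshots] == [0, 5, 10]
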