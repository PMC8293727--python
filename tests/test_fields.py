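"""Field solver: deposition conservation, closed forms, BCs, interpolation."""

import numpy as np
import pytest

from plaquesim.fields import (
    ReactionDensity,
    SoluteFields,
    SteadySolver,
    deposit_rates,
    relax_to_steady,
    sample_field,
    step_fields,
)


def _no_reactions(shape):
    return ReactionDensity(np.zeros(shape), np.zeros(shape))


class TestDeposit:
    def test_single_particle_single_voxel(self, small_params):
        p = small_params
        dens = deposit_rates(np.array([[7.0, 7.0, 7.0]]), np.array([5.0]), p)
        total = dens.gl_sink * p.voxel_volume * p.conv_gl
        assert np.count_nonzero(dens.gl_sink) == 1
        assert total.sum() == pytest.approx(5.0, rel=1e-12)

    def test_colocated_particles_add(self, small_params):
        pos = np.array([[7.0, 7.0, 7.0], [7.0, 7.0, 7.0]])
        dens = deposit_rates(pos, np.array([1.0, 2.0]), small_params)
        total = dens.gl_sink * small_params.voxel_volume * small_params.conv_gl
        assert total.sum() == pytest.approx(3.0, rel=1e-12)

    def test_conservation_500_random_particles(self, small_params, rng):
        p = small_params
        n = 500
        pos = rng.random((n, 3)) * [p.L, p.L, p.B]
        r = rng.random(n)
        dens = deposit_rates(pos, r, p)
        assert (dens.gl_sink * p.voxel_volume * p.conv_gl).sum() == pytest.approx(
            r.sum(), rel=1e-10
        )
        # stoichiometry: acid source is the (1-Y) mass fraction, voxelwise
        np.testing.assert_allclose(
            dens.acid_source * p.conv_acid,
            dens.gl_sink * p.conv_gl * (1 - p.Y),
            rtol=1e-12,
        )

    def test_outside_box_rejected(self, small_params):
        with pytest.raises(ValueError):
            deposit_rates(np.array([[0.0, 0.0, 1e4]]), np.array([1.0]), small_params)


class TestStepFields:
    def test_no_reaction_steady_state_is_uniform(self, small_params):
        p = small_params
        f = SoluteFields.resting(p)
        g0 = 3.0
        dt = 0.9 * p.stable_dt_chem()
        for _ in range(4000):
            f = step_fields(f, _no_reactions(p.grid_shape), g0, dt, p.D_Gl, p.D_acid)
        assert np.allclose(f.gl, g0, atol=1e-6 * g0)

    def test_no_sources_acid_stays_zero(self, small_params):
        p = small_params
        f = SoluteFields.resting(p)
        dt = 0.9 * p.stable_dt_chem()
        for _ in range(50):
            f = step_fields(f, _no_reactions(p.grid_shape), 1.0, dt, p.D_Gl, p.D_acid)
        assert np.all(f.acid == 0.0)

    def test_uniform_equilibrium_is_conserved_exactly(self, small_params):
        # uniform field with matching top boundary: zero flux everywhere, so
        # every step must leave the field bit-identical
        p = small_params
        shape = p.grid_shape
        f = SoluteFields(np.full(shape, 2.5), np.zeros(shape), p.grid_spacing)
        dt = 0.9 * p.stable_dt_chem()
        for _ in range(100):
            f = step_fields(f, _no_reactions(shape), 2.5, dt, p.D_Gl, p.D_acid)
        assert np.all(f.gl == 2.5)

    def test_boundary_conditions_after_every_step(self, small_params, rng):
        p = small_params
        shape = p.grid_shape
        f = SoluteFields(rng.random(shape), rng.random(shape), p.grid_spacing)
        dt = 0.9 * p.stable_dt_chem()
        src = ReactionDensity(np.zeros(shape), np.full(shape, 1e-3))
        for _ in range(10):
            f = step_fields(f, src, 1.7, dt, p.D_Gl, p.D_acid)
            assert np.all(f.gl[:, :, -1] == 1.7)
            assert np.all(f.acid[:, :, -1] == 0.0)
            assert np.all(f.gl >= 0) and np.all(f.acid >= 0)

    def test_nonnegativity_with_strong_sink(self, small_params):
        p = small_params
        shape = p.grid_shape
        f = SoluteFields(np.full(shape, 0.01), np.zeros(shape), p.grid_spacing)
        sink = ReactionDensity(np.full(shape, 1e3), np.zeros(shape))
        dt = 0.9 * p.stable_dt_chem()
        for _ in range(5):
            f = step_fields(f, sink, 0.01, dt, p.D_Gl, p.D_acid)
        assert np.all(f.gl >= 0.0)

    def test_unstable_timestep_rejected(self, small_params):
        p = small_params
        f = SoluteFields.resting(p)
        with pytest.raises(ValueError):
            step_fields(f, _no_reactions(p.grid_shape), 1.0,
                        10 * p.stable_dt_chem(), p.D_Gl, p.D_acid)


def _uniform_sink_setup(nz=41):
    """1-D column: uniform sink, Dirichlet top, zero-flux tooth plane."""
    shape = (2, 2, nz)
    spacing = 1.0
    H = (nz - 1) * spacing
    D, g0, sigma = 10.0, 5.0, 0.02
    z = np.arange(nz) * spacing
    exact = g0 - sigma * (H**2 - z**2) / (2 * D)
    return shape, spacing, D, g0, sigma, exact


class TestSteadyClosedForm:
    def test_direct_solver_matches_parabolic_profile(self):
        shape, spacing, D, g0, sigma, exact = _uniform_sink_setup()
        fields = SoluteFields(np.zeros(shape), np.zeros(shape), spacing)
        dens = ReactionDensity(np.full(shape, sigma), np.zeros(shape))
        out = relax_to_steady(fields, dens, g0, D, D)
        err = np.abs(out.gl[0, 0] - exact) / np.abs(exact)
        assert err.max() < 0.01

    def test_transient_long_time_limit_matches_direct_solve(self):
        shape, spacing, D, g0, sigma, exact = _uniform_sink_setup(nz=11)
        dens = ReactionDensity(np.full(shape, sigma), np.zeros(shape))
        f = SoluteFields(np.full(shape, g0), np.zeros(shape), spacing)
        dt = 0.9 * spacing**2 / (6 * D)
        for _ in range(4000):
            f = step_fields(f, dens, g0, dt, D, D)
        steady = relax_to_steady(f, dens, g0, D, D)
        assert np.allclose(f.gl, steady.gl, rtol=1e-4, atol=1e-8)

    def test_already_steady_input_is_fixed_point(self):
        shape, spacing, D, g0, sigma, exact = _uniform_sink_setup()
        dens = ReactionDensity(np.full(shape, sigma), np.zeros(shape))
        start = SoluteFields(np.zeros(shape), np.zeros(shape), spacing)
        once = relax_to_steady(start, dens, g0, D, D)
        twice = relax_to_steady(once, dens, g0, D, D)
        assert np.allclose(once.gl, twice.gl, rtol=1e-12)

    def test_tightening_tolerance_never_hurts(self):
        shape, spacing, D, g0, sigma, exact = _uniform_sink_setup()
        dens = ReactionDensity(np.full(shape, sigma), np.zeros(shape))
        start = SoluteFields(np.zeros(shape), np.zeros(shape), spacing)
        errs = []
        for tol in (1e-4, 1e-8, 1e-12):
            out = relax_to_steady(start, dens, g0, D, D, tol=tol)
            errs.append(np.abs(out.gl[0, 0] - exact).max())
        assert errs[1] <= errs[0] + 1e-12 and errs[2] <= errs[1] + 1e-12

    def test_backward_euler_converges_to_steady(self):
        shape, spacing, D, g0, sigma, exact = _uniform_sink_setup(nz=21)
        solver = SteadySolver(shape, spacing)
        src = np.full(shape, sigma)
        c = np.zeros(shape)
        for _ in range(300):
            c = solver.step_implicit(c, src, D, 5.0, 0.0)
        steady = solver.solve_steady(src, D, 0.0)
        assert np.allclose(c, steady, rtol=1e-6, atol=1e-9)


class TestSampleField:
    def test_nodal_values_exact(self, small_params, rng):
        p = small_params
        shape = p.grid_shape
        f = SoluteFields(rng.random(shape), rng.random(shape), p.grid_spacing)
        i, j, k = 1, 2, 3
        pos = np.array([[i * p.grid_spacing, j * p.grid_spacing, k * p.grid_spacing]])
        gl, acid = sample_field(f, pos)
        assert gl[0] == pytest.approx(f.gl[i, j, k], rel=1e-14)
        assert acid[0] == pytest.approx(f.acid[i, j, k], rel=1e-14)

    def test_uniform_field_everywhere(self, small_params, rng):
        p = small_params
        f = SoluteFields(
            np.full(p.grid_shape, 1.3), np.full(p.grid_shape, 0.4), p.grid_spacing
        )
        pos = rng.random((50, 3)) * [p.L, p.L, p.H]
        gl, acid = sample_field(f, pos)
        assert np.allclose(gl, 1.3) and np.allclose(acid, 0.4)

    def test_linear_in_z_reproduced_exactly(self, small_params, rng):
        p = small_params
        nz = p.grid_shape[2]
        z_nodes = np.arange(nz) * p.grid_spacing
        prof = 2.0 + 0.5 * z_nodes
        f = SoluteFields(
            np.broadcast_to(prof, p.grid_shape).copy(),
            np.zeros(p.grid_shape),
            p.grid_spacing,
        )
        pos = rng.random((100, 3)) * [p.L, p.L, p.H]
        gl, _ = sample_field(f, pos)
        assert np.allclose(gl, 2.0 + 0.5 * pos[:, 2], rtol=1e-12)

    def test_outside_box_rejected(self, small_params):
        f = SoluteFields.resting(small_params)
        with pytest.raises(ValueError):
            sample_field(f, np.array([[0.0, 0.0, -1.0]]))


class TestFieldExports:
    def test_flat_csv_round_trip(self, small_params, rng, tmp_path):
        from plaquesim.fields import fields_to_csv

        f = SoluteFields(
            rng.random(small_params.grid_shape),
            rng.random(small_params.grid_shape),
            small_params.grid_spacing,
        )
        path = tmp_path / "fields.csv"
        fields_to_csv(f, path)
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        assert data.shape == (f.gl.size, 5)
        i, j, k = data[:, 0].astype(int), data[:, 1].astype(int), data[:, 2].astype(int)
        np.testing.assert_allclose(data[:, 3], f.gl[i, j, k], rtol=1e-9)
        np.testing.assert_allclose(data[:, 4], f.acid[i, j, k], rtol=1e-9)

    def test_z_profile_lateral_average(self, small_params):
        from plaquesim.fields import z_profile

        shape = small_params.grid_shape
        nz = shape[2]
        prof = np.linspace(1.0, 2.0, nz)
        f = SoluteFields(
            np.broadcast_to(prof, shape).copy(), np.zeros(shape),
            small_params.grid_spacing,
        )
        z, gl_mean, acid_mean = z_profile(f)
        np.testing.assert_allclose(gl_mean, prof, rtol=1e-12)
        assert z[1] - z[0] == small_params.grid_spacing
        assert np.all(acid_mean == 0)
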