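"""Staggered-grid solver: projection, viscous solve, IBM, forcing, valve."""

import numpy as np
import pytest
import trimesh

from atriflow import solver
from atriflow._kernels import interp3, spread3
from atriflow.solver import (FluidState, Grid, ImmersedSurfaceMarkers,
                             adaptive_dt, advance_substep, divergence,
                             ibm_wall_force, make_buffer, make_valve,
                             mitral_outlet, pressure_projection,
                             pv_inflow_force, valve_flux)


@pytest.fixture()
def grid():
    return Grid(n=24, length=4.8)


def _random_fields(grid, rng):
    u = rng.standard_normal((grid.n + 1, grid.n, grid.n))
    v = rng.standard_normal((grid.n, grid.n + 1, grid.n))
    w = rng.standard_normal((grid.n, grid.n, grid.n + 1))
    u[0] = u[-1] = 0
    v[:, 0] = v[:, -1] = 0
    w[:, :, 0] = w[:, :, -1] = 0
    return u, v, w


class TestProjection:
    def test_random_field_becomes_divergence_free(self, grid, rng):
        u, v, w = _random_fields(grid, rng)
        u2, v2, w2, _ = pressure_projection(grid, u, v, w, 1e-3)
        div = divergence(grid, u2, v2, w2)
        scale = max(np.abs(u).max(), np.abs(v).max()) / grid.dx
        assert np.abs(div).max() <= 1e-8 * scale

    def test_divergence_free_input_unchanged(self, grid, rng):
        u, v, w = _random_fields(grid, rng)
        u, v, w, _ = pressure_projection(grid, u, v, w, 1e-3)
        u2, v2, w2, phi = pressure_projection(grid, u, v, w, 1e-3)
        assert np.allclose(u2, u, atol=1e-10)
        assert np.abs(phi).max() < 1e-7 * np.abs(u).max() / grid.dx

    def test_pure_gradient_field_is_annihilated(self, grid, rng):
        phi = rng.standard_normal((grid.n,) * 3)
        gu = grid.zeros("u")
        gv = grid.zeros("v")
        gw = grid.zeros("w")
        gu[1:-1] = (phi[1:] - phi[:-1]) / grid.dx
        gv[:, 1:-1] = (phi[:, 1:] - phi[:, :-1]) / grid.dx
        gw[:, :, 1:-1] = (phi[:, :, 1:] - phi[:, :, :-1]) / grid.dx
        u2, v2, w2, _ = pressure_projection(grid, gu, gv, gw, 1.0)
        assert max(np.abs(u2).max(), np.abs(v2).max(),
                   np.abs(w2).max()) < 1e-11 * max(np.abs(gu).max(), 1.0)


class TestViscousSolve:
    def test_series_path_matches_direct_transform_solve(self, grid, rng):
        rhs = rng.standard_normal((grid.n + 1, grid.n, grid.n))
        rhs[0] = rhs[-1] = 0
        coef_small = 1e-7          # series regime
        direct = np.zeros_like(rhs)
        direct[1:-1] = solver._helmholtz_axis0(rhs[1:-1], coef_small,
                                               grid.n, grid.dx)
        series = solver._helmholtz_solve(grid, "u", rhs, coef_small)
        assert np.abs(series - direct).max() <= 1e-10 * np.abs(direct).max()

    def test_direct_solve_satisfies_operator(self, grid, rng):
        rhs = rng.standard_normal((grid.n + 1, grid.n, grid.n))
        rhs[0] = rhs[-1] = 0
        coef = 0.05 * grid.dx**2   # large enough to force the transform path
        sol = solver._helmholtz_solve(grid, "u", rhs, coef)
        resid = sol - coef * solver._laplacian_axis0(sol, grid.dx) - rhs
        assert np.abs(resid[1:-1]).max() < 1e-11 * np.abs(rhs).max()


class TestAdvanceSubstep:
    def test_quiescent_state_stays_quiescent(self, grid):
        st = FluidState.quiescent(grid)
        st.dt = 1e-3
        adv = None
        for stage in range(3):
            st, adv = advance_substep(st, stage, adv_prev=adv)
        assert st.max_speed() == 0.0
        assert np.abs(st.p).max() == 0.0

    def test_free_slip_box_faces_zero_normal_velocity(self, grid, rng):
        st = FluidState.quiescent(grid)
        st.u[1:-1] = rng.standard_normal(st.u[1:-1].shape)
        st.v[:, 1:-1] = rng.standard_normal(st.v[:, 1:-1].shape)
        st.dt = 1e-4
        adv = None
        for stage in range(3):
            st, adv = advance_substep(st, stage, adv_prev=adv)
        assert np.abs(st.u[0]).max() == 0.0 and np.abs(st.u[-1]).max() == 0.0
        assert np.abs(st.v[:, 0]).max() == 0.0
        assert np.abs(st.w[:, :, 0]).max() == 0.0


def _taylor_green(n, nu=0.01, m=2):
    g = Grid(n=n, length=1.0)
    st = FluidState.quiescent(g, nu=nu)
    k = np.pi * m
    x0 = g.origin
    xu, yu, _ = np.meshgrid(*g.coords("u"), indexing="ij")
    xv, yv, _ = np.meshgrid(*g.coords("v"), indexing="ij")
    st.u = np.sin(k * (xu - x0[0])) * np.cos(k * (yu - x0[1]))
    st.v = -np.cos(k * (xv - x0[0])) * np.sin(k * (yv - x0[1]))
    st.enforce_boundaries()
    return g, st, k, (xu, yu)


def _run_tg(st, tend, cfl=0.3, dt_max=5e-3):
    adv = None
    while st.t < tend - 1e-12:
        st.dt = min(adaptive_dt(st, cfl, dt_max), tend - st.t)
        for stage in range(3):
            st, adv = advance_substep(st, stage, adv_prev=adv)
    return st


class TestTaylorGreen:
    def test_energy_decay_matches_viscous_rate(self):
        """Kinetic energy of the vortex array decays as exp(-4 nu k^2 t)."""
        nu, tend = 0.01, 0.25
        g, st, k, _ = _taylor_green(48, nu=nu)
        e0 = np.sum(st.u**2) + np.sum(st.v**2)
        st = _run_tg(st, tend)
        e1 = np.sum(st.u**2) + np.sum(st.v**2)
        assert e1 / e0 == pytest.approx(np.exp(-4 * nu * k**2 * tend),
                                        rel=5e-3)

    def test_spatial_convergence_second_order(self):
        nu, tend = 0.01, 0.1
        errs = []
        for n in (16, 32):
            g, st, k, (xu, yu) = _taylor_green(n, nu=nu)
            st = _run_tg(st, tend, dt_max=1e-3)
            ua = (np.sin(k * (xu - g.origin[0]))
                  * np.cos(k * (yu - g.origin[1]))
                  * np.exp(-2 * nu * k**2 * tend))
            errs.append(np.abs(st.u - ua).max())
        order = np.log2(errs[0] / errs[1])
        assert order >= 1.9


class TestIBM:
    def _sphere_markers(self, radius=1.2, subdiv=3, vel=0.0):
        sph = trimesh.creation.icosphere(subdivisions=subdiv, radius=radius)
        m = len(sph.faces)
        return ImmersedSurfaceMarkers(
            positions=np.asarray(sph.triangles_center),
            velocities=np.full((m, 3), vel),
            areas=np.asarray(sph.area_faces))

    def test_zero_force_when_fluid_matches_wall(self, grid):
        mk = self._sphere_markers(vel=3.0)
        u = np.full((grid.n + 1, grid.n, grid.n), 3.0)
        v = np.full((grid.n, grid.n + 1, grid.n), 3.0)
        w = np.full((grid.n, grid.n, grid.n + 1), 3.0)
        u2, v2, w2, forces = ibm_wall_force(grid, u, v, w, mk, 1e-3)
        assert np.abs(forces).max() < 1e-10
        assert np.allclose(u2, u)

    def test_spread_conserves_total_force(self, grid, rng):
        """Kernel partition of unity: grid total equals marker total."""
        pos = rng.uniform(-1.2, 1.2, (400, 3))
        vals = rng.standard_normal(400)
        fld = grid.zeros("u")
        spread3(fld, pos, vals, grid.origin,
                np.array([0.0, 0.5, 0.5]), grid.dx)
        assert fld.sum() == pytest.approx(vals.sum(), abs=1e-10 * len(vals))

    def test_static_surface_suppresses_marker_velocity(self, grid):
        """Direct forcing pins the interpolated velocity at the markers of a
        static surface to a few percent of the outer flow after one step."""
        mk = self._sphere_markers()
        st = FluidState.quiescent(grid)
        st.u[1:-1] = 10.0
        st.dt = 1e-3
        adv = None
        for stage in range(3):
            st, adv = advance_substep(st, stage, markers=mk, adv_prev=adv)
        iv = interp3(st.u, mk.positions, grid.origin,
                     np.array([0.0, 0.5, 0.5]), grid.dx)
        assert np.abs(iv).max() < 0.05 * 10.0

    def test_marker_outside_margin_raises(self, grid):
        mk = ImmersedSurfaceMarkers(positions=np.array([[2.39, 0.0, 0.0]]),
                                    velocities=np.zeros((1, 3)),
                                    areas=np.ones(1))
        u, v, w = grid.zeros("u"), grid.zeros("v"), grid.zeros("w")
        with pytest.raises(ValueError, match="margin"):
            ibm_wall_force(grid, u, v, w, mk, 1e-3)


class TestPVBuffer:
    def test_zero_force_at_target(self, grid):
        buf = make_buffer(grid, np.array([0.0, 0.0, 0.0]),
                          np.array([1.0, 0.0, 0.0]), 0.8, 3,
                          flow=lambda t: np.pi * 0.64 * 5.0)
        u = np.full((grid.n + 1, grid.n, grid.n), 5.0)
        v, w = grid.zeros("v"), grid.zeros("w")
        u2, _, _ = pv_inflow_force(grid, u, v, w, [buf], 0.0, 1e-3, 1e-4)
        assert np.allclose(u2, u, atol=1e-12)

    def test_relaxation_follows_exponential(self, grid):
        """A buffer cell obeys dv/dt = (v_t - v)/tau: after 5 tau the
        deviation from target is below 1% of the initial deviation."""
        vt = 10.0
        buf = make_buffer(grid, np.zeros(3), np.array([1.0, 0, 0]), 0.8, 3,
                          flow=lambda t: np.pi * 0.64 * vt)
        tau = 10 * 1e-4
        u, v, w = grid.zeros("u"), grid.zeros("v"), grid.zeros("w")
        nsteps = int(round(5 * tau / 1e-4))
        for _ in range(nsteps):
            u, v, w = pv_inflow_force(grid, u, v, w, [buf], 0.0, tau, 1e-4)
        inside = u[buf.masks["u"]]
        assert np.abs(inside - vt).max() < 0.01 * vt
        # exponential envelope: the implicit update stays within the exact
        # solution's ballpark (1+dt/tau)^-n vs exp(-n dt/tau)
        exact = vt * (1 - np.exp(-nsteps * 1e-4 / tau))
        assert inside.mean() == pytest.approx(exact, rel=0.05)

    def test_nonpositive_tau_rejected(self, grid):
        buf = make_buffer(grid, np.zeros(3), np.array([1.0, 0, 0]), 0.8, 3)
        u, v, w = grid.zeros("u"), grid.zeros("v"), grid.zeros("w")
        with pytest.raises(ValueError):
            pv_inflow_force(grid, u, v, w, [buf], 0.0, 0.0, 1e-4)


class TestMitralValve:
    def _valve(self, grid, q):
        return make_valve(grid, np.array([0.0, 0.0, -1.2]),
                          np.array([0.0, 0.0, -1.0]), 0.9, q)

    def test_closed_valve_zero_flux_machine_precision(self, grid, rng):
        patch = self._valve(grid, lambda t: 0.0)
        u, v, w = _random_fields(grid, rng)
        u, v, w = mitral_outlet(grid, u, v, w, patch, 0.0, 1e-3, 1e-4, "post")
        assert valve_flux(patch, u, v, w, grid.dx) == 0.0

    def test_open_valve_reaches_prescribed_flux(self, grid):
        """A valve plane fed by an upstream inflow (as in the chamber, where
        mass conservation supplies the flux) passes Q_MV within 1% when the
        uniform-patch outflow condition is active."""
        q = 100.0
        patch = self._valve(grid, lambda t: q)
        patch.rescale_open = True
        buf = make_buffer(grid, np.array([0.0, 0.0, 0.3]),
                          np.array([0.0, 0.0, -1.0]), 0.9, 3,
                          flow=lambda t: q)
        st = FluidState.quiescent(grid)
        st.dt = 5e-4
        adv = None
        for _ in range(60):
            for stage in range(3):
                st, adv = advance_substep(st, stage, buffers=[buf],
                                          valve=patch, tau=10 * st.dt,
                                          adv_prev=adv)
        assert valve_flux(patch, st.u, st.v, st.w, grid.dx) == pytest.approx(
            q, rel=0.01)

    def test_instant_closure_kills_flux_on_first_closed_step(self, grid):
        opening = {"open": True}
        patch = self._valve(grid, lambda t: 80.0 if opening["open"] else 0.0)
        st = FluidState.quiescent(grid)
        st.dt = 5e-4
        adv = None
        for _ in range(20):
            for stage in range(3):
                st, adv = advance_substep(st, stage, valve=patch,
                                          tau=10 * st.dt, adv_prev=adv)
        assert abs(valve_flux(patch, st.u, st.v, st.w, grid.dx)) > 1.0
        opening["open"] = False
        for stage in range(3):
            st, adv = advance_substep(st, stage, valve=patch,
                                      tau=10 * st.dt, adv_prev=adv)
        assert valve_flux(patch, st.u, st.v, st.w, grid.dx) == 0.0


class TestAdaptiveDt:
    def test_zero_velocity_returns_cap(self, grid):
        st = FluidState.quiescent(grid)
        assert adaptive_dt(st, 0.3, 2e-3) == 2e-3

    def test_cfl_bound_arithmetic(self):
        g = Grid(n=10, length=1.0)
        st = FluidState.quiescent(g)
        st.u[1:-1] = 30.0
        dt = adaptive_dt(st, 0.3, 1.0)
        assert dt == pytest.approx(0.3 * g.dx / 30.0)
        assert 30.0 * dt / g.dx <= 0.3 + 1e-12

    def test_doubling_speed_halves_dt(self, grid, rng):
        st = FluidState.quiescent(grid)
        st.u[1:-1] = rng.standard_normal(st.u[1:-1].shape)
        d1 = adaptive_dt(st, 0.3, 10.0)
        st.u *= 2.0
        assert adaptive_dt(st, 0.3, 10.0) == pytest.approx(d1 / 2)

    def test_nonfinite_velocity_raises(self, grid):
        st = FluidState.quiescent(grid)
        st.u[3, 3, 3] = np.nan
        with pytest.raises(FloatingPointError):
            adaptive_dt(st)


class TestKernelConsistency:
    """Numba stencils agree with the plain-numpy reference operators."""

    def test_advection_and_laplacian_match_reference(self, grid, rng):
        u, v, w = _random_fields(grid, rng)
        (adv, lap) = solver.advection_laplacian_terms(grid, u, v, w)
        assert np.allclose(adv[0], solver._advect_axis0(u, v, w, grid.dx),
                           atol=1e-12)
        assert np.allclose(lap[0], solver._laplacian_axis0(u, grid.dx),
                           atol=1e-12)
        fwd, inv = solver._PERM["w"]
        ref = solver._advect_axis0(w.transpose(fwd), u.transpose(fwd),
                                   v.transpose(fwd), grid.dx).transpose(inv)
        assert np.allclose(adv[2], ref, atol=1e-12)
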