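"""End-to-end heartbeat simulations of a synthetic atrium case.

Wires a :class:`~atriflow.synthetic.SyntheticCase` into the flow solver:
immersed-boundary markers from the kinematic wall model, relaxation buffers
upstream of the four PV inlet planes, the instantly opening/closing mitral
plane, and the residence-time scalar sharing the solver's Runge-Kutta stages.
Runs are initialized from rest and advanced for a prescribed number of
heartbeats (optionally a coarse stage, a conservative interpolation restart,
and a fine stage); appendage statistics are accumulated at snapshot phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from . import geometry, metrics, residence, solver
from .solver import (CFL_DEFAULT, NU_BLOOD, RK3_ALPHA, RK3_GAMMA, RK3_ZETA,
                     FluidState, Grid, ImmersedSurfaceMarkers)


@dataclass
class SolverConfig:
    """Grid, protocol and tolerance settings for a case run."""

    n: int = 48                     # cells per side
    box: float = solver.BOX_SIDE    # cm
    nu: float = NU_BLOOD
    cfl: float = CFL_DEFAULT
    dt_max: float = 5e-4            # s
    dt: float | None = None         # constant-time-step mode when set
    tau_steps: float = 10.0         # forcing time constant, units of dt
    buffer_cells: int = 3           # inlet buffer thickness
    beats: int = 4
    coarse: tuple | None = None     # (n_coarse, beats_coarse) restart protocol
    with_residence: bool = True
    snapshots_per_beat: int = 25
    wall_band_firstorder: bool = True
    # bounded WENO undershoot floor for the residence scalar: values below
    # -negative_tol * max(1, t) abort the run; smaller negatives are floored
    negative_tol: float = 5e-3
    seed: int = 0

    def tau(self, dt: float) -> float:
        return self.tau_steps * dt


@dataclass
class Snapshot:
    t: float
    beat: int
    laa_tr: np.ndarray          # masked LAA voxel values of T_R (s)
    laa_k: np.ndarray           # masked LAA voxel values of K (cm^2/s^2)
    body_tr_mean: float
    body_k_mean: float
    mv_flux: float


@dataclass
class RunResult:
    """History of one heartbeat run with accumulated appendage samples."""

    config: SolverConfig
    state: FluidState
    residence_field: residence.ResidenceField | None
    snapshots: list
    diagnostics: pd.DataFrame
    beat_means: np.ndarray          # per-beat mean of volume-averaged LAA T_R
    converged: bool
    converged_beat: int | None

    def laa_metrics(self, last_beats: int = 2, seed: int = 0,
                    require_convergence: bool = False) -> metrics.HemoMetrics:
        """Pool the last ``last_beats`` heartbeats into appendage statistics."""
        beats = np.array([s.beat for s in self.snapshots])
        keep = beats > beats.max() - last_beats
        snaps = [s for s, k in zip(self.snapshots, keep) if k]
        return metrics.laa_statistics(
            [s.laa_tr for s in snaps], [s.laa_k for s in snaps],
            np.array([s.beat for s in snaps]),
            converged=self.converged,
            require_convergence=require_convergence, seed=seed,
            body_tr=np.array([s.body_tr_mean for s in snaps]),
            body_k=np.array([s.body_k_mean for s in snaps]),
            snapshot_times=np.array([s.t for s in snaps]))


class Simulation:
    """Stateful driver advancing flow + residence time for one case."""

    def __init__(self, case, config: SolverConfig,
                 state: FluidState | None = None,
                 residence_values: np.ndarray | None = None, t0: float = 0.0):
        self.case = case
        self.config = config
        self.grid = Grid(n=config.n, length=config.box,
                         center=case.shape.center)
        self.state = state if state is not None else FluidState.quiescent(
            self.grid, nu=config.nu)
        self.state.t = t0
        wf = case.waveforms
        self.buffers = [
            solver.make_buffer(self.grid, inlet.center, inlet.normal,
                               inlet.radius, config.buffer_cells,
                               flow=(lambda t, i=i: wf.q_i(t)))
            for i, inlet in enumerate(wf.inlets)
        ]
        mv = case.mitral
        self.valve = solver.make_valve(self.grid, mv.center, mv.normal,
                                       mv.radius, wf.q_mv)
        self.T = (residence_values if residence_values is not None
                  else self.grid.zeros("c")) if config.with_residence else None
        self._adv_prev = None
        self._rhs_prev = None
        self._cells = self.grid.cell_centers()
        self.fo_mask = None
        if config.wall_band_firstorder:
            self.fo_mask = self._surface_band()
        self._reset_masks = self._pv_reset_masks()
        self._mitral_faces = np.flatnonzero(case.face_tags == geometry.MITRAL)
        pv_tags = [geometry.PV_BASE + i for i in range(len(wf.inlets))]
        self._wall_faces = np.flatnonzero(
            ~np.isin(case.face_tags, pv_tags + [geometry.MITRAL]))

    def _pv_reset_masks(self) -> list:
        """Residence-time reset regions: the momentum buffers plus the PV
        tube lumina outside the chamber body.

        Blood in the veins is fresh by definition; resetting it over the whole
        stub (rather than only the thin buffer it crosses in a few relaxation
        times) makes the inlet age condition robust to grid spacing.
        """
        shape = self.case.shape
        b_max = float(np.max(self.case.body_scales))
        masks = []
        n = self.grid.n
        for tube, buf in zip(shape.pv_tubes, self.buffers):
            rel = self._cells - shape.center
            s = rel @ tube.axis
            rad = np.linalg.norm(rel - s[:, None] * tube.axis, axis=1)
            r_body = float(shape._body_radius(tube.axis[None, :], b_max)[0])
            lumen = ((s > r_body) & (s <= tube.length)
                     & (rad <= tube.radius)).reshape((n,) * 3)
            masks.append(lumen | buf.cell_mask)
        return masks

    def _surface_band(self, width_cells: float = 2.0) -> np.ndarray:
        """Cells within ~2 dx of the (time-averaged) chamber surface, where
        scalar fluxes degrade to first-order upwinding."""
        shape = self.case.shape
        b = float(np.mean(self.case.body_scales))
        g = float(np.mean(self.case.laa_scales))
        p = self._cells - shape.center
        d = np.linalg.norm(p, axis=1)
        dirs = p / np.maximum(d, 1e-12)[:, None]
        r, _, _ = shape.radius_field(dirs, body_scale=b, laa_scale=g)
        band = np.abs(d - r) < width_cells * self.grid.dx
        return band.reshape((self.grid.n,) * 3)

    # -- markers ------------------------------------------------------------

    def markers_at(self, t: float) -> ImmersedSurfaceMarkers:
        model = self.case.model
        pos = model.centroid_positions(t)
        vel = model.centroid_velocities(t)
        areas, _ = model.face_areas_normals(t)
        faces = self._wall_faces
        if not self.valve.is_open(t):
            faces = np.concatenate([faces, self._mitral_faces])
        return ImmersedSurfaceMarkers(positions=pos[faces],
                                      velocities=vel[faces],
                                      areas=areas[faces])

    # -- stepping -----------------------------------------------------------

    def step(self) -> None:
        cfg = self.config
        st = self.state
        st.dt = cfg.dt if cfg.dt is not None else solver.adaptive_dt(
            st, cfg.cfl, cfg.dt_max)
        tau = cfg.tau(st.dt)
        for stage in range(3):
            t_stage = st.t + RK3_ALPHA[stage] * st.dt
            mk = self.markers_at(t_stage)
            st, self._adv_prev = solver.advance_substep(
                st, stage, markers=mk, buffers=self.buffers,
                valve=self.valve, tau=tau, adv_prev=self._adv_prev)
            if self.T is not None:
                self.T, self._rhs_prev = residence.advance_residence_stage(
                    self.T, st.u, st.v, st.w, self.grid.dx, st.dt, stage,
                    self._rhs_prev, RK3_GAMMA, RK3_ZETA, RK3_ALPHA,
                    reset_masks=self._reset_masks, tau=tau,
                    fo_mask=self.fo_mask)
        if self.T is not None:
            lo = float(self.T.min())
            if lo < -self.config.negative_tol * max(1.0, st.t):
                raise residence.MonotonicityError(
                    f"residence time fell to {lo:.3e} at t={st.t:.3f}")
            np.maximum(self.T, 0.0, out=self.T)
        self.state = st

    # -- observation ----------------------------------------------------------

    def snapshot(self) -> Snapshot:
        st = self.state
        t = st.t
        laa = self.case.laa_mask(self._cells, t).reshape((self.grid.n,) * 3)
        chamber = self.case.chamber_mask(self._cells, t).reshape(laa.shape)
        # sample the resolved lumen: cells inside the one-cell band spanned by
        # the regularized immersed interface move with the wall, not the
        # blood, and would bias the pooled statistics at coarse spacing
        from scipy.ndimage import binary_erosion
        laa_core = binary_erosion(laa)
        if laa_core.sum() >= 8:
            laa = laa_core
        chamber_core = binary_erosion(chamber)
        if chamber_core.sum() >= 64:
            chamber = chamber_core
        body = chamber & ~laa
        k = metrics.kinetic_energy(st.u, st.v, st.w)
        tr = self.T if self.T is not None else np.zeros_like(k)
        beat = int(t / self.case.params.period) + 1
        return Snapshot(
            t=t, beat=beat,
            laa_tr=tr[laa].copy(), laa_k=k[laa].copy(),
            body_tr_mean=float(tr[body].mean()) if body.any() else np.nan,
            body_k_mean=float(k[body].mean()) if body.any() else np.nan,
            mv_flux=solver.valve_flux(self.valve, st.u, st.v, st.w,
                                      self.grid.dx))


def run_heartbeats(case, config: SolverConfig, observer=None,
                   progress: bool = False) -> RunResult:
    """Initialize from rest and run ``config.beats`` heartbeats.

    With ``config.coarse = (n_coarse, beats_coarse)`` the run starts on the
    coarse grid and restarts on the fine grid by conservative interpolation
    followed by a projection.  Snapshots are taken at uniform phases of each
    beat; ``observer(sim, snapshot)`` is called on each.  Returns a
    :class:`RunResult` with per-beat appendage washout means and the
    quasi-periodicity convergence flag.
    """
    period = case.params.period
    t0 = 0.0
    state = None
    tvals = None
    if config.coarse is not None:
        n_c, beats_c = config.coarse
        cfg_c = SolverConfig(**{**vars(config), "n": n_c, "coarse": None,
                                "beats": beats_c})
        res_c = run_heartbeats(case, cfg_c, observer=None, progress=progress)
        fine_grid = Grid(n=config.n, length=config.box,
                         center=case.shape.center)
        state = refine_state(res_c.state, fine_grid)
        tvals = (refine_scalar(res_c.residence_field.values, res_c.state.grid,
                               fine_grid)
                 if res_c.residence_field is not None else None)
        t0 = res_c.state.t

    sim = Simulation(case, config, state=state, residence_values=tvals, t0=t0)
    t_end = t0 + config.beats * period
    snap_phases = (np.arange(config.snapshots_per_beat) + 1.0) \
        / config.snapshots_per_beat * period
    snapshots = []
    diag_rows = []
    next_beat_start = t0
    pending = list(next_beat_start + snap_phases)
    while sim.state.t < t_end - 1e-12:
        sim.step()
        st = sim.state
        while pending and st.t >= pending[0] - 1e-12:
            pending.pop(0)
            snap = sim.snapshot()
            snapshots.append(snap)
            if observer is not None:
                observer(sim, snap)
            if not pending:
                next_beat_start += period
                if next_beat_start < t_end - 1e-12:
                    pending = list(next_beat_start + snap_phases)
        diag_rows.append({
            "t_s": st.t, "dt_s": st.dt,
            "cfl": st.max_speed() * st.dt / sim.grid.dx,
            "max_div": float(np.abs(solver.divergence(
                sim.grid, st.u, st.v, st.w)).max()) if len(diag_rows) % 50 == 0
            else np.nan,
            "ke_total": float(np.sum(metrics.kinetic_energy(st.u, st.v, st.w))
                              * sim.grid.dx**3),
        })
        if progress and len(diag_rows) % 200 == 0:
            print(f"  t={st.t:.3f}s dt={st.dt:.2e} "
                  f"KE={diag_rows[-1]['ke_total']:.1f}", flush=True)

    beats = np.array([s.beat for s in snapshots])
    series = np.array([s.laa_tr.mean() if len(s.laa_tr) else np.nan
                       for s in snapshots])
    beat_means = np.array([series[beats == b].mean()
                           for b in np.unique(beats)])
    if len(beat_means) >= 3:
        conv, conv_beat = residence.detect_convergence(beat_means)
    else:
        conv, conv_beat = False, None
    return RunResult(config=config, state=sim.state,
                     residence_field=(residence.ResidenceField(sim.T, sim.state.t)
                                      if sim.T is not None else None),
                     snapshots=snapshots,
                     diagnostics=pd.DataFrame(diag_rows),
                     beat_means=beat_means, converged=conv,
                     converged_beat=conv_beat)


# ---------------------------------------------------------------------------
# Restart interpolation
# ---------------------------------------------------------------------------

def _interp_component(field: np.ndarray, grid: Grid, fine: Grid,
                      kind: str) -> np.ndarray:
    coords = grid.coords(kind)
    interp = RegularGridInterpolator(coords, field, method="linear",
                                     bounds_error=False, fill_value=None)
    fx = fine.coords(kind)
    xx, yy, zz = np.meshgrid(*fx, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    return interp(pts).reshape(xx.shape)


def refine_scalar(values: np.ndarray, grid: Grid, fine: Grid) -> np.ndarray:
    return _interp_component(values, grid, fine, "c")


def refine_state(state: FluidState, fine: Grid) -> FluidState:
    """Interpolate a coarse solution onto a finer grid and re-project.

    Linear interpolation per staggered component followed by one pressure
    projection, so the restart field is divergence-free to solver tolerance.
    """
    u = _interp_component(state.u, state.grid, fine, "u")
    v = _interp_component(state.v, state.grid, fine, "v")
    w = _interp_component(state.w, state.grid, fine, "w")
    p = _interp_component(state.p, state.grid, fine, "c")
    new = FluidState(grid=fine, u=u, v=v, w=w, p=p, t=state.t,
                     dt=state.dt, nu=state.nu)
    new.enforce_boundaries()
    u, v, w, _ = solver.pressure_projection(fine, new.u, new.v, new.w, 1.0)
    new.u, new.v, new.w = u, v, w
    return new
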