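"""Incompressible Navier-Stokes on a staggered Cartesian grid with immersed
moving walls.

The chamber surface is imposed on a fixed grid by a direct-forcing immersed
boundary method (IBM): Lagrangian markers at the triangle centroids of the
kinematic wall model carry the wall velocity; a localized volumetric force,
built with a 3-point regularized delta kernel, drives the fluid to that
velocity.  Pulmonary-vein inflow is imposed by relaxation forcing
``f = (v_t - v)/tau`` in small buffer boxes upstream of each inlet plane, and
the mitral outlet is a plane that opens and closes instantaneously with the
prescribed transmitral flow.

Discretization: centered second-order finite differences on a staggered grid;
low-storage three-stage semi-implicit Runge-Kutta in time (explicit advection,
implicit viscous terms) with a fractional-step pressure projection per stage.
The cubic domain has free-slip boundaries; both the pressure Poisson problem
and the per-component viscous Helmholtz problems are solved by fast
cosine/sine transforms, which are exact direct solvers for these boundary
conditions.

Units: cm, s; velocity cm/s; kinematic viscosity 0.04 cm^2/s for blood.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.fft import dctn, idctn, dst, idst

from ._kernels import advect_lap_axis0, interp3, spread3

NU_BLOOD = 0.04       # kinematic viscosity of blood, cm^2/s
BOX_SIDE = 13.0       # default cubic domain side, cm
CFL_DEFAULT = 0.3

# low-storage three-stage Runge-Kutta (Spalart-Moser-Rogers / Le-Moin
# triplet); alpha_k = gamma_k + zeta_k are the stage fractions of dt and the
# weights of the semi-implicit viscous terms.  Swap these constants for an
# alternative scheme if desired.
RK3_GAMMA = (8.0 / 15.0, 5.0 / 12.0, 3.0 / 4.0)
RK3_ZETA = (0.0, -17.0 / 60.0, -5.0 / 12.0)
RK3_ALPHA = tuple(g + z for g, z in zip(RK3_GAMMA, RK3_ZETA))
RK3_STAGE_TIME = tuple(np.cumsum(RK3_ALPHA))    # fraction of dt after stage k

# staggering offsets (node p of axis d sits at origin[d] + (p+offset)*dx)
_OFFSETS = {
    "u": (0.0, 0.5, 0.5),
    "v": (0.5, 0.0, 0.5),
    "w": (0.5, 0.5, 0.0),
    "c": (0.5, 0.5, 0.5),
}


# ---------------------------------------------------------------------------
# Grid and state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid:
    """Isotropic staggered grid on a cube of side ``length`` with ``n`` cells."""

    n: int
    length: float
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))

    @property
    def dx(self) -> float:
        return self.length / self.n

    @property
    def origin(self) -> np.ndarray:
        return self.center - 0.5 * self.length

    def coords(self, kind: str):
        """1-D node coordinates per axis for field kind 'u','v','w','c'."""
        off = _OFFSETS[kind]
        sizes = {0.0: self.n + 1, 0.5: self.n}
        return tuple(self.origin[d] + (np.arange(sizes[off[d]]) + off[d]) * self.dx
                     for d in range(3))

    def cell_centers(self) -> np.ndarray:
        """(n^3, 3) array of cell-center coordinates."""
        x, y, z = self.coords("c")
        xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")
        return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)

    def zeros(self, kind: str) -> np.ndarray:
        shp = {"u": (self.n + 1, self.n, self.n),
               "v": (self.n, self.n + 1, self.n),
               "w": (self.n, self.n, self.n + 1),
               "c": (self.n, self.n, self.n)}[kind]
        return np.zeros(shp)


@dataclass
class FluidState:
    """Staggered velocity components, cell-centered pressure and time info."""

    grid: Grid
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    p: np.ndarray
    t: float = 0.0
    dt: float = 1e-3
    nu: float = NU_BLOOD

    @classmethod
    def quiescent(cls, grid: Grid, nu: float = NU_BLOOD, dt: float = 1e-3) -> "FluidState":
        return cls(grid=grid, u=grid.zeros("u"), v=grid.zeros("v"),
                   w=grid.zeros("w"), p=grid.zeros("c"), dt=dt, nu=nu)

    def max_speed(self) -> float:
        return max(np.abs(self.u).max(), np.abs(self.v).max(),
                   np.abs(self.w).max())

    def copy(self) -> "FluidState":
        return replace(self, u=self.u.copy(), v=self.v.copy(),
                       w=self.w.copy(), p=self.p.copy())

    def enforce_boundaries(self) -> None:
        """Zero normal velocity on all six box faces (free slip)."""
        self.u[0], self.u[-1] = 0.0, 0.0
        self.v[:, 0], self.v[:, -1] = 0.0, 0.0
        self.w[:, :, 0], self.w[:, :, -1] = 0.0, 0.0


def divergence(grid: Grid, u, v, w) -> np.ndarray:
    dx = grid.dx
    return ((u[1:] - u[:-1]) + (v[:, 1:] - v[:, :-1])
            + (w[:, :, 1:] - w[:, :, :-1])) / dx


def cell_velocity(state: FluidState):
    """Velocity components averaged to cell centers."""
    u = 0.5 * (state.u[:-1] + state.u[1:])
    v = 0.5 * (state.v[:, :-1] + state.v[:, 1:])
    w = 0.5 * (state.w[:, :, :-1] + state.w[:, :, 1:])
    return u, v, w


# ---------------------------------------------------------------------------
# Fast transform solvers (free-slip box)
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=32)
def _lambda_center(n: int, dx: float) -> np.ndarray:
    """Eigenvalues of the 1-D Neumann (cell-centered) Laplacian under DCT-II."""
    k = np.arange(n)
    return 2.0 * (np.cos(np.pi * k / n) - 1.0) / dx**2


@functools.lru_cache(maxsize=32)
def _lambda_face(n: int, dx: float) -> np.ndarray:
    """Eigenvalues of the 1-D Dirichlet (interior-face) Laplacian under DST-I."""
    k = np.arange(1, n)
    return 2.0 * (np.cos(np.pi * k / n) - 1.0) / dx**2


def solve_poisson_neumann(grid: Grid, rhs: np.ndarray) -> np.ndarray:
    """Solve lap(phi) = rhs with homogeneous Neumann BC; zero-mean gauge.

    Exact direct solve of the 7-point discrete Laplacian by DCT-II
    diagonalization — the residual is at machine precision by construction.
    """
    n, dx = grid.n, grid.dx
    lam = _lambda_center(n, dx)
    f = dctn(rhs, type=2, norm="ortho")
    den = (lam[:, None, None] + lam[None, :, None] + lam[None, None, :])
    den[0, 0, 0] = 1.0
    f /= den
    f[0, 0, 0] = 0.0
    return idctn(f, type=2, norm="ortho")


def _helmholtz_axis0(q_int: np.ndarray, coef: float, n: int, dx: float) -> np.ndarray:
    """Solve (1 - coef*lap) x = q on interior faces of axis 0 (Dirichlet along
    axis 0, Neumann along axes 1 and 2)."""
    lamf = _lambda_face(n, dx)
    lamc = _lambda_center(n, dx)
    f = dst(q_int, type=1, axis=0, norm="ortho")
    f = dctn(f, type=2, axes=(1, 2), norm="ortho")
    den = 1.0 - coef * (lamf[:, None, None] + lamc[None, :, None]
                        + lamc[None, None, :])
    f /= den
    f = idctn(f, type=2, axes=(1, 2), norm="ortho")
    return idst(f, type=1, axis=0, norm="ortho")


# ---------------------------------------------------------------------------
# Spatial operators (component-generic via axis transposition)
# ---------------------------------------------------------------------------

def _advect_axis0(c, a, b, dx):
    """Conservative centered advection for the component staggered on axis 0.

    ``c`` is the advected face component (n+1, n, n); ``a`` and ``b`` are the
    transverse components staggered on axes 1 and 2.  Boundary fluxes vanish
    because the transverse normal velocities are zero on the box faces and the
    tangential derivative uses mirror ghosts.
    """
    cc = 0.25 * (c[:-1] + c[1:]) ** 2
    out = np.zeros_like(c)
    out[1:-1] = (cc[1:] - cc[:-1]) / dx

    cp = np.pad(c, ((0, 0), (1, 1), (0, 0)), mode="edge")
    c_e = 0.5 * (cp[1:-1, :-1] + cp[1:-1, 1:])        # (n-1, n+1, n)
    a_e = 0.5 * (a[:-1] + a[1:])                      # (n-1, n+1, n)
    flux = c_e * a_e
    out[1:-1] += (flux[:, 1:] - flux[:, :-1]) / dx

    cp = np.pad(c, ((0, 0), (0, 0), (1, 1)), mode="edge")
    c_e = 0.5 * (cp[1:-1, :, :-1] + cp[1:-1, :, 1:])  # (n-1, n, n+1)
    b_e = 0.5 * (b[:-1] + b[1:])                      # (n-1, n, n+1)
    flux = c_e * b_e
    out[1:-1] += (flux[:, :, 1:] - flux[:, :, :-1]) / dx
    return out


def _laplacian_axis0(c, dx):
    """Laplacian of an axis-0 face component: Dirichlet along its own axis
    (boundary faces pinned to zero), mirror-Neumann along the others."""
    out = np.zeros_like(c)
    out[1:-1] = (c[2:] - 2.0 * c[1:-1] + c[:-2]) / dx**2
    cp = np.pad(c[1:-1], ((0, 0), (1, 1), (0, 0)), mode="edge")
    out[1:-1] += (cp[:, 2:] - 2.0 * cp[:, 1:-1] + cp[:, :-2]) / dx**2
    cp = np.pad(c[1:-1], ((0, 0), (0, 0), (1, 1)), mode="edge")
    out[1:-1] += (cp[:, :, 2:] - 2.0 * cp[:, :, 1:-1] + cp[:, :, :-2]) / dx**2
    return out


# transpositions mapping each component into the axis-0-specialized layout
_PERM = {
    "u": ((0, 1, 2), (0, 1, 2)),
    "v": ((1, 0, 2), (1, 0, 2)),
    "w": ((2, 0, 1), (1, 2, 0)),
}


def advection_laplacian_terms(grid: Grid, u, v, w):
    """Advection div(u u_i) and Laplacian for all components (fused kernel)."""
    dx = grid.dx
    cc = np.ascontiguousarray
    adv_u, lap_u = advect_lap_axis0(u, v, w, dx)
    fwd, inv = _PERM["v"]
    a, l = advect_lap_axis0(cc(v.transpose(fwd)), cc(u.transpose(fwd)),
                            cc(w.transpose(fwd)), dx)
    adv_v, lap_v = cc(a.transpose(inv)), cc(l.transpose(inv))
    fwd, inv = _PERM["w"]
    a, l = advect_lap_axis0(cc(w.transpose(fwd)), cc(u.transpose(fwd)),
                            cc(v.transpose(fwd)), dx)
    adv_w, lap_w = cc(a.transpose(inv)), cc(l.transpose(inv))
    return (adv_u, adv_v, adv_w), (lap_u, lap_v, lap_w)


def advection_terms(grid: Grid, u, v, w):
    """Centered conservative advection terms (div(u u_i)) for all components."""
    return advection_laplacian_terms(grid, u, v, w)[0]


def laplacian_terms(grid: Grid, u, v, w):
    return advection_laplacian_terms(grid, u, v, w)[1]


def _helmholtz_solve(grid: Grid, comp: str, rhs_full: np.ndarray,
                     coef: float) -> np.ndarray:
    """Semi-implicit viscous solve (1 - coef*lap) q = rhs for one component.
    Boundary faces stay zero (free-slip normal velocity).

    The operator is diagonally dominant with ``coef * ||lap|| = 12 coef/dx^2``
    well below one at hemodynamic parameters, so a short Neumann series
    ``q = sum_k (coef*lap)^k rhs`` converges geometrically; it is used
    whenever it reaches a 1e-12 relative residual, with the exact
    transform-based direct solve as the general path.
    """
    n, dx = grid.n, grid.dx
    rho = 12.0 * coef / dx**2          # bound on coef * spectral radius
    if rho < 2e-3:
        n_terms = 1
        while rho ** (n_terms + 1) > 1e-12 and n_terms < 4:
            n_terms += 1
        q = rhs_full
        term = rhs_full
        for _ in range(n_terms):
            term = coef * _laplacian_like(grid, comp, term)
            q = q + term
        return q
    fwd, inv = _PERM[comp]
    r = rhs_full.transpose(fwd)
    out = np.zeros_like(r)
    out[1:-1] = _helmholtz_axis0(r[1:-1], coef, n, dx)
    return np.ascontiguousarray(out.transpose(inv))


def _laplacian_like(grid: Grid, comp: str, f: np.ndarray) -> np.ndarray:
    """Discrete Laplacian of one staggered component (same BCs as the solve)."""
    dx = grid.dx
    if comp == "u":
        return _laplacian_axis0(f, dx)
    fwd, inv = _PERM[comp]
    return np.ascontiguousarray(
        _laplacian_axis0(np.ascontiguousarray(f.transpose(fwd)), dx)
        .transpose(inv))


# ---------------------------------------------------------------------------
# Pressure projection
# ---------------------------------------------------------------------------

def pressure_projection(grid: Grid, u, v, w, dt_eff: float):
    """Project a provisional staggered field onto divergence-free space.

    Solves ``lap(phi) = div(u*)/dt_eff`` with Neumann BC and corrects the
    interior face velocities by ``-dt_eff * grad(phi)``.  Returns the
    corrected components and ``phi`` (zero-mean pressure increment).
    """
    dx = grid.dx
    div = divergence(grid, u, v, w)
    phi = solve_poisson_neumann(grid, div / dt_eff)
    u = u.copy()
    v = v.copy()
    w = w.copy()
    u[1:-1] -= dt_eff * (phi[1:] - phi[:-1]) / dx
    v[:, 1:-1] -= dt_eff * (phi[:, 1:] - phi[:, :-1]) / dx
    w[:, :, 1:-1] -= dt_eff * (phi[:, :, 1:] - phi[:, :, :-1]) / dx
    return u, v, w, phi


# ---------------------------------------------------------------------------
# Immersed boundary forcing
# ---------------------------------------------------------------------------

@dataclass
class ImmersedSurfaceMarkers:
    """Lagrangian markers: triangle centroids with areas and wall velocities."""

    positions: np.ndarray      # (m, 3) cm
    velocities: np.ndarray     # (m, 3) cm/s
    areas: np.ndarray          # (m,) cm^2

    def __len__(self) -> int:
        return len(self.positions)


def ibm_wall_force(grid: Grid, u, v, w, markers: ImmersedSurfaceMarkers,
                   dt_eff: float):
    """Direct-forcing IBM: drive the interpolated fluid velocity at each
    marker to the wall velocity.

    Returns updated components and the marker force densities (dyn/cm^3 per
    unit density, i.e. cm/s^2).  The same kernel interpolates and spreads, so
    the total spread force equals the total marker force exactly (partition
    of unity).
    """
    dx = grid.dx
    origin = grid.origin
    lo = origin + 2.0 * dx
    hi = origin + grid.length - 2.0 * dx
    if np.any(markers.positions < lo) or np.any(markers.positions > hi):
        raise ValueError("immersed-boundary marker outside the domain "
                         "interior margin (2 cells)")
    dv_m = markers.areas * dx          # marker volume weight, cm^3
    out = []
    forces = np.empty_like(markers.positions)
    for comp, fld in (("u", u), ("v", v), ("w", w)):
        off = np.asarray(_OFFSETS[comp])
        axis = "uvw".index(comp)
        interp = interp3(fld, markers.positions, origin, off, dx)
        dvel = markers.velocities[:, axis] - interp
        forces[:, axis] = dvel / dt_eff
        fld = fld.copy()
        spread3(fld, markers.positions, dvel * dv_m / dx**3,
                origin, off, dx)
        out.append(fld)
    return out[0], out[1], out[2], forces


# ---------------------------------------------------------------------------
# PV inflow buffers and mitral outlet
# ---------------------------------------------------------------------------

@dataclass
class BufferRegion:
    """Relaxation-forcing buffer upstream of one inlet plane.

    ``masks`` holds one boolean array per staggered component; ``normal`` is
    the unit inflow direction; ``flow`` maps time to the vein flow rate Q_i
    (ml/s); the target velocity is (Q_i/area) * normal.
    """

    masks: dict                     # {"u": bool (n+1,n,n), "v": ..., "w": ...}
    cell_mask: np.ndarray           # cell-centered bool (scalar reset region)
    normal: np.ndarray
    area: float
    flow: Callable[[float], float]

    def target(self, t: float) -> np.ndarray:
        return (self.flow(t) / self.area) * self.normal

    def flat_index(self, comp: str) -> np.ndarray:
        cache = self.__dict__.setdefault("_flat", {})
        if comp not in cache:
            cache[comp] = np.flatnonzero(self.masks[comp].reshape(-1))
        return cache[comp]


def make_buffer(grid: Grid, center: np.ndarray, normal: np.ndarray,
                radius: float, thickness_cells: int = 3,
                flow: Callable[[float], float] = lambda t: 0.0,
                upstream_axis: np.ndarray | None = None) -> BufferRegion:
    """Cylindrical buffer just upstream of an inlet plane.

    ``center``/``normal`` describe the inlet plane (normal = inflow
    direction); the buffer occupies axial positions in (0, thickness*dx]
    measured *against* the inflow direction (i.e. outside the chamber).
    """
    ax = -normal if upstream_axis is None else upstream_axis
    ax = np.asarray(ax, float) / np.linalg.norm(ax)
    th = thickness_cells * grid.dx
    masks = {}
    for comp in ("u", "v", "w", "c"):
        xs = grid.coords(comp)
        xx, yy, zz = np.meshgrid(*xs, indexing="ij")
        rel = np.stack([xx - center[0], yy - center[1], zz - center[2]], axis=-1)
        s = rel @ ax
        rad = np.linalg.norm(rel - s[..., None] * ax, axis=-1)
        m = (s > 0.0) & (s <= th) & (rad <= radius)
        if comp == "c":
            cell_mask = m
        else:
            masks[comp] = m
    return BufferRegion(masks=masks, cell_mask=cell_mask,
                        normal=np.asarray(normal, float),
                        area=float(np.pi * radius**2), flow=flow)


def pv_inflow_force(grid: Grid, u, v, w, buffers: Sequence[BufferRegion],
                    t: float, tau: float, dt_eff: float):
    """Apply the relaxation forcing f = (v_t - v)/tau inside each buffer.

    Integrated implicitly over the stage (v <- (v + c v_t)/(1+c) with
    c = dt_eff/tau), which reproduces the exponential relaxation toward the
    target for any tau > 0.
    """
    if tau <= 0:
        raise ValueError("relaxation time tau must be positive")
    c = dt_eff / tau
    u = u.copy()
    v = v.copy()
    w = w.copy()
    for buf in buffers:
        vt = buf.target(t)
        for i, fld in enumerate((u, v, w)):
            idx = buf.flat_index("uvw"[i])
            flat = fld.reshape(-1)
            flat[idx] = (flat[idx] + c * vt[i]) / (1.0 + c)
    return u, v, w


@dataclass
class ValvePatch:
    """Mitral plane on a grid-aligned plane of ``w`` faces (axis given by
    ``axis``; the generator always builds the mitral stub along -z)."""

    axis: int                  # 0,1,2 -> normal along x,y,z
    k: int                     # face index along the axis
    disk: np.ndarray           # boolean mask over the transverse cell indices
    outward: float             # +1 or -1: sign of outflow normal velocity
    area: float                # disk area represented on the grid, cm^2
    q_mv: Callable[[float], float]
    # rescaling the open-valve plane to the exact flux is available for
    # diagnostics, but the default leaves the projected field untouched: in a
    # sealed box the chamber kinematics already fix the net mitral flux
    rescale_open: bool = False

    def is_open(self, t: float) -> bool:
        return self.q_mv(t) > 0.0


def make_valve(grid: Grid, center: np.ndarray, outward_normal: np.ndarray,
               radius: float, q_mv: Callable[[float], float]) -> ValvePatch:
    nrm = np.asarray(outward_normal, float)
    axis = int(np.argmax(np.abs(nrm)))
    if abs(abs(nrm[axis]) - 1.0) > 1e-6:
        raise ValueError("mitral plane must be grid-aligned")
    comp = "uvw"[axis]
    xs = grid.coords(comp)
    k = int(np.argmin(np.abs(xs[axis] - center[axis])))
    trans = [d for d in range(3) if d != axis]
    cc = grid.coords("c")
    g0, g1 = np.meshgrid(cc[trans[0]], cc[trans[1]], indexing="ij")
    disk = ((g0 - center[trans[0]]) ** 2 + (g1 - center[trans[1]]) ** 2
            <= radius**2)
    area = float(disk.sum()) * grid.dx**2
    return ValvePatch(axis=axis, k=k, disk=disk, outward=float(np.sign(nrm[axis])),
                      area=area, q_mv=q_mv)


def _valve_slice(patch: ValvePatch, fld: np.ndarray):
    idx = [slice(None)] * 3
    idx[patch.axis] = patch.k
    return tuple(idx)


def valve_flux(patch: ValvePatch, u, v, w, dx: float) -> float:
    """Net outflow (ml/s) through the valve plane."""
    fld = (u, v, w)[patch.axis]
    vals = fld[_valve_slice(patch, fld)]
    return float(patch.outward * vals[patch.disk].sum() * dx**2)


def mitral_outlet(grid: Grid, u, v, w, patch: ValvePatch, t: float,
                  tau: float, dt_eff: float, stage_of: str = "pre"):
    """Valve treatment for the current substage.

    Pre-projection (``stage_of='pre'``): when open, relax the plane's normal
    velocity toward the uniform target Q_MV/A (an actuator-disk outflow
    condition); when closed, relax it toward zero (the cap triangles also
    rejoin the IBM marker set, so the plane acts as a wall).
    Post-projection (``stage_of='post'``): when closed, zero the plane's
    normal velocity exactly — the valve closes instantly; when open, rescale
    the plane's normal velocities so the net flux matches Q_MV exactly.
    """
    fld = (u, v, w)[patch.axis].copy()
    sl = _valve_slice(patch, fld)
    q = patch.q_mv(t)
    target = patch.outward * q / patch.area
    vals = fld[sl]
    if stage_of == "pre":
        c = dt_eff / tau
        vals[patch.disk] = (vals[patch.disk] + c * target) / (1.0 + c)
    else:
        if q <= 0.0:
            vals[patch.disk] = 0.0
        elif patch.rescale_open:
            # additive uniform correction: exact net flux, bounded update
            flux = patch.outward * vals[patch.disk].sum() * grid.dx**2
            n_cells = int(patch.disk.sum())
            vals[patch.disk] += patch.outward * (q - flux) / (n_cells * grid.dx**2)
    fld[sl] = vals
    out = [u, v, w]
    out[patch.axis] = fld
    return out[0], out[1], out[2]


# ---------------------------------------------------------------------------
# Time stepping
# ---------------------------------------------------------------------------

def adaptive_dt(state: FluidState, cfl_max: float = CFL_DEFAULT,
                dt_max: float = 2e-3) -> float:
    """Largest time step with max(|u|,|v|,|w|) dt / dx <= cfl_max, capped."""
    vmax = state.max_speed()
    if not np.isfinite(vmax):
        raise FloatingPointError("velocity field is not finite")
    if vmax <= 0.0:
        return dt_max
    return min(dt_max, cfl_max * state.grid.dx / vmax)


def advance_substep(state: FluidState, stage: int,
                    markers: ImmersedSurfaceMarkers | None = None,
                    buffers: Sequence[BufferRegion] = (),
                    valve: ValvePatch | None = None,
                    tau: float | None = None,
                    adv_prev: tuple | None = None,
                    stage_time: float | None = None):
    """One Runge-Kutta substage: explicit advection, semi-implicit viscosity,
    IBM / inflow / valve forcing, and pressure projection.

    Returns ``(state, adv_terms)`` where ``adv_terms`` must be passed back as
    ``adv_prev`` for the next substage.  ``stage`` is 0-based (0..2).
    """
    g = RK3_GAMMA[stage]
    z = RK3_ZETA[stage]
    a = RK3_ALPHA[stage]
    grid = state.grid
    dt = state.dt
    dt_eff = a * dt
    # state.t tracks the end of the previous substage, so each substage
    # advances the clock by its own fraction alpha_k of dt
    t_stage = state.t + a * dt if stage_time is None else stage_time

    adv, lap = advection_laplacian_terms(grid, state.u, state.v, state.w)
    if adv_prev is None:
        adv_prev = adv
    dx = grid.dx
    gp = [np.zeros_like(state.u), np.zeros_like(state.v), np.zeros_like(state.w)]
    gp[0][1:-1] = (state.p[1:] - state.p[:-1]) / dx
    gp[1][:, 1:-1] = (state.p[:, 1:] - state.p[:, :-1]) / dx
    gp[2][:, :, 1:-1] = (state.p[:, :, 1:] - state.p[:, :, :-1]) / dx

    coef = 0.5 * state.nu * dt_eff
    fields = []
    for comp, q, advq, advp, lapq, gpq in zip(
            "uvw", (state.u, state.v, state.w), adv, adv_prev, lap, gp):
        rhs = (q + dt * (-g * advq - z * advp) + coef * lapq - dt_eff * gpq)
        fields.append(_helmholtz_solve(grid, comp, rhs, coef))
    u, v, w = fields

    if markers is not None and len(markers):
        u, v, w, _ = ibm_wall_force(grid, u, v, w, markers, dt_eff)
    if buffers:
        u, v, w = pv_inflow_force(grid, u, v, w, buffers, t_stage,
                                  tau if tau is not None else 10 * dt, dt_eff)
    if valve is not None:
        u, v, w = mitral_outlet(grid, u, v, w, valve, t_stage,
                                tau if tau is not None else 10 * dt, dt_eff, "pre")

    u, v, w, phi = pressure_projection(grid, u, v, w, dt_eff)
    p = state.p + phi

    if valve is not None:
        u, v, w = mitral_outlet(grid, u, v, w, valve, t_stage,
                                tau if tau is not None else 10 * dt, dt_eff, "post")

    new = replace(state, u=u, v=v, w=w, p=p, t=t_stage)
    new.enforce_boundaries()
    if not np.isfinite(new.u).all():
        raise FloatingPointError(f"solver diverged at t={new.t:.4f}")
    return new, adv
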