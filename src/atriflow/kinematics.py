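"""Continuous-time wall kinematics, chamber volumes and atrial-function indices.

A sequence of corresponded, closed surface triangulations (one per cardiac
phase) is turned into a periodic Fourier-in-time kinematic model that evaluates
wall position and velocity at arbitrary time.  Chamber and appendage volumes,
the standard atrial-function indices (ejection fractions, expansion index,
conduit ratio, sphericity) and the mass-conserving pulmonary-vein inflow
waveform are derived from it.

Units are cm, s and ml (= cm^3) throughout.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import trimesh

from . import geometry

N_FOU_DEFAULT = 6  # temporal Fourier modes used for the kinematic wall model


# ---------------------------------------------------------------------------
# Kinematic surface model
# ---------------------------------------------------------------------------

@dataclass
class KinematicSurfaceModel:
    """Periodic Fourier-in-time model of a moving closed triangulated surface.

    Vertex positions are represented as
    ``x(t) = c_0 + sum_{k=1..K} 2 Re{ c_k exp(2 pi i k t / T) }``
    with complex coefficients from a least-squares (truncated-DFT) fit to
    uniformly spaced frames.  The velocity evaluator is the term-by-term
    analytic derivative, so position and velocity are exactly periodic and
    mutually consistent.
    """

    coeffs: np.ndarray            # complex, (K+1, n_vertices, 3)
    faces: np.ndarray             # (n_faces, 3) int
    period: float                 # s
    face_tags: np.ndarray | None = None   # region tag per face

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=complex)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.period <= 0:
            raise ValueError("period must be positive")

    @property
    def n_modes(self) -> int:
        return self.coeffs.shape[0] - 1

    @property
    def n_vertices(self) -> int:
        return self.coeffs.shape[1]

    def _phases(self, t: float) -> np.ndarray:
        k = np.arange(1, self.n_modes + 1)
        return np.exp(2j * np.pi * k * (t / self.period))

    def positions(self, t: float) -> np.ndarray:
        """Vertex positions (cm) at time ``t`` (periodic in ``period``)."""
        ph = self._phases(t)
        x = self.coeffs[0].real + 2.0 * np.real(
            np.tensordot(ph, self.coeffs[1:], axes=(0, 0)))
        return x

    def velocities(self, t: float) -> np.ndarray:
        """Vertex velocities (cm/s): analytic time derivative of the series."""
        k = np.arange(1, self.n_modes + 1)
        ph = self._phases(t) * (2j * np.pi * k / self.period)
        return 2.0 * np.real(np.tensordot(ph, self.coeffs[1:], axes=(0, 0)))

    def mean_positions(self) -> np.ndarray:
        """Zero-mode (time-averaged) vertex positions."""
        return self.coeffs[0].real.copy()

    def frozen(self) -> "KinematicSurfaceModel":
        """Model with walls fixed at the zero mode of the Fourier series."""
        c = np.zeros_like(self.coeffs)
        c[0] = self.coeffs[0]
        return KinematicSurfaceModel(coeffs=c, faces=self.faces,
                                     period=self.period, face_tags=self.face_tags)

    # -- triangle-level evaluators (the solver's Lagrangian markers) --------

    def centroid_positions(self, t: float) -> np.ndarray:
        return self.positions(t)[self.faces].mean(axis=1)

    def centroid_velocities(self, t: float) -> np.ndarray:
        return self.velocities(t)[self.faces].mean(axis=1)

    def face_areas_normals(self, t: float):
        """Per-triangle areas (cm^2) and outward unit normals at time ``t``."""
        x = self.positions(t)
        tri = x[self.faces]
        cr = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        nrm = np.linalg.norm(cr, axis=1)
        areas = 0.5 * nrm
        normals = cr / np.maximum(nrm, 1e-300)[:, None]
        return areas, normals

    def mesh_at(self, t: float) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.positions(t), faces=self.faces,
                               process=False)

    def volume(self, t: float) -> float:
        """Chamber volume (ml) at time ``t`` by the divergence theorem."""
        return mesh_volume(self.mesh_at(t))

    def volume_rate(self, t: float) -> float:
        """Exact dV/dt (ml/s) via the product rule on the signed-volume sum."""
        x = self.positions(t)
        v = self.velocities(t)
        a, b, c = (x[self.faces[:, i]] for i in range(3))
        da, db, dc = (v[self.faces[:, i]] for i in range(3))
        det = np.einsum("ij,ij->i", np.cross(da, b), c) \
            + np.einsum("ij,ij->i", np.cross(a, db), c) \
            + np.einsum("ij,ij->i", np.cross(a, b), dc)
        return float(det.sum() / 6.0)


def fit_fourier_model(frames, n_modes: int = N_FOU_DEFAULT, period: float = 1.0,
                      faces: np.ndarray | None = None,
                      face_tags: np.ndarray | None = None) -> KinematicSurfaceModel:
    """Fit the periodic Fourier wall model to uniformly spaced surface frames.

    ``frames`` is either a list of :class:`trimesh.Trimesh` with identical
    connectivity, or an array of vertex positions with shape ``(M, n, 3)``
    (then ``faces`` is required).  Frames sample one period uniformly at
    ``t_m = m T / M``.  With ``M = 2 n_modes + 1`` the fit is an exact
    trigonometric interpolant; with more frames it is the least-squares
    truncated-DFT fit.
    """
    if isinstance(frames, (list, tuple)) and isinstance(frames[0], trimesh.Trimesh):
        f0 = np.asarray(frames[0].faces)
        for fr in frames[1:]:
            if not np.array_equal(np.asarray(fr.faces), f0):
                raise ValueError("frames have mismatched connectivity")
        verts = np.stack([np.asarray(fr.vertices, dtype=float) for fr in frames])
        faces = f0
    else:
        verts = np.asarray(frames, dtype=float)
        if faces is None:
            raise ValueError("faces required when frames given as arrays")
    m = verts.shape[0]
    if m < 2 * n_modes + 1:
        raise ValueError(
            f"need at least {2 * n_modes + 1} frames for {n_modes} modes, got {m}")
    coeffs = np.fft.rfft(verts, axis=0)[: n_modes + 1] / m
    return KinematicSurfaceModel(coeffs=coeffs, faces=np.asarray(faces),
                                 period=period, face_tags=face_tags)


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def mesh_volume(surface) -> float:
    """Signed volume (ml) of a closed triangulated surface.

    Divergence-theorem sum of signed tetrahedra about the vertex centroid,
    which is exact for closed polyhedra and exactly translation invariant.
    Raises on open surfaces and on inward (negative-volume) orientation.
    """
    if isinstance(surface, trimesh.Trimesh):
        verts, faces = np.asarray(surface.vertices, float), np.asarray(surface.faces)
        watertight = surface.is_watertight
    else:
        verts, faces = (np.asarray(surface[0], float), np.asarray(surface[1]))
        watertight = trimesh.Trimesh(vertices=verts, faces=faces,
                                     process=False).is_watertight
    if not watertight:
        raise ValueError("surface is not closed (watertight)")
    v = _signed_volume(verts, faces)
    if v <= 0:
        raise ValueError("surface has inward orientation (negative signed volume)")
    return v


def _signed_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    c = verts.mean(axis=0)
    a, b, d = (verts[faces[:, i]] - c for i in range(3))
    return float(np.einsum("ij,ij->i", np.cross(a, b), d).sum() / 6.0)


def _laa_subsurface_volume(verts: np.ndarray, faces: np.ndarray,
                           laa_faces: np.ndarray) -> float:
    """Volume of the appendage region: LAA-tagged faces + fan caps over each
    boundary (orifice) loop."""
    sub = faces[laa_faces]
    edges = np.concatenate([sub[:, [0, 1]], sub[:, [1, 2]], sub[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    _, idx, cnt = np.unique(key, axis=0, return_index=True, return_counts=True)
    boundary = edges[idx[cnt == 1]]  # directed as in the LAA faces
    tris = [verts[sub]]
    # close each boundary loop with a fan to its own centroid (cap normal
    # points out of the LAA volume because boundary edges keep their winding)
    loops = _edge_loops(boundary)
    for loop in loops:
        ring = verts[loop]
        c = ring.mean(axis=0)
        nxt = np.roll(loop, -1)
        cap = np.stack([verts[nxt], verts[loop],
                        np.broadcast_to(c, (len(loop), 3))], axis=1)
        tris.append(cap)
    tri = np.concatenate(tris)
    ref = tri[:, 0].mean(axis=0)
    a, b, d = (tri[:, i] - ref for i in range(3))
    return float(np.einsum("ij,ij->i", np.cross(a, b), d).sum() / 6.0)


def _edge_loops(directed_edges: np.ndarray) -> list[np.ndarray]:
    nxt = {int(a): int(b) for a, b in directed_edges}
    loops = []
    while nxt:
        start, cur = next(iter(nxt.items()))
        loop = [start]
        while cur != start:
            loop.append(cur)
            cur = nxt.pop(cur)
        nxt.pop(start)
        loops.append(np.asarray(loop))
    return loops


@dataclass
class ChamberVolumeSeries:
    """Sampled chamber (and appendage) volume waveforms over one period."""

    times: np.ndarray             # s
    v_la: np.ndarray              # ml
    v_laa: np.ndarray | None      # ml, None when no LAA tags were available
    period: float
    pre_a_time: float | None = None   # s, onset of atrial contraction

    def __post_init__(self):
        if np.any(self.v_la <= 0):
            raise ValueError("chamber volumes must be positive")

    @property
    def v_min(self) -> float:
        return float(self.v_la.min())

    @property
    def v_max(self) -> float:
        return float(self.v_la.max())

    @property
    def v_mean(self) -> float:
        return float(self.v_la.mean())

    @property
    def v_pre_a(self) -> float | None:
        if self.pre_a_time is None:
            return None
        i = int(np.argmin(np.abs(self.times - self.pre_a_time)))
        return float(self.v_la[i])

    def laa_stats(self):
        if self.v_laa is None:
            return None
        return (float(self.v_laa.min()), float(self.v_laa.mean()),
                float(self.v_laa.max()))


def compute_volume_series(model: KinematicSurfaceModel, samples: int = 200,
                          pre_a_time: float | None = None,
                          waveforms: "FlowWaveforms | None" = None) -> ChamberVolumeSeries:
    """Sample V_LA(t) and V_LAA(t) from the kinematic model.

    The pre-A-wave instant is taken from ``pre_a_time`` if given, otherwise
    from the A-wave annotation of ``waveforms``; with neither, booster/passive
    indices will be unavailable downstream.
    """
    times = np.linspace(0.0, model.period, samples, endpoint=False)
    has_laa = (model.face_tags is not None
               and np.any(model.face_tags == geometry.LAA))
    v_la = np.empty(samples)
    v_laa = np.empty(samples) if has_laa else None
    laa_faces = (np.flatnonzero(model.face_tags == geometry.LAA)
                 if has_laa else None)
    for i, t in enumerate(times):
        verts = model.positions(t)
        v_la[i] = _signed_volume(verts, model.faces)
        if has_laa:
            v_laa[i] = _laa_subsurface_volume(verts, model.faces, laa_faces)
    if pre_a_time is None and waveforms is not None:
        win = waveforms.annotations.get("a_wave")
        if win is not None:
            pre_a_time = float(win[0])
    return ChamberVolumeSeries(times=times, v_la=v_la, v_laa=v_laa,
                               period=model.period, pre_a_time=pre_a_time)


# ---------------------------------------------------------------------------
# Function indices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FunctionIndices:
    """Standard volume-derived indices of atrial function (dimensionless)."""

    global_ef: float              # (Vmax - Vmin) / Vmax
    expansion_index: float        # (Vmax - Vmin) / Vmin
    passive_ef: float | None      # (Vmax - VpreA) / Vmax
    booster_ef: float | None      # (VpreA - Vmin) / VpreA
    laa_ef: float | None          # (VLAA,max - VLAA,min) / VLAA,max
    conduit_ratio: float | None   # 1 - (Vmax - Vmin) / SV
    sphericity: float | None = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "global_ef", "expansion_index", "passive_ef", "booster_ef",
            "laa_ef", "conduit_ratio", "sphericity")}


def atrial_function_indices(vols: ChamberVolumeSeries,
                            stroke_volume: float | None = None,
                            surface=None) -> FunctionIndices:
    """Compute ejection fractions and related indices from a volume series.

    ``stroke_volume`` (ml, LV stroke volume) enables the conduit-volume ratio;
    ``surface`` (a closed mesh, typically at maximum volume) enables
    sphericity.  Values are kept at full precision — round only for reporting.
    """
    vmax, vmin = vols.v_max, vols.v_min
    if vmax <= 0 or vmin <= 0:
        raise ZeroDivisionError("volumes must be positive")
    g_ef = (vmax - vmin) / vmax
    exp_i = (vmax - vmin) / vmin
    vpre = vols.v_pre_a
    p_ef = (vmax - vpre) / vmax if vpre is not None else None
    b_ef = (vpre - vmin) / vpre if vpre is not None else None
    laa = vols.laa_stats()
    laa_ef = None
    if laa is not None:
        lmin, _, lmax = laa
        if lmax <= 0:
            raise ZeroDivisionError("LAA volumes must be positive")
        laa_ef = (lmax - lmin) / lmax
    conduit = None
    if stroke_volume is not None:
        if stroke_volume <= 0:
            raise ZeroDivisionError("stroke volume must be positive")
        conduit = 1.0 - (vmax - vmin) / stroke_volume
    sph = sphericity(surface) if surface is not None else None
    return FunctionIndices(global_ef=g_ef, expansion_index=exp_i,
                           passive_ef=p_ef, booster_ef=b_ef, laa_ef=laa_ef,
                           conduit_ratio=conduit, sphericity=sph)


def sphericity(surface) -> float:
    """Psi = pi^(1/3) (6V)^(2/3) / A in (0, 1]; 1 for a sphere."""
    v = mesh_volume(surface)
    if isinstance(surface, trimesh.Trimesh):
        area = float(surface.area)
    else:
        area = float(trimesh.Trimesh(vertices=surface[0], faces=surface[1],
                                     process=False).area)
    return float(np.pi ** (1.0 / 3.0) * (6.0 * v) ** (2.0 / 3.0) / area)


# ---------------------------------------------------------------------------
# Flow waveforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InletGeometry:
    """A PV inlet plane: center, inward unit normal and cross-sectional area."""

    center: np.ndarray        # cm
    normal: np.ndarray        # unit vector, pointing INTO the chamber
    area: float               # cm^2
    radius: float             # cm


@dataclass
class FlowWaveforms:
    """Transmitral and pulmonary-vein flow-rate waveforms plus inlet targets.

    ``q_mv(t)`` (ml/s, >= 0) is the transmitral outflow; ``q_pv(t)`` (ml/s,
    signed; negative = Ar backflow) is the combined PV inflow closed by mass
    conservation, split evenly over the four veins.  ``annotations`` maps wave
    names (``e_wave``, ``a_wave``, ...) to ``(t_start, t_end)`` windows.
    """

    period: float
    q_mv: Callable[[float], float]
    q_pv: Callable[[float], float]
    inlets: tuple[InletGeometry, ...] = ()
    annotations: dict = field(default_factory=dict)

    @property
    def n_veins(self) -> int:
        return max(len(self.inlets), 1)

    def q_i(self, t: float) -> float:
        """Per-vein flow rate: the combined PV flow split evenly."""
        return self.q_pv(t) / self.n_veins

    def target_velocity(self, i: int, t: float) -> np.ndarray:
        """v_t = (Q_i / A_i) n for vein ``i`` — the buffer forcing target (cm/s)."""
        inlet = self.inlets[i]
        return (self.q_i(t) / inlet.area) * inlet.normal

    def sample(self, nt: int = 200) -> pd.DataFrame:
        t = np.linspace(0.0, self.period, nt, endpoint=False)
        return pd.DataFrame({
            "t_s": t,
            "q_mv_ml_s": [self.q_mv(ti) for ti in t],
            "q_pv_ml_s": [self.q_pv(ti) for ti in t],
        })


def pv_flow_balance(model: KinematicSurfaceModel, q_mv: Callable[[float], float],
                    inlets: Sequence[InletGeometry] = (),
                    annotations: dict | None = None) -> FlowWaveforms:
    """Close the PV inflow by mass conservation: Q_PV(t) = dV/dt + Q_MV(t).

    dV/dt is the exact analytic rate of the Fourier surface model, so the
    balance holds to machine precision at any t.  The combined flow is split
    evenly among the veins (``FlowWaveforms.q_i``); backflow (Ar wave,
    Q_PV < 0) is permitted.
    """
    @functools.lru_cache(maxsize=64)
    def q_pv(t: float) -> float:
        return model.volume_rate(t) + q_mv(t)

    return FlowWaveforms(period=model.period, q_mv=q_mv, q_pv=q_pv,
                         inlets=tuple(inlets), annotations=annotations or {})
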