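"""Synthetic moving left-atrium test cases.

Generates idealized, corresponded, closed surface frames of a left-atrium-like
chamber (ellipsoidal body, four PV stubs, mitral stub, lobed appendage) whose
volume waveform realizes prescribed atrial-function indices — reservoir,
conduit and booster phases — together with a physiological transmitral
flow-rate waveform with E and A waves.  These cases stand in for 4D-CT
segmentations: they are born corresponded (shared icosphere connectivity),
carry region tags (body, LAA, PV1–4 inlet planes, mitral plane) and ground
truth, and feed directly into the kinematics and flow-solver modules.

The wall motion model is deliberately simple: a time-varying isotropic scale of
the body and an independent radial scale of the appendage, each fitted per
phase by 1-D root finding so the meshed volumes match the prescribed V(t) to
high accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from . import geometry, kinematics
from .geometry import ChamberShape, SphereTemplate, Tube
from .kinematics import FlowWaveforms, InletGeometry, KinematicSurfaceModel

# cycle timeline (fractions of the period, t = 0 at minimum volume /
# mitral-valve closure).  Reservoir filling peaks at 0.40; the E-wave spans
# [0.42, 0.60]; diastasis follows; the A-wave occupies the final 22% of the
# cycle (A-wave duration 0.18-0.30 cycles in patients).
T_PEAK = 0.40
E_WINDOW = (0.42, 0.60)
A_DURATION = 0.22


class ParameterError(ValueError):
    """Raised for mutually infeasible or invalid anatomy parameters."""


@dataclass(frozen=True)
class AnatomyParams:
    """Parameters of a synthetic moving-atrium case.  Lengths cm, times s.

    The function-index targets mirror the standard volume-derived indices:
    ``global_ef`` and ``booster_ef`` are prescribed, ``passive_ef`` follows
    from the identity (1 - global) = (1 - passive)(1 - booster) unless given
    explicitly (then it must be consistent).
    """

    semi_axes: tuple = (3.1, 2.7, 2.3)     # body ellipsoid semi-axes
    pv_radius: float = 0.85
    pv_length: float = 4.2                 # center -> inlet plane
    laa_orifice: float = 2.4               # appendage tube diameter at center
    laa_length: float = 5.6                # center -> apex cap
    laa_taper: float = 0.35
    laa_lobes: int = 1
    mitral_radius: float = 1.35
    mitral_length: float = 3.4
    triangle_budget: int = 5120
    period: float = 1.0                    # s
    n_phases: int = 20                     # frames per cycle (5% RR)
    v_max: float = 108.0                   # ml, maximum chamber volume target
    global_ef: float = 0.45
    booster_ef: float = 0.37
    passive_ef: float | None = None        # derived when None
    laa_ef: float = 0.52
    mv_stroke_volume: float = 72.0         # ml, cycle integral of Q_MV
    ea_ratio: float = 1.64                 # E-wave / A-wave peak flow ratio
    anatomy_jitter: float = 0.0            # relative scale of seeded variation
    seed: int = 0

    def __post_init__(self):
        for name in ("pv_radius", "pv_length", "laa_orifice", "laa_length",
                     "mitral_radius", "mitral_length", "period", "v_max"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if any(a <= 0 for a in self.semi_axes):
            raise ParameterError("semi-axes must be positive")
        if self.n_phases < 10:
            raise ParameterError("need at least 10 phases per cycle")
        if self.laa_lobes < 1:
            raise ParameterError("lobe count must be >= 1")
        for name in ("global_ef", "booster_ef", "laa_ef"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ParameterError(f"{name} must lie in [0, 1)")
        if self.mv_stroke_volume < 0 or self.ea_ratio < 0:
            raise ParameterError("stroke volume and E/A ratio must be non-negative")
        if self.booster_ef > self.global_ef + 1e-12:
            raise ParameterError(
                "booster EF cannot exceed global EF (pre-A volume would "
                "exceed the maximum volume)")
        if self.global_ef > 0 >= self.v_max * self.global_ef:
            raise ParameterError("invalid volume targets")
        derived = self.derived_passive_ef()
        if self.passive_ef is not None and abs(self.passive_ef - derived) > 5e-3:
            raise ParameterError(
                f"passive EF {self.passive_ef} inconsistent with global/booster "
                f"targets (implied {derived:.4f})")
        if self.global_ef == 0.0 and self.booster_ef != 0.0:
            raise ParameterError("rigid case (global EF 0) requires booster EF 0")

    def derived_passive_ef(self) -> float:
        if self.booster_ef >= 1.0:
            raise ParameterError("booster EF must be < 1")
        return 1.0 - (1.0 - self.global_ef) / (1.0 - self.booster_ef)

    @property
    def v_min(self) -> float:
        return self.v_max * (1.0 - self.global_ef)

    @property
    def v_pre_a(self) -> float:
        return self.v_min / (1.0 - self.booster_ef)

    @property
    def pre_a_time(self) -> float:
        return (1.0 - A_DURATION) * self.period

    def index_targets(self) -> dict:
        return {
            "global_ef": self.global_ef,
            "expansion_index": self.global_ef / (1.0 - self.global_ef),
            "passive_ef": self.derived_passive_ef(),
            "booster_ef": self.booster_ef,
            "laa_ef": self.laa_ef,
            "v_max": self.v_max,
            "v_min": self.v_min,
            "v_pre_a": self.v_pre_a,
        }


# ---------------------------------------------------------------------------
# Prescribed volume waveform
# ---------------------------------------------------------------------------

def _smoothstep(s: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(s, 0.0, 1.0)))


def volume_waveform(params: AnatomyParams):
    """Prescribed V_LA(t): C1-smooth, periodic, with reservoir rise to V_max,
    E-wave fall to the pre-A volume, diastasis plateau and A-wave fall to
    V_min.  Returns a vectorized callable of time (s) -> volume (ml)."""
    t_pk = T_PEAK * params.period
    e0, e1 = (f * params.period for f in E_WINDOW)
    t_pre = params.pre_a_time
    vmin, vmax, vpre = params.v_min, params.v_max, params.v_pre_a

    def v_of_t(t):
        tt = np.asarray(t, dtype=float) % params.period
        out = np.empty_like(tt)
        seg = tt <= t_pk
        out[seg] = vmin + (vmax - vmin) * _smoothstep(tt[seg] / t_pk)
        seg = (tt > t_pk) & (tt <= e0)
        out[seg] = vmax
        seg = (tt > e0) & (tt <= e1)
        out[seg] = vmax + (vpre - vmax) * _smoothstep((tt[seg] - e0) / (e1 - e0))
        seg = (tt > e1) & (tt <= t_pre)
        out[seg] = vpre
        seg = tt > t_pre
        out[seg] = vpre + (vmin - vpre) * _smoothstep(
            (tt[seg] - t_pre) / (params.period - t_pre))
        return out if out.ndim else float(out)

    return v_of_t


# ---------------------------------------------------------------------------
# Transmitral waveform
# ---------------------------------------------------------------------------

def make_transmitral_waveform(params: AnatomyParams,
                              fixed_wall: bool = False) -> FlowWaveforms:
    """Q_MV(t): smooth, periodic, non-negative, with sin^2 E and A lobes.

    Lobe peak flow rates are set so the cycle integral equals the prescribed
    transmitral stroke volume and the peak ratio equals ``ea_ratio``.  With
    ``fixed_wall=True`` the A lobe is removed — Q_MV is exactly zero over the
    whole atrial-contraction window, mirroring the fixed-wall protocol in
    which walls are frozen and late diastolic ejection is absent.

    When called standalone the returned waveform closes mass conservation with
    rigid walls (Q_PV = Q_MV); case generation rebinds Q_PV to the moving
    chamber via :func:`atriflow.kinematics.pv_flow_balance`.
    """
    T = params.period
    e0, e1 = (f * T for f in E_WINDOW)
    a0, a1 = params.pre_a_time, T
    w_e, w_a = (e1 - e0) / T, (a1 - a0) / T
    sv = params.mv_stroke_volume
    # integral of q sin^2(pi s) over a window of width w*T is q*w*T/2
    if sv == 0.0 or (params.ea_ratio == 0.0 and w_a == 0.0):
        q_e_pk = q_a_pk = 0.0
    else:
        q_a_pk = 2.0 * sv / (T * (params.ea_ratio * w_e + w_a))
        q_e_pk = params.ea_ratio * q_a_pk
    if fixed_wall:
        # preserve the E wave, digitally remove the A wave
        q_a_pk = 0.0

    def q_mv(t):
        tt = np.asarray(t, dtype=float) % T
        out = np.zeros_like(tt)
        seg = (tt >= e0) & (tt <= e1)
        out[seg] = q_e_pk * np.sin(np.pi * (tt[seg] - e0) / (e1 - e0)) ** 2
        seg = (tt >= a0) & (tt <= a1)
        out[seg] += q_a_pk * np.sin(np.pi * (tt[seg] - a0) / (a1 - a0)) ** 2
        return out if out.ndim else float(out)

    annotations = {"e_wave": (e0, e1), "a_wave": (a0, a1)}
    return FlowWaveforms(period=T, q_mv=q_mv, q_pv=q_mv,
                         annotations=annotations)


# ---------------------------------------------------------------------------
# Case generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCase:
    """A generated moving-atrium case: meshes, kinematic model, waveforms,
    region tags and ground truth."""

    params: AnatomyParams
    shape: ChamberShape
    template: SphereTemplate
    frames: np.ndarray                     # (M, n_vertices, 3)
    model: KinematicSurfaceModel
    waveforms: FlowWaveforms
    face_tags: np.ndarray                  # per-face region tag
    body_scales: np.ndarray                # beta at each phase
    laa_scales: np.ndarray                 # gamma at each phase
    v_target: np.ndarray                   # prescribed V_LA at each phase (ml)
    index_targets: dict = field(default_factory=dict)
    fixed_wall: bool = False

    @property
    def phase_times(self) -> np.ndarray:
        m = len(self.frames)
        return np.arange(m) * self.params.period / m

    def _scale_at(self, series: np.ndarray, t: float) -> float:
        # scales vary smoothly; periodic linear interpolation is ample for
        # region masks (volumes come from the meshes, not from here)
        tt = (t / self.params.period) % 1.0
        m = len(series)
        x = tt * m
        i = int(np.floor(x)) % m
        f = x - np.floor(x)
        return float((1 - f) * series[i] + f * series[(i + 1) % m])

    def body_scale(self, t: float) -> float:
        return self._scale_at(self.body_scales, t)

    def laa_scale(self, t: float) -> float:
        return self._scale_at(self.laa_scales, t)

    def laa_mask(self, points: np.ndarray, t: float) -> np.ndarray:
        """Boolean mask of points inside the appendage at time ``t``."""
        if self.fixed_wall:
            t = None
        if t is None:
            b = float(self.body_scales.mean())
            g = float(self.laa_scales.mean())
        else:
            b, g = self.body_scale(t), self.laa_scale(t)
        return self.shape.laa_interior(points, body_scale=b, laa_scale=g)

    def chamber_mask(self, points: np.ndarray, t: float) -> np.ndarray:
        if self.fixed_wall:
            t = None
        if t is None:
            b = float(self.body_scales.mean())
            g = float(self.laa_scales.mean())
        else:
            b, g = self.body_scale(t), self.laa_scale(t)
        return self.shape.contains(points, body_scale=b, laa_scale=g)

    @property
    def mitral(self) -> InletGeometry:
        tube = self.shape.mitral_tube
        return InletGeometry(center=self.shape.center + tube.length * tube.axis,
                             normal=tube.axis.copy(), area=tube.cap_area,
                             radius=tube.cap_radius)

    def as_fixed_wall(self) -> "SyntheticCase":
        """Fixed-wall variant: walls frozen at the Fourier zero mode, A wave
        removed from the transmitral flow, PV inflow rebalanced (Q_PV = Q_MV)."""
        frozen = self.model.frozen()
        wf_fixed = make_transmitral_waveform(self.params, fixed_wall=True)
        waveforms = kinematics.pv_flow_balance(
            frozen, wf_fixed.q_mv, inlets=self.waveforms.inlets,
            annotations=wf_fixed.annotations)
        return replace(self, model=frozen, waveforms=waveforms, fixed_wall=True)


def _build_shape(params: AnatomyParams, rng: np.random.Generator) -> ChamberShape:
    j = params.anatomy_jitter

    def jit(scale=1.0):
        return 1.0 + j * scale * rng.uniform(-1.0, 1.0)

    semi = np.array(params.semi_axes) * np.array([jit(), jit(), jit()])
    laa_axis = np.array([0.97, 0.0, -0.24])
    laa_axis = laa_axis + j * rng.uniform(-0.25, 0.25, size=3)
    laa = geometry.default_laa_tubes(
        orifice_diameter=params.laa_orifice * jit(0.5),
        length=params.laa_length * jit(0.5),
        taper=params.laa_taper, lobes=params.laa_lobes, main_axis=laa_axis)
    mitral = Tube(axis=np.array([0.0, 0.0, -1.0]), radius=params.mitral_radius,
                  length=params.mitral_length, tag=geometry.BODY,
                  cap_tag=geometry.MITRAL)
    return ChamberShape(center=np.zeros(3), semi_axes=semi,
                        pv_tubes=geometry.default_pv_tubes(
                            params.pv_radius * jit(0.5), params.pv_length),
                        mitral_tube=mitral, laa_tubes=laa)


def _chamber_volume(shape: ChamberShape, template: SphereTemplate,
                    beta: float, gamma: float, include_laa: bool = True) -> float:
    r, _, _ = shape.radius_field(template.vertex_dirs, body_scale=beta,
                                 laa_scale=gamma, include_laa=include_laa)
    verts = shape.center + r[:, None] * template.vertex_dirs
    return kinematics._signed_volume(verts, template.faces)


def _measured_laa_volume(shape: ChamberShape, template: SphereTemplate,
                         laa_faces: np.ndarray, beta: float, gamma: float) -> float:
    r, _, _ = shape.radius_field(template.vertex_dirs, body_scale=beta,
                                 laa_scale=gamma, include_laa=True)
    verts = shape.center + r[:, None] * template.vertex_dirs
    return kinematics._laa_subsurface_volume(verts, template.faces, laa_faces)


def _solve_scales(shape: ChamberShape, template: SphereTemplate,
                  laa_faces: np.ndarray | None,
                  v_target: float, v_laa_target: float | None,
                  beta0: float = 1.0) -> tuple[float, float]:
    """Find (beta, gamma) so the meshed total and appendage volumes match the
    targets.  The appendage volume is measured exactly as the kinematics
    module measures it (tagged patch closed by orifice caps), so requested and
    recovered LAA indices agree by construction.  The two scales interact only
    weakly (the orifice shifts with the body), so a few rounds of alternating
    1-D Brent solves converge far below the 1% contract."""
    beta, gamma = beta0, 1.0
    for _ in range(3):
        if v_laa_target is not None:
            def laa_vol(g, b=beta):
                return (_measured_laa_volume(shape, template, laa_faces, b, g)
                        - v_laa_target)
            try:
                gamma = brentq(laa_vol, 0.2, 1.6, xtol=1e-10)
            except ValueError as exc:
                raise ParameterError(
                    "appendage EF target infeasible for this geometry") from exc

        def tot(b, g=gamma):
            return _chamber_volume(shape, template, b, g, True) - v_target
        try:
            beta = brentq(tot, 0.3, 2.5, xtol=1e-12)
        except ValueError as exc:
            raise ParameterError(
                "volume target out of reach for this geometry") from exc
    return beta, gamma


def generate_case(params: AnatomyParams) -> SyntheticCase:
    """Generate a synthetic moving-atrium case realizing the requested targets.

    Deterministic given ``params`` (the seed drives the anatomical jitter).
    Raises :class:`ParameterError` for infeasible targets and ``RuntimeError``
    if a generated frame fails the closed-manifold check.
    """
    rng = np.random.default_rng(params.seed)
    shape = _build_shape(params, rng)
    template = SphereTemplate.for_budget(params.triangle_budget)

    m = params.n_phases
    times = np.arange(m) * params.period / m
    v_of_t = volume_waveform(params)
    v_target = np.asarray(v_of_t(times))

    # appendage volume target: same phase as the chamber, scaled to LAA EF
    if params.global_ef > 0:
        phase = (params.v_max - v_target) / (params.v_max - params.v_min)
    else:
        phase = np.zeros(m)
    face_tags = shape.face_tags(template)
    laa_faces = np.flatnonzero(face_tags == geometry.LAA)
    v_laa_ref = _measured_laa_volume(shape, template, laa_faces, 1.0, 1.0)
    v_laa_target = v_laa_ref * (1.0 - params.laa_ef * phase)

    betas = np.empty(m)
    gammas = np.empty(m)
    frames = np.empty((m, len(template.vertex_dirs), 3))
    beta0 = 1.0
    for i in range(m):
        betas[i], gammas[i] = _solve_scales(
            shape, template, laa_faces, float(v_target[i]),
            float(v_laa_target[i]) if params.laa_ef > 0 else None, beta0=beta0)
        beta0 = betas[i]
        mesh = shape.mesh(template, body_scale=betas[i], laa_scale=gammas[i])
        if not mesh.is_watertight:
            raise RuntimeError(f"generated frame {i} is not watertight")
        if abs(mesh.volume - v_target[i]) > 0.01 * v_target[i]:
            raise RuntimeError(f"frame {i} volume misses prescription by >1%")
        frames[i] = mesh.vertices

    model = kinematics.fit_fourier_model(
        frames, n_modes=kinematics.N_FOU_DEFAULT, period=params.period,
        faces=template.faces, face_tags=face_tags)

    wf_mv = make_transmitral_waveform(params, fixed_wall=False)
    inlets = tuple(
        InletGeometry(center=shape.center + t.length * t.axis,
                      normal=-t.axis, area=t.cap_area, radius=t.cap_radius)
        for t in shape.pv_tubes)
    waveforms = kinematics.pv_flow_balance(model, wf_mv.q_mv, inlets=inlets,
                                           annotations=wf_mv.annotations)

    return SyntheticCase(params=params, shape=shape, template=template,
                         frames=frames, model=model, waveforms=waveforms,
                         face_tags=face_tags, body_scales=betas,
                         laa_scales=gammas, v_target=v_target,
                         index_targets=params.index_targets())
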