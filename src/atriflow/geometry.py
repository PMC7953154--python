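"""Star-shaped parametric chamber geometry.

The synthetic left atrium is modelled as a *star-shaped* surface about a fixed
center: an ellipsoidal body, four cylindrical pulmonary-vein (PV) stubs, one
mitral-annulus stub, and one or more tapered appendage (LAA) tubes.  Every
primitive is expressed as a radius field ``r(omega)`` over unit directions
``omega``; the chamber radius is the pointwise maximum.  Meshing the field over
a fixed icosphere template yields closed, consistently oriented, corresponded
triangulations at every phase of the cycle, with flat end caps that serve as
the PV inlet planes and the mitral plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

# face region tags
BODY = 0
LAA = 1
MITRAL = 2
PV_BASE = 3  # PV i has tag PV_BASE + i, i = 0..3


@dataclass(frozen=True)
class Tube:
    """Cylindrical (optionally tapered) stub protruding radially from the center.

    ``axis`` points outward; ``length`` is the distance from the chamber center
    to the flat end cap; ``radius`` is the tube radius at the center, linearly
    tapering to ``radius * (1 - taper)`` at the cap.
    """

    axis: np.ndarray          # unit outward direction
    radius: float             # cm
    length: float             # cm, center -> cap plane
    taper: float = 0.0        # 0 => cylinder; 0.5 => half radius at cap
    tag: int = BODY
    cap_tag: int | None = None  # tag for cap faces; None => same as tag

    def __post_init__(self):
        a = np.asarray(self.axis, dtype=float)
        a = a / np.linalg.norm(a)
        object.__setattr__(self, "axis", a)
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("tube radius and length must be positive")
        if not (0.0 <= self.taper < 1.0):
            raise ValueError("taper must lie in [0, 1)")

    @property
    def cap_radius(self) -> float:
        return self.radius * (1.0 - self.taper)

    @property
    def cap_area(self) -> float:
        return float(np.pi * self.cap_radius**2)

    def ray_radius(self, dirs: np.ndarray, scale: float = 1.0):
        """Distance along each unit direction to the tube surface (0 if missed).

        Returns ``(r, is_cap)``.  ``scale`` multiplies the tube radius
        (used for appendage contraction); the cap plane stays fixed.
        """
        a0 = self.radius * scale
        cos = dirs @ self.axis
        sin = np.sqrt(np.maximum(1.0 - cos**2, 0.0))
        r = np.zeros(len(dirs))
        is_cap = np.zeros(len(dirs), dtype=bool)
        fwd = cos > 1e-12
        # cap hit: t = L/cos, valid while the hit point lies within the cap disk
        with np.errstate(divide="ignore", invalid="ignore"):
            t_cap = np.where(fwd, self.length / np.maximum(cos, 1e-300), 0.0)
            cap_ok = fwd & (t_cap * sin <= a0 * (1.0 - self.taper) + 1e-12)
            # frustum side: t*sin = a0*(1 - taper*t*cos/L)
            denom = sin + a0 * self.taper * cos / self.length
            t_side = np.where(fwd & (denom > 1e-12), a0 / np.maximum(denom, 1e-300), 0.0)
            side_ok = fwd & ~cap_ok & (t_side * cos <= self.length + 1e-12)
        r[cap_ok] = t_cap[cap_ok]
        r[side_ok] = t_side[side_ok]
        is_cap[cap_ok] = True
        return r, is_cap


@dataclass(frozen=True)
class ChamberShape:
    """Complete star-shaped chamber: body + tubes, with per-phase scale factors."""

    center: np.ndarray                 # cm
    semi_axes: np.ndarray              # body ellipsoid semi-axes (cm)
    pv_tubes: tuple[Tube, ...]
    mitral_tube: Tube
    laa_tubes: tuple[Tube, ...]        # first tube is the main lobe

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "semi_axes", np.asarray(self.semi_axes, dtype=float))
        if np.any(self.semi_axes <= 0):
            raise ValueError("semi-axes must be positive")

    # -- radius fields ------------------------------------------------------

    def _body_radius(self, dirs: np.ndarray, body_scale: float) -> np.ndarray:
        ax = self.semi_axes * body_scale
        return 1.0 / np.sqrt(np.sum((dirs / ax) ** 2, axis=1))

    def radius_field(self, dirs: np.ndarray, body_scale: float = 1.0,
                     laa_scale: float = 1.0, include_laa: bool = True):
        """Radius and winning-primitive tag for each unit direction.

        Returns ``(r, tag, is_cap)`` arrays.  Rigid tubes (PV, mitral) are not
        scaled, so inlet planes and buffers stay fixed while the body and the
        appendage move.
        """
        dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
        r = self._body_radius(dirs, body_scale)
        tag = np.full(len(dirs), BODY, dtype=np.int32)
        is_cap = np.zeros(len(dirs), dtype=bool)
        tubes: list[tuple[Tube, float]] = [(t, 1.0) for t in (*self.pv_tubes, self.mitral_tube)]
        if include_laa:
            tubes += [(t, laa_scale) for t in self.laa_tubes]
        for tube, scale in tubes:
            rt, cap = tube.ray_radius(dirs, scale=scale)
            win = rt > r
            r[win] = rt[win]
            cap_tag = tube.cap_tag if tube.cap_tag is not None else tube.tag
            tag[win] = np.where(cap[win], cap_tag, tube.tag)
            is_cap[win] = cap[win]
        return r, tag, is_cap

    # -- meshing ------------------------------------------------------------

    def mesh(self, template: "SphereTemplate", body_scale: float = 1.0,
             laa_scale: float = 1.0, include_laa: bool = True) -> trimesh.Trimesh:
        r, _, _ = self.radius_field(template.vertex_dirs, body_scale, laa_scale,
                                    include_laa=include_laa)
        verts = self.center + r[:, None] * template.vertex_dirs
        return trimesh.Trimesh(vertices=verts, faces=template.faces, process=False)

    def face_tags(self, template: "SphereTemplate") -> np.ndarray:
        """Region tag per face, evaluated at the reference (unit-scale) shape."""
        _, tag, _ = self.radius_field(template.face_dirs, 1.0, 1.0)
        return tag

    # -- interior tests ------------------------------------------------------

    def contains(self, points: np.ndarray, body_scale: float = 1.0,
                 laa_scale: float = 1.0, include_laa: bool = True) -> np.ndarray:
        p = np.atleast_2d(points) - self.center
        d = np.linalg.norm(p, axis=1)
        safe = np.maximum(d, 1e-12)
        dirs = p / safe[:, None]
        r, _, _ = self.radius_field(dirs, body_scale, laa_scale, include_laa=include_laa)
        return d < r

    def laa_interior(self, points: np.ndarray, body_scale: float = 1.0,
                     laa_scale: float = 1.0) -> np.ndarray:
        """Points inside the chamber that belong to the appendage.

        The appendage interior is the set that is inside the full chamber but
        outside the chamber-without-LAA — i.e. the volume the LAA tubes add
        beyond the body.  This realizes the orifice plane implicitly as the
        surface where the appendage protrudes from the body.
        """
        inside = self.contains(points, body_scale, laa_scale, include_laa=True)
        without = self.contains(points, body_scale, laa_scale, include_laa=False)
        return inside & ~without


class SphereTemplate:
    """Fixed icosphere connectivity shared by all frames (correspondence)."""

    def __init__(self, subdivisions: int = 4):
        ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
        self.vertex_dirs = np.asarray(ico.vertices, dtype=float)
        self.vertex_dirs /= np.linalg.norm(self.vertex_dirs, axis=1)[:, None]
        self.faces = np.asarray(ico.faces, dtype=np.int64)
        fd = self.vertex_dirs[self.faces].mean(axis=1)
        self.face_dirs = fd / np.linalg.norm(fd, axis=1)[:, None]

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @classmethod
    def for_budget(cls, triangle_budget: int) -> "SphereTemplate":
        """Smallest icosphere with at least ``triangle_budget`` faces (max subdiv 5)."""
        if triangle_budget < 1:
            raise ValueError("triangle budget must be >= 1")
        sub = 1
        while 20 * 4**sub < triangle_budget and sub < 5:
            sub += 1
        return cls(subdivisions=sub)


def default_pv_tubes(radius: float = 0.75, length: float = 4.6) -> tuple[Tube, ...]:
    """Four PV stubs on the upper-posterior chamber, split left/right pairs."""
    dirs = np.array([
        [+0.62, +0.45, +0.65],
        [+0.62, -0.45, +0.65],
        [-0.62, +0.45, +0.65],
        [-0.62, -0.45, +0.65],
    ])
    return tuple(
        Tube(axis=d, radius=radius, length=length, tag=BODY, cap_tag=PV_BASE + i)
        for i, d in enumerate(dirs)
    )


def default_laa_tubes(orifice_diameter: float = 2.0, length: float = 5.6,
                      taper: float = 0.45, lobes: int = 1,
                      main_axis=(0.87, 0.38, -0.31)) -> tuple[Tube, ...]:
    """Main appendage lobe plus ``lobes - 1`` shorter secondary lobes.

    ``length`` is measured from the chamber center, so the protrusion beyond a
    ~3 cm body is ~2.5 cm, inside the 1.7–3.7 cm range seen in patients.
    Secondary lobes are tilted ~24 deg off the main axis at staggered azimuths,
    with 80% of the main length — enough separation for the skeleton branch
    graph to resolve them as distinct branches.
    """
    if lobes < 1:
        raise ValueError("lobe count must be >= 1")
    main = np.asarray(main_axis, dtype=float)
    main /= np.linalg.norm(main)
    tubes = [Tube(axis=main, radius=orifice_diameter / 2.0, length=length,
                  taper=taper, tag=LAA)]
    # orthonormal frame around the main axis
    ref = np.array([0.0, 0.0, 1.0])
    if abs(main @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(main, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(main, e1)
    tilt = np.deg2rad(24.0)
    for k in range(lobes - 1):
        phi = 2.0 * np.pi * k / max(lobes - 1, 1)
        ax = np.cos(tilt) * main + np.sin(tilt) * (np.cos(phi) * e1 + np.sin(phi) * e2)
        tubes.append(Tube(axis=ax, radius=0.55 * orifice_diameter / 2.0,
                          length=0.8 * length, taper=taper, tag=LAA))
    return tuple(tubes)


def default_chamber(center=(0.0, 0.0, 0.0), semi_axes=(3.1, 2.7, 2.3),
                    pv_radius: float = 0.75, pv_length: float = 4.6,
                    mitral_radius: float = 1.35, mitral_length: float = 3.4,
                    laa_orifice: float = 2.0, laa_length: float = 5.6,
                    laa_taper: float = 0.45, laa_lobes: int = 1) -> ChamberShape:
    mitral = Tube(axis=np.array([0.0, 0.0, -1.0]), radius=mitral_radius,
                  length=mitral_length, tag=BODY, cap_tag=MITRAL)
    return ChamberShape(
        center=np.asarray(center, dtype=float),
        semi_axes=np.asarray(semi_axes, dtype=float),
        pv_tubes=default_pv_tubes(pv_radius, pv_length),
        mitral_tube=mitral,
        laa_tubes=default_laa_tubes(laa_orifice, laa_length, laa_taper, laa_lobes),
    )
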