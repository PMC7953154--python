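"""Numba kernels for immersed-boundary interpolation and spreading.

The regularized delta function is the 3-point compact kernel of Roma, Peskin &
Berger, with support 3 grid cells per direction.  It satisfies the discrete
partition of unity and first-moment conditions, so spreading a marker force
onto the grid conserves the total force exactly and interpolation is
second-order for smooth fields.
"""

import numba
import numpy as np


@numba.njit(cache=True, inline="always")
def _delta3(r):
    """Roma-Peskin 3-point kernel, evaluated at signed offset r (grid units)."""
    a = abs(r)
    if a <= 0.5:
        return (1.0 + np.sqrt(1.0 - 3.0 * r * r)) / 3.0
    if a <= 1.5:
        return (5.0 - 3.0 * a - np.sqrt(1.0 - 3.0 * (1.0 - a) ** 2)) / 6.0
    return 0.0


@numba.njit(cache=True)
def interp3(field, pos, origin, offset, dx):
    """Interpolate a staggered ``field`` at marker positions.

    ``offset`` gives the staggering of the field's sample points in grid
    units: node p of axis d sits at ``origin[d] + (p + offset[d]) * dx``.
    """
    m = pos.shape[0]
    out = np.zeros(m)
    for q in range(m):
        acc = 0.0
        # grid-unit coordinates of the marker in this field's node numbering
        gx = (pos[q, 0] - origin[0]) / dx - offset[0]
        gy = (pos[q, 1] - origin[1]) / dx - offset[1]
        gz = (pos[q, 2] - origin[2]) / dx - offset[2]
        ix = int(np.floor(gx + 0.5)) - 1
        iy = int(np.floor(gy + 0.5)) - 1
        iz = int(np.floor(gz + 0.5)) - 1
        for a in range(3):
            wa = _delta3(gx - (ix + a))
            if wa == 0.0:
                continue
            for b in range(3):
                wb = wa * _delta3(gy - (iy + b))
                if wb == 0.0:
                    continue
                for c in range(3):
                    wc = wb * _delta3(gz - (iz + c))
                    if wc != 0.0:
                        acc += wc * field[ix + a, iy + b, iz + c]
        out[q] = acc
    return out


@numba.njit(cache=True)
def spread3(field, pos, values, origin, offset, dx):
    """Spread marker ``values`` (already volume-weighted, grid units) onto the
    staggered ``field`` in place with the same kernel as :func:`interp3`."""
    m = pos.shape[0]
    for q in range(m):
        gx = (pos[q, 0] - origin[0]) / dx - offset[0]
        gy = (pos[q, 1] - origin[1]) / dx - offset[1]
        gz = (pos[q, 2] - origin[2]) / dx - offset[2]
        ix = int(np.floor(gx + 0.5)) - 1
        iy = int(np.floor(gy + 0.5)) - 1
        iz = int(np.floor(gz + 0.5)) - 1
        val = values[q]
        for a in range(3):
            wa = _delta3(gx - (ix + a))
            if wa == 0.0:
                continue
            for b in range(3):
                wb = wa * _delta3(gy - (iy + b))
                if wb == 0.0:
                    continue
                for c in range(3):
                    wc = wb * _delta3(gz - (iz + c))
                    if wc != 0.0:
                        field[ix + a, iy + b, iz + c] += wc * val


# ---------------------------------------------------------------------------
# Stencil kernels (momentum advection / Laplacian, WENO3 scalar advection)
# ---------------------------------------------------------------------------

@numba.njit(cache=True)
def advect_lap_axis0(c, a, b, dx):
    """Advection div(u c) and Laplacian for the face component staggered on
    axis 0, with Dirichlet (zero) boundary faces on its own axis and
    mirror-Neumann tangential ghosts.  ``a``/``b`` are the transverse
    components staggered on axes 1/2."""
    n1, m, l = c.shape
    n = n1 - 1
    adv = np.zeros_like(c)
    lap = np.zeros_like(c)
    dx2 = dx * dx
    for i in range(1, n):
        for j in range(m):
            jp = j + 1 if j + 1 < m else j
            jm = j - 1 if j > 0 else 0
            for k in range(l):
                kp = k + 1 if k + 1 < l else k
                km = k - 1 if k > 0 else 0
                cc = c[i, j, k]
                # d(cc)/d0
                ccp = 0.25 * (cc + c[i + 1, j, k]) ** 2
                ccm = 0.25 * (c[i - 1, j, k] + cc) ** 2
                acc = (ccp - ccm) / dx
                # d(ca)/d1
                ce_p = 0.5 * (cc + c[i, jp, k])
                ae_p = 0.5 * (a[i - 1, j + 1, k] + a[i, j + 1, k])
                ce_m = 0.5 * (c[i, jm, k] + cc)
                ae_m = 0.5 * (a[i - 1, j, k] + a[i, j, k])
                acc += (ce_p * ae_p - ce_m * ae_m) / dx
                # d(cb)/d2
                ce_p = 0.5 * (cc + c[i, j, kp])
                be_p = 0.5 * (b[i - 1, j, k + 1] + b[i, j, k + 1])
                ce_m = 0.5 * (c[i, j, km] + cc)
                be_m = 0.5 * (b[i - 1, j, k] + b[i, j, k])
                acc += (ce_p * be_p - ce_m * be_m) / dx
                adv[i, j, k] = acc
                lap[i, j, k] = ((c[i + 1, j, k] - 2.0 * cc + c[i - 1, j, k])
                                + (c[i, jp, k] - 2.0 * cc + c[i, jm, k])
                                + (c[i, j, kp] - 2.0 * cc + c[i, j, km])) / dx2
    return adv, lap


@numba.njit(cache=True, inline="always")
def _weno_face(qm, q0, qp, qpp, up):
    """WENO3 face value between cells with averages (qm,q0 | qp,qpp);
    ``up`` True biases left (velocity >= 0)."""
    eps = 1e-6
    if up:
        c0 = 1.5 * q0 - 0.5 * qm
        c1 = 0.5 * (q0 + qp)
        b0 = (q0 - qm) ** 2
        b1 = (qp - q0) ** 2
    else:
        c0 = 1.5 * qp - 0.5 * qpp
        c1 = 0.5 * (q0 + qp)
        b0 = (qp - qpp) ** 2
        b1 = (q0 - qp) ** 2
    w0 = (1.0 / 3.0) / (eps + b0) ** 2
    w1 = (2.0 / 3.0) / (eps + b1) ** 2
    return (w0 * c0 + w1 * c1) / (w0 + w1)


@numba.njit(cache=True)
def weno_advection_axis0(q, uf, fo, use_fo, dx, out):
    """Add the axis-0 part of v.grad(q): conservative WENO3 flux difference
    minus q times the axis-0 dilatation.  ``uf`` holds the axis-0 face
    velocities (n+1 faces); edge stencils clamp (first-order); ``fo`` marks
    cells where the reconstruction degrades to first-order upwinding."""
    n, m, l = q.shape
    for j in range(m):
        for k in range(l):
            for i in range(n):
                # face i (lower) and i+1 (upper)
                fm = 0.0
                um = uf[i, j, k]
                if i > 0 and um != 0.0:
                    i0 = i - 1
                    qm = q[i0 - 1, j, k] if i0 > 0 else q[i0, j, k]
                    qpp = q[i + 1, j, k] if i + 1 < n else q[i, j, k]
                    if use_fo and (fo[i0, j, k] or fo[i, j, k]):
                        fv = q[i0, j, k] if um >= 0.0 else q[i, j, k]
                    else:
                        fv = _weno_face(qm, q[i0, j, k], q[i, j, k], qpp,
                                        um >= 0.0)
                    fm = um * fv
                fp = 0.0
                up = uf[i + 1, j, k]
                if i + 1 < n and up != 0.0:
                    qm = q[i - 1, j, k] if i > 0 else q[i, j, k]
                    qpp = q[i + 2, j, k] if i + 2 < n else q[i + 1, j, k]
                    if use_fo and (fo[i, j, k] or fo[i + 1, j, k]):
                        fv = q[i, j, k] if up >= 0.0 else q[i + 1, j, k]
                    else:
                        fv = _weno_face(qm, q[i, j, k], q[i + 1, j, k], qpp,
                                        up >= 0.0)
                    fp = up * fv
                out[i, j, k] += (fp - fm) / dx - q[i, j, k] * (up - um) / dx
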