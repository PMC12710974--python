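"""Numba Gauss-Seidel kernels for the XPBD constraint solver.

All kernels are sequential and allocation-free in the inner loops, which
makes runs bit-reproducible on a single thread.  Positions are modified in
place.  Units are internal solver units: mm, mg, s (1 Pa = 1e3 mg/(mm s^2)).

Constraint conventions (see :mod:`refold.xpbd` for the surrounding model):

* hydrostatic  C_H = V(x)/V0 - 1 with V0 the *original* rest volume —
  volume memory survives viscoelastic rest-pose relaxation;
* deviatoric   C_D = sqrt(tr(F^T F)), F = Ds * Bm with Bm the (relaxing)
  inverse rest-edge matrix;
* area         C_A = 0.5*||(x2-x1) x (x3-x1)|| - R;
* smoothing    C_S = 0.5*||(a+b)-(s0+s1)|| - L.

Each XPBD projection: dlam = (-C - at*lam) / (sum_i w_i |g_i|^2 + at),
at = alpha/dt^2, then x_i += w_i * dlam * g_i.
"""

import numpy as np
from numba import njit

_EPS = 1e-12


@njit(cache=True)
def project_tets(pos, invm, tets, Bm, restvol, alpha_h, alpha_d,
                 lam_h, lam_d, inv_dt2):
    # Gauss-Seidel across tets, block (Jacobi) update of the hydrostatic +
    # deviatoric pair within a tet: both constraint values and gradients are
    # evaluated at the same positions before either correction is applied.
    # Sequential hydro-then-devia updates bias the fixed point away from the
    # elastic equilibrium by a zig-zag term; the paired update removes it.
    for t in range(tets.shape[0]):
        i0 = tets[t, 0]; i1 = tets[t, 1]; i2 = tets[t, 2]; i3 = tets[t, 3]
        w0 = invm[i0]; w1 = invm[i1]; w2 = invm[i2]; w3 = invm[i3]
        if w0 + w1 + w2 + w3 <= 0.0:
            continue

        d1x = pos[i1, 0] - pos[i0, 0]; d1y = pos[i1, 1] - pos[i0, 1]; d1z = pos[i1, 2] - pos[i0, 2]
        d2x = pos[i2, 0] - pos[i0, 0]; d2y = pos[i2, 1] - pos[i0, 1]; d2z = pos[i2, 2] - pos[i0, 2]
        d3x = pos[i3, 0] - pos[i0, 0]; d3y = pos[i3, 1] - pos[i0, 1]; d3z = pos[i3, 2] - pos[i0, 2]

        # ---- hydrostatic: C = V/V0 - 1 --------------------------------
        v0 = restvol[t]
        s = 1.0 / (6.0 * v0)
        # grad(det) columns: d2 x d3, d3 x d1, d1 x d2
        h1x = (d2y * d3z - d2z * d3y) * s
        h1y = (d2z * d3x - d2x * d3z) * s
        h1z = (d2x * d3y - d2y * d3x) * s
        h2x = (d3y * d1z - d3z * d1y) * s
        h2y = (d3z * d1x - d3x * d1z) * s
        h2z = (d3x * d1y - d3y * d1x) * s
        h3x = (d1y * d2z - d1z * d2y) * s
        h3y = (d1z * d2x - d1x * d2z) * s
        h3z = (d1x * d2y - d1y * d2x) * s
        h0x = -(h1x + h2x + h3x); h0y = -(h1y + h2y + h3y); h0z = -(h1z + h2z + h3z)
        det = d1x * (d2y * d3z - d2z * d3y) - d1y * (d2x * d3z - d2z * d3x) \
            + d1z * (d2x * d3y - d2y * d3x)
        Ch = det * s - 1.0
        at_h = alpha_h[t] * inv_dt2
        denom_h = (w0 * (h0x * h0x + h0y * h0y + h0z * h0z)
                   + w1 * (h1x * h1x + h1y * h1y + h1z * h1z)
                   + w2 * (h2x * h2x + h2y * h2y + h2z * h2z)
                   + w3 * (h3x * h3x + h3y * h3y + h3z * h3z) + at_h)
        dlam_h = 0.0
        if denom_h > _EPS:
            dlam_h = (-Ch - at_h * lam_h[t]) / denom_h
            lam_h[t] += dlam_h

        # ---- deviatoric: C = ||F||_F, same positions ------------------
        dlam_d = 0.0
        g0x = g0y = g0z = g1x = g1y = g1z = 0.0
        g2x = g2y = g2z = g3x = g3y = g3z = 0.0
        if alpha_d[t] >= 0.0:
            b00 = Bm[t, 0, 0]; b01 = Bm[t, 0, 1]; b02 = Bm[t, 0, 2]
            b10 = Bm[t, 1, 0]; b11 = Bm[t, 1, 1]; b12 = Bm[t, 1, 2]
            b20 = Bm[t, 2, 0]; b21 = Bm[t, 2, 1]; b22 = Bm[t, 2, 2]
            # F = Ds @ Bm, Ds columns d1,d2,d3
            f00 = d1x * b00 + d2x * b10 + d3x * b20
            f01 = d1x * b01 + d2x * b11 + d3x * b21
            f02 = d1x * b02 + d2x * b12 + d3x * b22
            f10 = d1y * b00 + d2y * b10 + d3y * b20
            f11 = d1y * b01 + d2y * b11 + d3y * b21
            f12 = d1y * b02 + d2y * b12 + d3y * b22
            f20 = d1z * b00 + d2z * b10 + d3z * b20
            f21 = d1z * b01 + d2z * b11 + d3z * b21
            f22 = d1z * b02 + d2z * b12 + d3z * b22
            tr = (f00 * f00 + f01 * f01 + f02 * f02
                  + f10 * f10 + f11 * f11 + f12 * f12
                  + f20 * f20 + f21 * f21 + f22 * f22)
            Cd = np.sqrt(tr)
            if Cd > _EPS:
                inv_cd = 1.0 / Cd
                # grad wrt Ds columns: (F @ Bm^T) columns / Cd
                g1x = (f00 * b00 + f01 * b01 + f02 * b02) * inv_cd
                g1y = (f10 * b00 + f11 * b01 + f12 * b02) * inv_cd
                g1z = (f20 * b00 + f21 * b01 + f22 * b02) * inv_cd
                g2x = (f00 * b10 + f01 * b11 + f02 * b12) * inv_cd
                g2y = (f10 * b10 + f11 * b11 + f12 * b12) * inv_cd
                g2z = (f20 * b10 + f21 * b11 + f22 * b12) * inv_cd
                g3x = (f00 * b20 + f01 * b21 + f02 * b22) * inv_cd
                g3y = (f10 * b20 + f11 * b21 + f12 * b22) * inv_cd
                g3z = (f20 * b20 + f21 * b21 + f22 * b22) * inv_cd
                g0x = -(g1x + g2x + g3x); g0y = -(g1y + g2y + g3y); g0z = -(g1z + g2z + g3z)
                at_d = alpha_d[t] * inv_dt2
                denom_d = (w0 * (g0x * g0x + g0y * g0y + g0z * g0z)
                           + w1 * (g1x * g1x + g1y * g1y + g1z * g1z)
                           + w2 * (g2x * g2x + g2y * g2y + g2z * g2z)
                           + w3 * (g3x * g3x + g3y * g3y + g3z * g3z) + at_d)
                if denom_d > _EPS:
                    dlam_d = (-Cd - at_d * lam_d[t]) / denom_d
                    lam_d[t] += dlam_d

        pos[i0, 0] += w0 * (dlam_h * h0x + dlam_d * g0x)
        pos[i0, 1] += w0 * (dlam_h * h0y + dlam_d * g0y)
        pos[i0, 2] += w0 * (dlam_h * h0z + dlam_d * g0z)
        pos[i1, 0] += w1 * (dlam_h * h1x + dlam_d * g1x)
        pos[i1, 1] += w1 * (dlam_h * h1y + dlam_d * g1y)
        pos[i1, 2] += w1 * (dlam_h * h1z + dlam_d * g1z)
        pos[i2, 0] += w2 * (dlam_h * h2x + dlam_d * g2x)
        pos[i2, 1] += w2 * (dlam_h * h2y + dlam_d * g2y)
        pos[i2, 2] += w2 * (dlam_h * h2z + dlam_d * g2z)
        pos[i3, 0] += w3 * (dlam_h * h3x + dlam_d * g3x)
        pos[i3, 1] += w3 * (dlam_h * h3y + dlam_d * g3y)
        pos[i3, 2] += w3 * (dlam_h * h3z + dlam_d * g3z)


@njit(cache=True)
def project_areas(pos, invm, faces, restA, alpha_a, lam_a, inv_dt2):
    for f in range(faces.shape[0]):
        i1 = faces[f, 0]; i2 = faces[f, 1]; i3 = faces[f, 2]
        w1 = invm[i1]; w2 = invm[i2]; w3 = invm[i3]
        if w1 + w2 + w3 <= 0.0:
            continue
        e1x = pos[i2, 0] - pos[i1, 0]; e1y = pos[i2, 1] - pos[i1, 1]; e1z = pos[i2, 2] - pos[i1, 2]
        e2x = pos[i3, 0] - pos[i1, 0]; e2y = pos[i3, 1] - pos[i1, 1]; e2z = pos[i3, 2] - pos[i1, 2]
        nx = e1y * e2z - e1z * e2y
        ny = e1z * e2x - e1x * e2z
        nz = e1x * e2y - e1y * e2x
        nn = np.sqrt(nx * nx + ny * ny + nz * nz)
        if nn < _EPS:  # degenerate face
            continue
        C = 0.5 * nn - restA[f]
        ux = nx / nn; uy = ny / nn; uz = nz / nn
        # grad area: 0.5 * u x (edge opposite the vertex)
        # x1: opposite edge x3->x2 => 0.5 * u x (x3 - x2) ... signs verified
        ax = pos[i3, 0] - pos[i2, 0]; ay = pos[i3, 1] - pos[i2, 1]; az = pos[i3, 2] - pos[i2, 2]
        g1x = 0.5 * (uy * az - uz * ay)
        g1y = 0.5 * (uz * ax - ux * az)
        g1z = 0.5 * (ux * ay - uy * ax)
        bx = pos[i1, 0] - pos[i3, 0]; by = pos[i1, 1] - pos[i3, 1]; bz = pos[i1, 2] - pos[i3, 2]
        g2x = 0.5 * (uy * bz - uz * by)
        g2y = 0.5 * (uz * bx - ux * bz)
        g2z = 0.5 * (ux * by - uy * bx)
        cx = pos[i2, 0] - pos[i1, 0]; cy = pos[i2, 1] - pos[i1, 1]; cz = pos[i2, 2] - pos[i1, 2]
        g3x = 0.5 * (uy * cz - uz * cy)
        g3y = 0.5 * (uz * cx - ux * cz)
        g3z = 0.5 * (ux * cy - uy * cx)
        at = alpha_a[f] * inv_dt2
        denom = (w1 * (g1x * g1x + g1y * g1y + g1z * g1z)
                 + w2 * (g2x * g2x + g2y * g2y + g2z * g2z)
                 + w3 * (g3x * g3x + g3y * g3y + g3z * g3z) + at)
        if denom > _EPS:
            dlam = (-C - at * lam_a[f]) / denom
            lam_a[f] += dlam
            pos[i1, 0] += w1 * dlam * g1x; pos[i1, 1] += w1 * dlam * g1y; pos[i1, 2] += w1 * dlam * g1z
            pos[i2, 0] += w2 * dlam * g2x; pos[i2, 1] += w2 * dlam * g2y; pos[i2, 2] += w2 * dlam * g2z
            pos[i3, 0] += w3 * dlam * g3x; pos[i3, 1] += w3 * dlam * g3y; pos[i3, 2] += w3 * dlam * g3z


@njit(cache=True)
def project_smoothing(pos, invm, quads, restL, alpha_s, lam_s, inv_dt2):
    # quads rows: (s0, s1, a, b)
    for q in range(quads.shape[0]):
        s0 = quads[q, 0]; s1 = quads[q, 1]; ia = quads[q, 2]; ib = quads[q, 3]
        w0 = invm[s0]; w1 = invm[s1]; wa = invm[ia]; wb = invm[ib]
        if w0 + w1 + wa + wb <= 0.0:
            continue
        dx = (pos[ia, 0] + pos[ib, 0]) - (pos[s0, 0] + pos[s1, 0])
        dy = (pos[ia, 1] + pos[ib, 1]) - (pos[s0, 1] + pos[s1, 1])
        dz = (pos[ia, 2] + pos[ib, 2]) - (pos[s0, 2] + pos[s1, 2])
        dn = np.sqrt(dx * dx + dy * dy + dz * dz)
        if dn < _EPS:  # coincident midpoints: gradient undefined
            continue
        C = 0.5 * dn - restL[q]
        ux = 0.5 * dx / dn; uy = 0.5 * dy / dn; uz = 0.5 * dz / dn
        # grads: a,b -> +u ; s0,s1 -> -u
        at = alpha_s[q] * inv_dt2
        gg = ux * ux + uy * uy + uz * uz
        denom = (wa + wb + w0 + w1) * gg + at
        if denom > _EPS:
            dlam = (-C - at * lam_s[q]) / denom
            lam_s[q] += dlam
            pos[ia, 0] += wa * dlam * ux; pos[ia, 1] += wa * dlam * uy; pos[ia, 2] += wa * dlam * uz
            pos[ib, 0] += wb * dlam * ux; pos[ib, 1] += wb * dlam * uy; pos[ib, 2] += wb * dlam * uz
            pos[s0, 0] -= w0 * dlam * ux; pos[s0, 1] -= w0 * dlam * uy; pos[s0, 2] -= w0 * dlam * uz
            pos[s1, 0] -= w1 * dlam * ux; pos[s1, 1] -= w1 * dlam * uy; pos[s1, 2] -= w1 * dlam * uz


@njit(cache=True)
def relax_rest_pose(pos, tets, Dm, Bm, kappa):
    """Blend rest-edge matrices toward the current pose: Dm <- (1-k)Dm + k*Ds.

    Bm is refreshed to inv(Dm).  Rest volumes are untouched by design:
    hydrostatic memory is preserved while deviatoric stress relaxes.
    """
    if kappa <= 0.0:
        return
    for t in range(tets.shape[0]):
        i0 = tets[t, 0]; i1 = tets[t, 1]; i2 = tets[t, 2]; i3 = tets[t, 3]
        for c in range(3):
            Dm[t, c, 0] = (1.0 - kappa) * Dm[t, c, 0] + kappa * (pos[tets[t, 1], c] - pos[i0, c])
            Dm[t, c, 1] = (1.0 - kappa) * Dm[t, c, 1] + kappa * (pos[tets[t, 2], c] - pos[i0, c])
            Dm[t, c, 2] = (1.0 - kappa) * Dm[t, c, 2] + kappa * (pos[tets[t, 3], c] - pos[i0, c])
        # invert Dm[t] into Bm[t]
        a = Dm[t, 0, 0]; b = Dm[t, 0, 1]; c_ = Dm[t, 0, 2]
        d = Dm[t, 1, 0]; e = Dm[t, 1, 1]; f = Dm[t, 1, 2]
        g = Dm[t, 2, 0]; h = Dm[t, 2, 1]; i = Dm[t, 2, 2]
        det = a * (e * i - f * h) - b * (d * i - f * g) + c_ * (d * h - e * g)
        if abs(det) < _EPS:
            continue
        inv = 1.0 / det
        Bm[t, 0, 0] = (e * i - f * h) * inv
        Bm[t, 0, 1] = (c_ * h - b * i) * inv
        Bm[t, 0, 2] = (b * f - c_ * e) * inv
        Bm[t, 1, 0] = (f * g - d * i) * inv
        Bm[t, 1, 1] = (a * i - c_ * g) * inv
        Bm[t, 1, 2] = (c_ * d - a * f) * inv
        Bm[t, 2, 0] = (d * h - e * g) * inv
        Bm[t, 2, 1] = (b * g - a * h) * inv
        Bm[t, 2, 2] = (a * e - b * d) * inv


@njit(cache=True)
def residuals(pos, tets, Bm, restvol, faces, restA, quads, restL):
    """Max |C| per family: (hydrostatic, deviatoric sqrt(tr)-sqrt(3), area, smoothing)."""
    rh = 0.0
    rd = 0.0
    for t in range(tets.shape[0]):
        i0 = tets[t, 0]; i1 = tets[t, 1]; i2 = tets[t, 2]; i3 = tets[t, 3]
        d1x = pos[i1, 0] - pos[i0, 0]; d1y = pos[i1, 1] - pos[i0, 1]; d1z = pos[i1, 2] - pos[i0, 2]
        d2x = pos[i2, 0] - pos[i0, 0]; d2y = pos[i2, 1] - pos[i0, 1]; d2z = pos[i2, 2] - pos[i0, 2]
        d3x = pos[i3, 0] - pos[i0, 0]; d3y = pos[i3, 1] - pos[i0, 1]; d3z = pos[i3, 2] - pos[i0, 2]
        det = d1x * (d2y * d3z - d2z * d3y) - d1y * (d2x * d3z - d2z * d3x) \
            + d1z * (d2x * d3y - d2y * d3x)
        c = abs(det / (6.0 * restvol[t]) - 1.0)
        if c > rh:
            rh = c
        f00 = d1x * Bm[t, 0, 0] + d2x * Bm[t, 1, 0] + d3x * Bm[t, 2, 0]
        f01 = d1x * Bm[t, 0, 1] + d2x * Bm[t, 1, 1] + d3x * Bm[t, 2, 1]
        f02 = d1x * Bm[t, 0, 2] + d2x * Bm[t, 1, 2] + d3x * Bm[t, 2, 2]
        f10 = d1y * Bm[t, 0, 0] + d2y * Bm[t, 1, 0] + d3y * Bm[t, 2, 0]
        f11 = d1y * Bm[t, 0, 1] + d2y * Bm[t, 1, 1] + d3y * Bm[t, 2, 1]
        f12 = d1y * Bm[t, 0, 2] + d2y * Bm[t, 1, 2] + d3y * Bm[t, 2, 2]
        f20 = d1z * Bm[t, 0, 0] + d2z * Bm[t, 1, 0] + d3z * Bm[t, 2, 0]
        f21 = d1z * Bm[t, 0, 1] + d2z * Bm[t, 1, 1] + d3z * Bm[t, 2, 1]
        f22 = d1z * Bm[t, 0, 2] + d2z * Bm[t, 1, 2] + d3z * Bm[t, 2, 2]
        tr = (f00 * f00 + f01 * f01 + f02 * f02 + f10 * f10 + f11 * f11
              + f12 * f12 + f20 * f20 + f21 * f21 + f22 * f22)
        c = abs(np.sqrt(tr) - np.sqrt(3.0))
        if c > rd:
            rd = c
    ra = 0.0
    for f in range(faces.shape[0]):
        i1 = faces[f, 0]; i2 = faces[f, 1]; i3 = faces[f, 2]
        e1x = pos[i2, 0] - pos[i1, 0]; e1y = pos[i2, 1] - pos[i1, 1]; e1z = pos[i2, 2] - pos[i1, 2]
        e2x = pos[i3, 0] - pos[i1, 0]; e2y = pos[i3, 1] - pos[i1, 1]; e2z = pos[i3, 2] - pos[i1, 2]
        nx = e1y * e2z - e1z * e2y
        ny = e1z * e2x - e1x * e2z
        nz = e1x * e2y - e1y * e2x
        c = abs(0.5 * np.sqrt(nx * nx + ny * ny + nz * nz) - restA[f])
        if c > ra:
            ra = c
    rs = 0.0
    for q in range(quads.shape[0]):
        s0 = quads[q, 0]; s1 = quads[q, 1]; ia = quads[q, 2]; ib = quads[q, 3]
        dx = (pos[ia, 0] + pos[ib, 0]) - (pos[s0, 0] + pos[s1, 0])
        dy = (pos[ia, 1] + pos[ib, 1]) - (pos[s0, 1] + pos[s1, 1])
        dz = (pos[ia, 2] + pos[ib, 2]) - (pos[s0, 2] + pos[s1, 2])
        c = abs(0.5 * np.sqrt(dx * dx + dy * dy + dz * dz) - restL[q])
        if c > rs:
            rs = c
    return rh, rd, ra, rs
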