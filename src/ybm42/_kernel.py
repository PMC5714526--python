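"""Numba transport kernel: analogue photon random walk with collision-kerma
and track-length estimators.

Geometry is a short stack of coaxial finite cylinders (the seed) inside a
spherical phantom.  Boundaries are handled by exact ray/quadric intersection
with an epsilon nudge; the region of a point is resolved by innermost-first
containment, so the kernel never needs to classify which surface was hit.

Scoring:
- water mode: expected-value collision estimator — at every collision in the
  phantom medium the score is E * mu_en(E)/mu_tot(E), tallied into the
  shell-cone bin (and optionally a cylindrical rho-z mesh) containing the
  collision site;
- air-kerma mode: the phantom is vacuum, so once a photon leaves the seed it
  flies on a straight ray; the track length through the air ring detector is
  integrated numerically and scored as E * (mu_en/rho)_air * l / V_ring.
  Attenuation and re-scatter over the ~5 cm air path (< 0.1 %) are neglected.

All randomness comes from numba's internal np.random state, seeded per batch,
so a fixed seed gives bit-identical results.
"""

import numpy as np
from numba import njit

_EPS = 1e-7
_MAX_STEPS = 100000


@njit(cache=True, inline="always")
def _lookup(table, row, e, loge0, dloge, ngrid):
    x = (np.log(e) - loge0) / dloge
    i = int(x)
    if i < 0:
        i = 0
    if i > ngrid - 2:
        i = ngrid - 2
    f = x - i
    if f < 0.0:
        f = 0.0
    if f > 1.0:
        f = 1.0
    return table[row, i] * (1.0 - f) + table[row, i + 1] * f


@njit(cache=True, inline="always")
def _region(x, y, z, cyl_r2, cyl_zmin, cyl_zmax, cyl_mat, phantom_r2, phantom_mat):
    rho2 = x * x + y * y
    for i in range(cyl_r2.size):
        if rho2 <= cyl_r2[i] and cyl_zmin[i] <= z <= cyl_zmax[i]:
            return cyl_mat[i]
    if rho2 + z * z <= phantom_r2:
        return phantom_mat
    return -2


@njit(cache=True)
def _dist_to_cylinders(x, y, z, dx, dy, dz, cyl_r, cyl_zmin, cyl_zmax):
    """Nearest positive intersection with any finite-cylinder surface (inf if none)."""
    tmin = np.inf
    for i in range(cyl_r.size):
        r = cyl_r[i]
        zl = cyl_zmin[i]
        zh = cyl_zmax[i]
        # lateral surface
        a = dx * dx + dy * dy
        if a > 1e-20:
            b = x * dx + y * dy
            c = x * x + y * y - r * r
            disc = b * b - a * c
            if disc > 0.0:
                sq = np.sqrt(disc)
                for sgn in (-1.0, 1.0):
                    t = (-b + sgn * sq) / a
                    if _EPS < t < tmin:
                        zt = z + t * dz
                        if zl <= zt <= zh:
                            tmin = t
        # end planes
        if abs(dz) > 1e-20:
            for zp in (zl, zh):
                t = (zp - z) / dz
                if _EPS < t < tmin:
                    xt = x + t * dx
                    yt = y + t * dy
                    if xt * xt + yt * yt <= r * r:
                        tmin = t
    return tmin


@njit(cache=True, inline="always")
def _dist_to_sphere(x, y, z, dx, dy, dz, radius):
    b = x * dx + y * dy + z * dz
    c = x * x + y * y + z * z - radius * radius
    disc = b * b - c
    if disc <= 0.0:
        return np.inf
    sq = np.sqrt(disc)
    t = -b - sq
    if t > _EPS:
        return t
    t = -b + sq
    if t > _EPS:
        return t
    return np.inf


@njit(cache=True, inline="always")
def _sample_kn(e):
    """Klein-Nishina angle cosine by rejection (forward envelope = 2)."""
    alpha = e / 510.99895
    while True:
        c = 2.0 * np.random.random() - 1.0
        ratio = 1.0 / (1.0 + alpha * (1.0 - c))
        f = ratio * ratio * (ratio + 1.0 / ratio - (1.0 - c * c))
        if 2.0 * np.random.random() <= f:
            return c


@njit(cache=True, inline="always")
def _sample_thomson():
    while True:
        c = 2.0 * np.random.random() - 1.0
        if np.random.random() <= 0.5 * (1.0 + c * c):
            return c


@njit(cache=True, inline="always")
def _rotate(u, v, w, mu, phi):
    s = np.sqrt(max(0.0, 1.0 - mu * mu))
    cp = np.cos(phi)
    sp = np.sin(phi)
    den2 = 1.0 - w * w
    if den2 > 1e-12:
        den = np.sqrt(den2)
        nu = u * mu + s * (u * w * cp - v * sp) / den
        nv = v * mu + s * (v * w * cp + u * sp) / den
        nw = w * mu - s * den * cp
    else:
        nu = s * cp
        nv = s * sp
        nw = mu if w > 0.0 else -mu
    norm = np.sqrt(nu * nu + nv * nv + nw * nw)
    return nu / norm, nv / norm, nw / norm


@njit(cache=True, inline="always")
def _edge_bin(v, edges):
    k = np.searchsorted(edges, v, side="right")
    if k % 2 == 1:
        return (k - 1) // 2
    if v == edges[-1]:
        return edges.size // 2 - 1
    return -1


@njit(cache=True)
def run_batch(
    n_hist,
    seed,
    # primary source
    core_r,
    core_zmin,
    core_zmax,
    spec_e,
    spec_cdf,
    # geometry
    cyl_r,
    cyl_zmin,
    cyl_zmax,
    cyl_mat,
    phantom_r,
    phantom_mat,
    src_bound_r,
    # physics tables on a uniform log-energy grid
    loge0,
    dloge,
    mu_lin,
    frac_pe,
    frac_pe_inc,
    muen_ratio_score,
    muen_rho_ring,
    cutoff,
    # mode: 0 = water/polar, 1 = air ring, 2 = water/cylindrical mesh
    mode,
    primary_only,
    # polar grid
    r_edges,
    th_edges,
    n_radial,
    score_polar,
    # cylindrical mesh
    cyl_drho,
    cyl_z0,
    cyl_dz,
    cyl_nrho,
    cyl_nz,
    score_cyl,
    # air ring
    ring_r1,
    ring_r2,
    ring_cth_lo,
    ring_cth_hi,
    ring_volume,
    ring_cutoff,
    score_ring,
    # counters: [lost, emitted_keV, scored_keV_total, scored_keV_in_bins]
    counters,
):
    np.random.seed(seed)
    ngrid = mu_lin.shape[1]
    cyl_r2 = cyl_r * cyl_r
    phantom_r2 = phantom_r * phantom_r
    n_lines = spec_e.size

    for _ in range(n_hist):
        # --- primary photon ------------------------------------------------
        rho = core_r * np.sqrt(np.random.random())
        ang = 2.0 * np.pi * np.random.random()
        x = rho * np.cos(ang)
        y = rho * np.sin(ang)
        z = core_zmin + (core_zmax - core_zmin) * np.random.random()
        w = 2.0 * np.random.random() - 1.0
        psi = 2.0 * np.pi * np.random.random()
        s = np.sqrt(max(0.0, 1.0 - w * w))
        u = s * np.cos(psi)
        v = s * np.sin(psi)
        xi = np.random.random()
        lo = 0
        hi = n_lines - 1
        while lo < hi:
            mid = (lo + hi) // 2
            if spec_cdf[mid] < xi:
                lo = mid + 1
            else:
                hi = mid
        e = spec_e[lo]
        counters[1] += e
        first = True

        for _step in range(_MAX_STEPS):
            mat = _region(x, y, z, cyl_r2, cyl_zmin, cyl_zmax, cyl_mat, phantom_r2, phantom_mat)
            if mat == -2:
                break  # escaped the phantom
            if mat == -1:
                # vacuum: fly to the next material boundary, or (air mode)
                # integrate the straight ray through the ring detector
                t_cyl = _dist_to_cylinders(x, y, z, u, v, w, cyl_r, cyl_zmin, cyl_zmax)
                if t_cyl < np.inf:
                    x += (t_cyl + _EPS) * u
                    y += (t_cyl + _EPS) * v
                    z += (t_cyl + _EPS) * w
                    continue
                if mode == 1 and e >= ring_cutoff:
                    t_in = _dist_to_sphere(x, y, z, u, v, w, ring_r1)
                    t_out = _dist_to_sphere(x, y, z, u, v, w, ring_r2)
                    if t_out < np.inf:
                        if t_in == np.inf:
                            t_in = 0.0
                        nstep = 64
                        dt = (t_out - t_in) / nstep
                        ell = 0.0
                        for k in range(nstep):
                            t = t_in + (k + 0.5) * dt
                            xt = x + t * u
                            yt = y + t * v
                            zt = z + t * w
                            rt = np.sqrt(xt * xt + yt * yt + zt * zt)
                            cth = zt / rt
                            if ring_cth_lo <= cth <= ring_cth_hi:
                                ell += dt
                        if ell > 0.0:
                            muen = _lookup(muen_rho_ring, 0, e, loge0, dloge, ngrid)
                            score_ring[0] += e * muen * ell / ring_volume
                break
            mu_t = _lookup(mu_lin, mat, e, loge0, dloge, ngrid)
            if mu_t <= 0.0:
                break
            path = -np.log(np.random.random()) / mu_t
            t_cyl = _dist_to_cylinders(x, y, z, u, v, w, cyl_r, cyl_zmin, cyl_zmax)
            t_sph = _dist_to_sphere(x, y, z, u, v, w, phantom_r)
            t_b = t_cyl if t_cyl < t_sph else t_sph
            if path >= t_b:
                x += (t_b + _EPS) * u
                y += (t_b + _EPS) * v
                z += (t_b + _EPS) * w
                continue
            x += path * u
            y += path * v
            z += path * w
            # --- collision --------------------------------------------------
            if mat == phantom_mat and (mode == 0 or mode == 2):
                kerma = e * _lookup(muen_ratio_score, 0, e, loge0, dloge, ngrid)
                counters[2] += kerma
                if mode == 0:
                    r = np.sqrt(x * x + y * y + z * z)
                    cth = z / r
                    if cth > 1.0:
                        cth = 1.0
                    if cth < -1.0:
                        cth = -1.0
                    theta = np.degrees(np.arccos(cth))
                    ir = _edge_bin(r, r_edges)
                    it = _edge_bin(theta, th_edges)
                    if ir >= 0 and it >= 0:
                        score_polar[it * n_radial + ir] += kerma
                        counters[3] += kerma
                else:
                    irho = int(np.sqrt(x * x + y * y) / cyl_drho)
                    iz = int((z - cyl_z0) / cyl_dz)
                    if 0 <= irho < cyl_nrho and 0 <= iz < cyl_nz:
                        score_cyl[iz * cyl_nrho + irho] += kerma
                        counters[3] += kerma
            if primary_only and first:
                break
            first = False
            xi = np.random.random()
            fpe = _lookup(frac_pe, mat, e, loge0, dloge, ngrid)
            if xi < fpe:
                break  # photoelectric absorption
            fpi = _lookup(frac_pe_inc, mat, e, loge0, dloge, ngrid)
            if xi < fpi:
                c = _sample_kn(e)
                e = e / (1.0 + (e / 510.99895) * (1.0 - c))
                if e < cutoff:
                    break
                u, v, w = _rotate(u, v, w, c, 2.0 * np.pi * np.random.random())
            else:
                c = _sample_thomson()
                u, v, w = _rotate(u, v, w, c, 2.0 * np.pi * np.random.random())
        else:
            counters[0] += 1  # history hit the step guard: geometry leak


@njit(cache=True)
def sample_kn_batch(e, n, seed):
    """Vectorised Klein-Nishina angle-cosine samples (test/benchmark helper)."""
    np.random.seed(seed)
    out = np.empty(n)
    for i in range(n):
        out[i] = _sample_kn(e)
    return out
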