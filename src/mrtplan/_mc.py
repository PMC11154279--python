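"""Numba-compiled photon transport kernel (Woodcock delta-tracking).

Photons are sampled from the Gaussian focal spot, aimed uniformly into the
field aperture at the collimator plane, and tracked through the voxel grid
with delta tracking against the per-energy majorant.  At each real
interaction the transferred energy is deposited locally (kerma
approximation); the first interaction scores to the primary grid, every
later one to the scatter grid.  The microbeam structure is *not* simulated
here — the caller scales the result by the mean collimator transmittance.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

ELECTRON_REST_KEV = 511.0


@njit(cache=True)
def _rotate(ux, uy, uz, cost, phi):
    """Rotate a unit vector by polar angle acos(cost), azimuth phi."""
    sint = math.sqrt(max(0.0, 1.0 - cost * cost))
    cphi = math.cos(phi)
    sphi = math.sin(phi)
    if abs(uz) > 0.99999:
        sign = 1.0 if uz > 0.0 else -1.0
        return sint * cphi, sint * sphi, sign * cost
    srt = math.sqrt(1.0 - uz * uz)
    vx = ux * cost + sint * (ux * uz * cphi - uy * sphi) / srt
    vy = uy * cost + sint * (uy * uz * cphi + ux * sphi) / srt
    vz = uz * cost - sint * srt * cphi
    norm = math.sqrt(vx * vx + vy * vy + vz * vz)
    return vx / norm, vy / norm, vz / norm


@njit(cache=True)
def transport(
    density,  # (nz, ny, nx) g/cm^3
    mat_id,  # (nz, ny, nx) int16
    voxel_mm,
    z0_mm,  # entrance plane distance from source
    y0_mm,
    x0_mm,  # lateral coordinates of voxel [*,0,0] near corner
    sigma_mm,
    sd_mm,
    field_x_mm,
    field_y_mm,
    spec_cdf,
    spec_e,
    e0_kev,
    mu_rho,  # (n_mat, n_e) cm^2/g
    p_comp,  # (n_mat, n_e)
    invcdf_cost,  # (n_e, n_q)
    mu_max,  # (n_e,) majorant, 1/mm
    n_hist,
    seed,
    cutoff_kev,
    edep_p,  # (nz, ny, nx) keV, output
    edep_s,
):
    np.random.seed(seed)
    nz, ny, nx = density.shape
    n_e = mu_max.size
    n_q = invcdf_cost.shape[1]
    zmax = z0_mm + nz * voxel_mm
    ymax = y0_mm + ny * voxel_mm
    xmax = x0_mm + nx * voxel_mm

    e_emitted = 0.0
    e_entered = 0.0
    e_dep = 0.0
    e_exit = 0.0

    for _ in range(n_hist):
        # --- source sampling ---
        u = np.random.random()
        ib = np.searchsorted(spec_cdf, u)
        if ib >= spec_e.size:
            ib = spec_e.size - 1
        energy = spec_e[ib]
        e_emitted += energy

        if sigma_mm > 0.0:
            sx = np.random.normal() * sigma_mm
            sy = np.random.normal() * sigma_mm
        else:
            sx = 0.0
            sy = 0.0
        ax = (np.random.random() - 0.5) * field_x_mm
        ay = (np.random.random() - 0.5) * field_y_mm
        dx = ax - sx
        dy = ay - sy
        dz = sd_mm
        norm = math.sqrt(dx * dx + dy * dy + dz * dz)
        ux = dx / norm
        uy = dy / norm
        uz = dz / norm
        px = sx
        py = sy
        pz = 0.0

        # --- advance to the phantom bounding box (slab method) ---
        tmin = 0.0
        tmax = 1.0e30
        hit = True
        for axis in range(3):
            if axis == 0:
                p = pz
                d = uz
                lo = z0_mm
                hi = zmax
            elif axis == 1:
                p = py
                d = uy
                lo = y0_mm
                hi = ymax
            else:
                p = px
                d = ux
                lo = x0_mm
                hi = xmax
            if abs(d) < 1e-12:
                if p < lo or p > hi:
                    hit = False
                    break
            else:
                t1 = (lo - p) / d
                t2 = (hi - p) / d
                if t1 > t2:
                    t1, t2 = t2, t1
                if t1 > tmin:
                    tmin = t1
                if t2 < tmax:
                    tmax = t2
                if tmin > tmax:
                    hit = False
                    break
        if not hit:
            continue
        t = tmin + 1e-9
        px += ux * t
        py += uy * t
        pz += uz * t
        e_entered += energy

        first = True
        alive = True
        while alive:
            ie = int(energy - e0_kev)
            if ie < 0:
                ie = 0
            elif ie >= n_e:
                ie = n_e - 1
            mmax = mu_max[ie]
            if mmax <= 0.0:
                e_exit += energy
                break
            step = -math.log(np.random.random()) / mmax
            px += ux * step
            py += uy * step
            pz += uz * step
            iz = int((pz - z0_mm) / voxel_mm)
            iy = int((py - y0_mm) / voxel_mm)
            ix = int((px - x0_mm) / voxel_mm)
            if iz < 0 or iz >= nz or iy < 0 or iy >= ny or ix < 0 or ix >= nx:
                e_exit += energy
                break
            rho = density[iz, iy, ix]
            m = mat_id[iz, iy, ix]
            mu = rho * mu_rho[m, ie] * 0.1  # 1/mm
            if np.random.random() * mmax > mu:
                continue  # virtual interaction
            # real interaction
            if np.random.random() < p_comp[m, ie]:
                # incoherent scatter: sample cos(theta) from the tabulated
                # inverse CDF, deposit the recoil-electron energy
                qf = np.random.random() * (n_q - 1)
                qi = int(qf)
                frac = qf - qi
                if qi >= n_q - 1:
                    cost = invcdf_cost[ie, n_q - 1]
                else:
                    cost = invcdf_cost[ie, qi] * (1.0 - frac) + invcdf_cost[
                        ie, qi + 1
                    ] * frac
                k = energy / ELECTRON_REST_KEV
                eps = 1.0 / (1.0 + k * (1.0 - cost))
                dep = energy * (1.0 - eps)
                if first:
                    edep_p[iz, iy, ix] += dep
                else:
                    edep_s[iz, iy, ix] += dep
                e_dep += dep
                energy *= eps
                first = False
                if energy < cutoff_kev:
                    edep_s[iz, iy, ix] += energy
                    e_dep += energy
                    alive = False
                else:
                    phi = 2.0 * math.pi * np.random.random()
                    ux, uy, uz = _rotate(ux, uy, uz, cost, phi)
            else:
                # photoelectric-like local absorption
                if first:
                    edep_p[iz, iy, ix] += energy
                else:
                    edep_s[iz, iy, ix] += energy
                e_dep += energy
                alive = False

    return e_emitted, e_entered, e_dep, e_exit
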