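"""Compiled (numba) photon-packet transport kernel.

One scalar code path traces a single packet from launch to termination;
the batch driver loops packets serially, each with its own splitmix64
random stream keyed by (run seed, packet index), so results do not depend
on execution order and identical seeds replay bit-for-bit.

The kernel mirrors the vectorized physics primitives in
:mod:`photonmc.optics` and the geometry queries in
:mod:`photonmc.geometry`; unit tests pin the two routes against each
other.  All arrays arrive pre-flattened from :class:`CompiledScene` and
the recorder objects in :mod:`photonmc.transport`.

Status codes: 0 exited, 1 roulette-killed, 2 fully absorbed,
3 step-cap exceeded, 4 lost (never entered the scene).
"""

from __future__ import annotations

import numpy as np
from numba import njit

C_MM_PER_PS = 0.299792458
EPS_NUDGE = 1e-7

_U64 = np.uint64
_GOLD = _U64(0x9E3779B97F4A7C15)
_MIX1 = _U64(0xBF58476D1CE4E5B9)
_MIX2 = _U64(0x94D049BB133111EB)
_S30 = _U64(30)
_S27 = _U64(27)
_S31 = _U64(31)
_S11 = _U64(11)
_INV53 = 1.0 / 9007199254740992.0  # 2^-53

STATUS_EXIT = 0
STATUS_ROULETTE = 1
STATUS_ABSORBED = 2
STATUS_CAP = 3
STATUS_LOST = 4

# totals[] layout
T_LAUNCHED = 0
T_SPECULAR = 1
T_DEPOSITED = 2
T_EXITED = 3
T_ROULETTE_KILLED = 4
T_ROULETTE_INJECTED = 5
T_CAP = 6
T_CONVERTED = 7
T_LOST = 8
N_TOTALS = 9

# probe direction for parity region location, (1,2,3)/sqrt(14)
_PX = 0.2672612419124244
_PY = 0.5345224838248488
_PZ = 0.8017837257372732


@njit(cache=True)
def _rng_uniform(state):
    """splitmix64 step -> (new_state, uniform double in (0, 1))."""
    state = state + _GOLD
    z = state
    z = (z ^ (z >> _S30)) * _MIX1
    z = (z ^ (z >> _S27)) * _MIX2
    z = z ^ (z >> _S31)
    return state, (np.float64(z >> _S11) + 0.5) * _INV53


def derive_photon_seeds(run_seed: int, n: int) -> np.ndarray:
    """Independent 64-bit stream keys for each photon index (vectorized)."""
    idx = np.arange(n, dtype=np.uint64)
    with np.errstate(over="ignore"):
        z = (np.uint64(run_seed) + np.uint64(1)) * _GOLD + (idx + np.uint64(1)) * _MIX1
        z = (z ^ (z >> np.uint64(30))) * _MIX1
        z = (z ^ (z >> np.uint64(27))) * _MIX2
        return z ^ (z >> np.uint64(31))


@njit(cache=True)
def _ray_aabb(ox, oy, oz, dx, dy, dz, lo, hi, tmax):
    t0 = 0.0
    t1 = tmax
    for a in range(3):
        if a == 0:
            o, d = ox, dx
        elif a == 1:
            o, d = oy, dy
        else:
            o, d = oz, dz
        if abs(d) < 1e-300:
            if o < lo[a] or o > hi[a]:
                return False
        else:
            inv = 1.0 / d
            ta = (lo[a] - o) * inv
            tb = (hi[a] - o) * inv
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
            if t0 > t1:
                return False
    return True


@njit(cache=True)
def _tri_hit(ox, oy, oz, dx, dy, dz, v0, v1, v2, i):
    """Scalar Moller-Trumbore with inclusive edges; returns t or -1."""
    e1x = v1[i, 0] - v0[i, 0]
    e1y = v1[i, 1] - v0[i, 1]
    e1z = v1[i, 2] - v0[i, 2]
    e2x = v2[i, 0] - v0[i, 0]
    e2y = v2[i, 1] - v0[i, 1]
    e2z = v2[i, 2] - v0[i, 2]
    px = dy * e2z - dz * e2y
    py = dz * e2x - dx * e2z
    pz = dx * e2y - dy * e2x
    det = e1x * px + e1y * py + e1z * pz
    if abs(det) <= 1e-14:
        return -1.0
    inv = 1.0 / det
    tx = ox - v0[i, 0]
    ty = oy - v0[i, 1]
    tz = oz - v0[i, 2]
    u = (tx * px + ty * py + tz * pz) * inv
    if u < 0.0 or u > 1.0:
        return -1.0
    qx = ty * e1z - tz * e1y
    qy = tz * e1x - tx * e1z
    qz = tx * e1y - ty * e1x
    v = (dx * qx + dy * qy + dz * qz) * inv
    if v < 0.0 or u + v > 1.0:
        return -1.0
    t = (e2x * qx + e2y * qy + e2z * qz) * inv
    if t <= EPS_NUDGE:
        return -1.0
    return t


@njit(cache=True)
def _nearest_hit(
    ox, oy, oz, dx, dy, dz, tmax,
    v0, v1, v2, reg_bb_min, reg_bb_max, reg_start, reg_end,
):
    best_i = -1
    best_t = tmax
    for r in range(reg_start.shape[0]):
        if not _ray_aabb(ox, oy, oz, dx, dy, dz, reg_bb_min[r], reg_bb_max[r], best_t):
            continue
        for i in range(reg_start[r], reg_end[r]):
            t = _tri_hit(ox, oy, oz, dx, dy, dz, v0, v1, v2, i)
            if 0.0 < t <= best_t:
                if t < best_t or best_i < 0 or i < best_i:
                    best_t = t
                    best_i = i
    return best_i, best_t


@njit(cache=True)
def _locate(ox, oy, oz, v0, v1, v2, reg_start, reg_end, depth):
    """Innermost region index containing the point, -1 = ambient."""
    best = -1
    best_depth = -1
    for r in range(reg_start.shape[0]):
        cnt = 0
        for i in range(reg_start[r], reg_end[r]):
            t = _tri_hit(ox, oy, oz, _PX, _PY, _PZ, v0, v1, v2, i)
            if t > 0.0:
                cnt += 1
        if cnt % 2 == 1 and depth[r] > best_depth:
            best = r
            best_depth = depth[r]
    return best


@njit(cache=True)
def _hg_cos(g, xi):
    if abs(g) < 1e-12:
        return 2.0 * xi - 1.0
    frac = (1.0 - g * g) / (1.0 + g - 2.0 * g * xi)
    ct = (1.0 + g * g - frac * frac) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True)
def _fresnel_cos(n_i, n_t, cos_i):
    """Unpolarized reflectance from the incidence cosine (s/p average form)."""
    if n_i == n_t:
        return 0.0
    if cos_i > 1.0:
        cos_i = 1.0
    sin_i = np.sqrt(1.0 - cos_i * cos_i)
    sin_t = n_i / n_t * sin_i
    if sin_t >= 1.0:
        return 1.0
    cos_t = np.sqrt(1.0 - sin_t * sin_t)
    if sin_i < 1e-9:
        r = (n_i - n_t) / (n_i + n_t)
        return r * r
    rs = (n_i * cos_i - n_t * cos_t) / (n_i * cos_i + n_t * cos_t)
    rp = (n_i * cos_t - n_t * cos_i) / (n_i * cos_t + n_t * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _spin(ux, uy, uz, ct, phi):
    st = np.sqrt(max(0.0, 1.0 - ct * ct))
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(uz) > 0.99999:
        sign = 1.0 if uz >= 0.0 else -1.0
        nx = st * cp
        ny = st * sp
        nz = sign * ct
    else:
        den = np.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nz = -st * cp * den + uz * ct
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def _gate_index(t, gate_start, gate_dt, n_gates, td):
    if not td:
        return 0
    k = int(np.floor((t - gate_start) / gate_dt))
    if k < 0 or k >= n_gates:
        return n_gates  # overflow gate
    return k


@njit(cache=True)
def _face_bins(px, py, pz, tri_nx, tri_ny, tri_nz, box_min, box_max, rows, cols):
    """(face, row, col) on an axis-aligned outer box, from the hit normal."""
    ax = abs(tri_nx)
    ay = abs(tri_ny)
    az = abs(tri_nz)
    if ax >= ay and ax >= az:
        axis = 0
        positive = tri_nx > 0.0
    elif ay >= az:
        axis = 1
        positive = tri_ny > 0.0
    else:
        axis = 2
        positive = tri_nz > 0.0
    face = 2 * axis + (1 if positive else 0)
    if axis == 0:
        a1, a2 = 1, 2
        c1, c2 = py, pz
    elif axis == 1:
        a1, a2 = 0, 2
        c1, c2 = px, pz
    else:
        a1, a2 = 0, 1
        c1, c2 = px, py
    d1 = (box_max[a1] - box_min[a1]) / rows
    d2 = (box_max[a2] - box_min[a2]) / cols
    row = int((c1 - box_min[a1]) / d1)
    col = int((c2 - box_min[a2]) / d2)
    if row >= rows:
        row = rows - 1
    if col >= cols:
        col = cols - 1
    if row < 0:
        row = 0
    if col < 0:
        col = 0
    return face, row, col


@njit(cache=True)
def _trace_one(
    state, px, py, pz, ux, uy, uz, w, t, reg, band,
    # geometry
    v0, v1, v2, normals, tri_inside, tri_outside,
    reg_bb_min, reg_bb_max, reg_start, reg_end, depth,
    # optics (R, B) + ambient
    mu_a, mu_s, g_arr, n_arr, ambient_n,
    # fluorophore
    fluo_region, fluo_eta,
    # controls
    roulette_threshold, roulette_m, max_steps,
    gate_start, gate_dt, n_gates, td,
    # recorders (band-leading)
    tri_rec, face_rec, face_enabled, box_min, box_max, face_rows, face_cols,
    vox_rec, vox_enabled, vox_origin, vox_size, vox_overflow,
    totals,
):
    """Trace one packet to termination.

    Returns (status, exit_weight, exit_time, exit_triangle, final_band).
    The sampled dimensionless step is decremented by the optical depth
    traversed to a boundary and the remainder carried across the
    interface, rescaled by the new region's mu_t (MCML convention).
    """
    state, xi = _rng_uniform(state)
    s = -np.log(xi)  # dimensionless step
    steps = 0
    while True:
        steps += 1
        if steps > max_steps:
            totals[T_CAP] += w
            return state, STATUS_CAP, 0.0, t, -1, band
        if reg < 0:
            # in the ambient medium: ballistic flight to the next boundary
            tri, dist = _nearest_hit(
                px, py, pz, ux, uy, uz, 1e30,
                v0, v1, v2, reg_bb_min, reg_bb_max, reg_start, reg_end,
            )
            if tri < 0:
                totals[T_LOST] += w
                return state, STATUS_LOST, 0.0, t, -1, band
            px += dist * ux
            py += dist * uy
            pz += dist * uz
            t += dist * ambient_n / C_MM_PER_PS
            reg_to = tri_inside[tri] if (
                ux * normals[tri, 0] + uy * normals[tri, 1] + uz * normals[tri, 2]
            ) < 0.0 else tri_outside[tri]
            if reg_to >= 0:
                # entry specular loss at normal-incidence reflectance
                n_t = n_arr[reg_to, band]
                rsp = (ambient_n - n_t) / (ambient_n + n_t)
                rsp = rsp * rsp
                totals[T_SPECULAR] += w * rsp
                w *= 1.0 - rsp
            reg = reg_to
            px += EPS_NUDGE * ux
            py += EPS_NUDGE * uy
            pz += EPS_NUDGE * uz
            continue

        mu_t = mu_a[reg, band] + mu_s[reg, band]
        d_free = s / mu_t if mu_t > 0.0 else 1e30
        tri, dist = _nearest_hit(
            px, py, pz, ux, uy, uz, d_free,
            v0, v1, v2, reg_bb_min, reg_bb_max, reg_start, reg_end,
        )
        if tri >= 0:
            # boundary reached before the interaction site
            px += dist * ux
            py += dist * uy
            pz += dist * uz
            t += dist * n_arr[reg, band] / C_MM_PER_PS
            s -= dist * mu_t
            if s < 0.0:
                s = 0.0
            nx = normals[tri, 0]
            ny = normals[tri, 1]
            nz = normals[tri, 2]
            dot = ux * nx + uy * ny + uz * nz
            reg_to = tri_outside[tri] if dot > 0.0 else tri_inside[tri]
            n_i = n_arr[reg, band]
            n_t = ambient_n if reg_to < 0 else n_arr[reg_to, band]
            ci = abs(dot)
            if ci > 1.0:
                ci = 1.0
            refl = _fresnel_cos(n_i, n_t, ci)
            state, xi = _rng_uniform(state)
            if xi <= refl:
                # specular reflection, region unchanged
                ux -= 2.0 * dot * nx
                uy -= 2.0 * dot * ny
                uz -= 2.0 * dot * nz
                norm = np.sqrt(ux * ux + uy * uy + uz * uz)
                ux /= norm
                uy /= norm
                uz /= norm
            else:
                if n_i != n_t:
                    # Snell refraction about the normal oriented against travel
                    gx, gy, gz = (-nx, -ny, -nz) if dot > 0.0 else (nx, ny, nz)
                    eta = n_i / n_t
                    sin2t = eta * eta * (1.0 - ci * ci)
                    cost = np.sqrt(max(0.0, 1.0 - sin2t))
                    k = eta * ci - cost
                    ux = eta * ux + k * gx
                    uy = eta * uy + k * gy
                    uz = eta * uz + k * gz
                    norm = np.sqrt(ux * ux + uy * uy + uz * uz)
                    ux /= norm
                    uy /= norm
                    uz /= norm
                if reg_to < 0:
                    # crossed the outermost boundary: terminate and record
                    totals[T_EXITED] += w
                    gate = _gate_index(t, gate_start, gate_dt, n_gates, td)
                    tri_rec[band, tri, gate] += w
                    if face_enabled:
                        face, row, col = _face_bins(
                            px, py, pz,
                            normals[tri, 0], normals[tri, 1], normals[tri, 2],
                            box_min, box_max, face_rows, face_cols,
                        )
                        face_rec[band, face, row, col, gate] += w
                    return state, STATUS_EXIT, w, t, tri, band
                reg = reg_to
            px += EPS_NUDGE * ux
            py += EPS_NUDGE * uy
            pz += EPS_NUDGE * uz
            continue

        if mu_t <= 0.0:
            # non-participating region and no boundary ahead (open scene)
            totals[T_LOST] += w
            return state, STATUS_LOST, 0.0, t, -1, band

        # interaction site
        px += d_free * ux
        py += d_free * uy
        pz += d_free * uz
        t += d_free * n_arr[reg, band] / C_MM_PER_PS
        dw = w * mu_a[reg, band] / mu_t
        if dw > 0.0:
            totals[T_DEPOSITED] += dw
            gate = _gate_index(t, gate_start, gate_dt, n_gates, td)
            if vox_enabled:
                ix = int(np.floor((px - vox_origin[0]) / vox_size))
                iy = int(np.floor((py - vox_origin[1]) / vox_size))
                iz = int(np.floor((pz - vox_origin[2]) / vox_size))
                if (
                    0 <= ix < vox_rec.shape[1]
                    and 0 <= iy < vox_rec.shape[2]
                    and 0 <= iz < vox_rec.shape[3]
                ):
                    vox_rec[band, ix, iy, iz, gate] += dw
                else:
                    vox_overflow[band, gate] += dw
            w -= dw
        if w <= 0.0:
            return state, STATUS_ABSORBED, 0.0, t, -1, band

        # fluorescence conversion: once per interaction site, before scatter
        if fluo_region >= 0 and band == 0 and reg == fluo_region:
            state, xi = _rng_uniform(state)
            if xi < fluo_eta:
                totals[T_CONVERTED] += 1.0
                band = 1
                state, xi = _rng_uniform(state)
                ct = 2.0 * xi - 1.0
                state, xi = _rng_uniform(state)
                phi = 2.0 * np.pi * xi
                st = np.sqrt(1.0 - ct * ct)
                ux = st * np.cos(phi)
                uy = st * np.sin(phi)
                uz = ct
                state, xi = _rng_uniform(state)
                s = -np.log(xi)
                continue

        # Russian roulette below the weight threshold
        if roulette_threshold > 0.0 and w < roulette_threshold:
            state, xi = _rng_uniform(state)
            if xi <= 1.0 / roulette_m:
                totals[T_ROULETTE_INJECTED] += (roulette_m - 1.0) * w
                w *= roulette_m
            else:
                totals[T_ROULETTE_KILLED] += w
                return state, STATUS_ROULETTE, 0.0, t, -1, band

        # scatter
        state, xi = _rng_uniform(state)
        ct = _hg_cos(g_arr[reg, band], xi)
        state, xi = _rng_uniform(state)
        phi = 2.0 * np.pi * xi
        ux, uy, uz = _spin(ux, uy, uz, ct, phi)
        state, xi = _rng_uniform(state)
        s = -np.log(xi)


@njit(cache=True)
def run_photons(
    seeds, w0, src_band,
    # source: kind 0 = internal volume, 1 = external beam
    src_kind, src_shape, src_center, src_radius, src_box_min, src_box_max,
    src_entry, src_dir,
    # geometry
    v0, v1, v2, normals, tri_inside, tri_outside,
    reg_bb_min, reg_bb_max, reg_start, reg_end, depth,
    # optics
    mu_a, mu_s, g_arr, n_arr, ambient_n,
    fluo_region, fluo_eta,
    roulette_threshold, roulette_m, max_steps,
    gate_start, gate_dt, n_gates, td,
    tri_rec, face_rec, face_enabled, box_min, box_max, face_rows, face_cols,
    vox_rec, vox_enabled, vox_origin, vox_size, vox_overflow,
    totals,
    status_out, exit_w_out, exit_t_out, exit_tri_out, band_out,
):
    """Launch and trace every packet; fills recorders and per-photon logs."""
    n = seeds.shape[0]
    for i in range(n):
        state = seeds[i]
        band = src_band
        if src_kind == 0:
            # uniform position over the source volume by rejection sampling
            if src_shape == 0:
                lox = src_center[0] - src_radius
                loy = src_center[1] - src_radius
                loz = src_center[2] - src_radius
                span = 2.0 * src_radius
            else:
                lox = src_box_min[0]
                loy = src_box_min[1]
                loz = src_box_min[2]
                span = 0.0
            while True:
                state, x1 = _rng_uniform(state)
                state, x2 = _rng_uniform(state)
                state, x3 = _rng_uniform(state)
                if src_shape == 0:
                    px = lox + span * x1
                    py = loy + span * x2
                    pz = loz + span * x3
                    ddx = px - src_center[0]
                    ddy = py - src_center[1]
                    ddz = pz - src_center[2]
                    if ddx * ddx + ddy * ddy + ddz * ddz <= src_radius * src_radius:
                        break
                else:
                    px = lox + (src_box_max[0] - lox) * x1
                    py = loy + (src_box_max[1] - loy) * x2
                    pz = loz + (src_box_max[2] - loz) * x3
                    break
            # isotropic initial direction: cos(theta) uniform on [-1, 1]
            state, x1 = _rng_uniform(state)
            ct = 2.0 * x1 - 1.0
            state, x2 = _rng_uniform(state)
            phi = 2.0 * np.pi * x2
            st = np.sqrt(1.0 - ct * ct)
            ux = st * np.cos(phi)
            uy = st * np.sin(phi)
            uz = ct
            reg = _locate(px, py, pz, v0, v1, v2, reg_start, reg_end, depth)
        else:
            px = src_entry[0] + EPS_NUDGE * src_dir[0]
            py = src_entry[1] + EPS_NUDGE * src_dir[1]
            pz = src_entry[2] + EPS_NUDGE * src_dir[2]
            ux = src_dir[0]
            uy = src_dir[1]
            uz = src_dir[2]
            reg = _locate(px, py, pz, v0, v1, v2, reg_start, reg_end, depth)
        w = w0
        totals[T_LAUNCHED] += w0
        if src_kind == 1 and reg >= 0:
            # beam entering at the surface: remove the specular fraction
            n_t = n_arr[reg, band]
            rsp = (ambient_n - n_t) / (ambient_n + n_t)
            rsp = rsp * rsp
            totals[T_SPECULAR] += w * rsp
            w *= 1.0 - rsp
        state, status, wex, tex, triex, band = _trace_one(
            state, px, py, pz, ux, uy, uz, w, 0.0, reg, band,
            v0, v1, v2, normals, tri_inside, tri_outside,
            reg_bb_min, reg_bb_max, reg_start, reg_end, depth,
            mu_a, mu_s, g_arr, n_arr, ambient_n,
            fluo_region, fluo_eta,
            roulette_threshold, roulette_m, max_steps,
            gate_start, gate_dt, n_gates, td,
            tri_rec, face_rec, face_enabled, box_min, box_max, face_rows, face_cols,
            vox_rec, vox_enabled, vox_origin, vox_size, vox_overflow,
            totals,
        )
        status_out[i] = status
        exit_w_out[i] = wex
        exit_t_out[i] = tex
        exit_tri_out[i] = triex
        band_out[i] = band
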