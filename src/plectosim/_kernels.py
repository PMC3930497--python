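"""Numba-compiled numerical core.

Everything that runs inside the per-step loop lives here: quaternion algebra,
capsule geometry, constraint-row assembly, the three constraint solvers
(banded-exact, projected SOR, active-set direct), collision detection,
elastic torques, thermostat updates and the main time-stepping loop.

All quantities are in reduced units (cylinder length b = 1, cylinder mass
m = 1, thermal energy k_BT = 1 unless stated otherwise).  Quaternions are
stored (w, x, y, z); angular velocities are world-frame.

Joint kind codes (path order along the chain is assumed):
    0 = ball-and-socket            (3 rows)
    1 = weld (ball + orientation)  (6 rows)
    2 = bead orientation clamp     (3 rows, driven about z)
    3 = bead x/y orientation lock  (2 rows)
A body index of -1 denotes the static world (ground plane / magnet frame).
"""

import numpy as np
from numba import njit

NJIT_OPTS = dict(cache=True, fastmath=False)

# ---------------------------------------------------------------------------
# quaternion / rotation helpers
# ---------------------------------------------------------------------------


@njit(**NJIT_OPTS)
def quat_mul(a, b):
    out = np.empty(4)
    out[0] = a[0] * b[0] - a[1] * b[1] - a[2] * b[2] - a[3] * b[3]
    out[1] = a[0] * b[1] + a[1] * b[0] + a[2] * b[3] - a[3] * b[2]
    out[2] = a[0] * b[2] - a[1] * b[3] + a[2] * b[0] + a[3] * b[1]
    out[3] = a[0] * b[3] + a[1] * b[2] - a[2] * b[1] + a[3] * b[0]
    return out


@njit(**NJIT_OPTS)
def quat_conj(q):
    out = np.empty(4)
    out[0] = q[0]
    out[1] = -q[1]
    out[2] = -q[2]
    out[3] = -q[3]
    return out


@njit(**NJIT_OPTS)
def quat_normalize(q):
    n = np.sqrt(q[0] * q[0] + q[1] * q[1] + q[2] * q[2] + q[3] * q[3])
    return q / n


@njit(**NJIT_OPTS)
def quat_to_rot(q):
    """3x3 rotation matrix of unit quaternion (w,x,y,z)."""
    w, x, y, z = q[0], q[1], q[2], q[3]
    R = np.empty((3, 3))
    R[0, 0] = 1.0 - 2.0 * (y * y + z * z)
    R[0, 1] = 2.0 * (x * y - w * z)
    R[0, 2] = 2.0 * (x * z + w * y)
    R[1, 0] = 2.0 * (x * y + w * z)
    R[1, 1] = 1.0 - 2.0 * (x * x + z * z)
    R[1, 2] = 2.0 * (y * z - w * x)
    R[2, 0] = 2.0 * (x * z - w * y)
    R[2, 1] = 2.0 * (y * z + w * x)
    R[2, 2] = 1.0 - 2.0 * (x * x + y * y)
    return R


@njit(**NJIT_OPTS)
def exp_map_quat(w_vec, dt):
    """Quaternion exp(0.5 * w_vec * dt); series branch near zero angle."""
    wx, wy, wz = w_vec[0], w_vec[1], w_vec[2]
    ang = np.sqrt(wx * wx + wy * wy + wz * wz) * dt
    out = np.empty(4)
    half = 0.5 * ang
    if ang < 1e-8:
        # sin(half)/ang -> 0.5 - ang^2/48
        s = 0.5 - ang * ang / 48.0
        out[0] = 1.0 - half * half / 2.0
    else:
        s = np.sin(half) / ang
        out[0] = np.cos(half)
    out[1] = wx * dt * s
    out[2] = wy * dt * s
    out[3] = wz * dt * s
    return out


@njit(**NJIT_OPTS)
def exp_map_update(q, w_vec, dt):
    return quat_normalize(quat_mul(exp_map_quat(w_vec, dt), q))


@njit(**NJIT_OPTS)
def rotvec_from_quat(q):
    """Small-angle rotation vector 2*vec(q)*sign(w) (exact axis, angle to O(angle^3))."""
    out = np.empty(3)
    w = q[0]
    s = 1.0 if w >= 0.0 else -1.0
    # use exact log map for robustness
    vn = np.sqrt(q[1] * q[1] + q[2] * q[2] + q[3] * q[3])
    if vn < 1e-12:
        out[0] = 2.0 * s * q[1]
        out[1] = 2.0 * s * q[2]
        out[2] = 2.0 * s * q[3]
        return out
    ang = 2.0 * np.arctan2(vn, s * w)
    f = ang / vn
    out[0] = s * q[1] * f
    out[1] = s * q[2] * f
    out[2] = s * q[3] * f
    return out


@njit(**NJIT_OPTS)
def cross3(a, b):
    out = np.empty(3)
    out[0] = a[1] * b[2] - a[2] * b[1]
    out[1] = a[2] * b[0] - a[0] * b[2]
    out[2] = a[0] * b[1] - a[1] * b[0]
    return out


# ---------------------------------------------------------------------------
# frames, inertia
# ---------------------------------------------------------------------------


@njit(**NJIT_OPTS)
def compute_frames(quat, R_out):
    nb = quat.shape[0]
    for i in range(nb):
        R_out[i] = quat_to_rot(quat[i])


@njit(**NJIT_OPTS)
def world_inertia_inv(R, Ibody, out):
    """out[i] = R diag(1/Ibody) R^T for each body."""
    nb = R.shape[0]
    for i in range(nb):
        for a in range(3):
            for bcol in range(3):
                s = 0.0
                for k in range(3):
                    s += R[i, a, k] * R[i, bcol, k] / Ibody[i, k]
                out[i, a, bcol] = s


@njit(**NJIT_OPTS)
def world_inertia(R, Ibody, out):
    nb = R.shape[0]
    for i in range(nb):
        for a in range(3):
            for bcol in range(3):
                s = 0.0
                for k in range(3):
                    s += R[i, a, k] * R[i, bcol, k] * Ibody[i, k]
                out[i, a, bcol] = s


# ---------------------------------------------------------------------------
# bending / twisting elasticity
# ---------------------------------------------------------------------------


@njit(**NJIT_OPTS)
def bend_twist_from_frames(R0, R1):
    """Bending angle theta and principal-value twist phi between two triads.

    Triad columns: tangent t = R[:,2], normal u = R[:,0], binormal v = R[:,1].
    phi is the ZXZ twist (alpha + gamma), well defined except at theta = pi.
    """
    ct = R0[0, 2] * R1[0, 2] + R0[1, 2] * R1[1, 2] + R0[2, 2] * R1[2, 2]
    if ct > 1.0:
        ct = 1.0
    if ct < -1.0:
        ct = -1.0
    theta = np.arccos(ct)
    a = 0.0
    b2 = 0.0
    for k in range(3):
        a += R0[k, 0] * R1[k, 0] + R0[k, 1] * R1[k, 1]
        b2 += R0[k, 1] * R1[k, 0] - R0[k, 0] * R1[k, 1]
    phi = np.arctan2(b2, a)
    return theta, phi


@njit(**NJIT_OPTS)
def elastic_torque_pair(R0, R1, g_b, g_t):
    """Restoring torque on body 1 (torque on body 0 is the negative).

    Energy  E = g_b (1 - cos theta) + g_t (1 - cos phi)  with the ZXZ twist
    phi; the torque is the negative rotational gradient of E with respect to
    a world-frame rotation of body 1.  Near the gimbal degeneracy
    (theta -> pi) the twist term is switched off for the step.
    """
    t0 = R0[:, 2]
    t1 = R1[:, 2]
    u0 = R0[:, 0]
    u1 = R1[:, 0]
    v0 = R0[:, 1]
    v1 = R1[:, 1]
    ct = t0[0] * t1[0] + t0[1] * t1[1] + t0[2] * t1[2]
    txt = cross3(t1, t0)
    tq = np.empty(3)
    for k in range(3):
        tq[k] = g_b * txt[k]
    rho = 1.0 + ct
    if rho > 1e-6 and g_t != 0.0:
        a = 0.0
        for k in range(3):
            a += u0[k] * u1[k] + v0[k] * v1[k]
        uxu = cross3(u1, u0)
        vxv = cross3(v1, v0)
        for k in range(3):
            tq[k] += g_t * ((uxu[k] + vxv[k]) / rho - a / (rho * rho) * txt[k])
    return tq


@njit(**NJIT_OPTS)
def elastic_energy_chain(R, n_cyl, g_b, g_t):
    E = 0.0
    for i in range(n_cyl - 1):
        theta, phi = bend_twist_from_frames(R[i], R[i + 1])
        E += g_b * (1.0 - np.cos(theta)) + g_t * (1.0 - np.cos(phi))
    return E


@njit(**NJIT_OPTS)
def add_elastic_torques(R, n_cyl, g_b, g_t, torque):
    for i in range(n_cyl - 1):
        tq = elastic_torque_pair(R[i], R[i + 1], g_b, g_t)
        for k in range(3):
            torque[i + 1, k] += tq[k]
            torque[i, k] -= tq[k]


@njit(**NJIT_OPTS)
def wrap_angle(x):
    """Map angle to (-pi, pi]."""
    twopi = 2.0 * np.pi
    y = x % twopi
    if y > np.pi:
        y -= twopi
    if y <= -np.pi:
        y += twopi
    return y


@njit(**NJIT_OPTS)
def update_cumulative_twists(R, n_cyl, tw_cum):
    """Unwrap per-joint twist; assumes |delta phi| < pi per step."""
    for i in range(n_cyl - 1):
        theta, phi = bend_twist_from_frames(R[i], R[i + 1])
        if theta > np.pi - 1e-3:
            continue  # gimbal: carry previous value
        d = wrap_angle(phi - wrap_angle(tw_cum[i]))
        tw_cum[i] += d


# ---------------------------------------------------------------------------
# capsule geometry / collision narrow phase
# ---------------------------------------------------------------------------


@njit(**NJIT_OPTS)
def segment_closest_params(p1, d1, hl1, p2, d2, hl2):
    """Closest-approach parameters (s, t) of segments p +/- hl*d (unit d)."""
    r = np.empty(3)
    for k in range(3):
        r[k] = p1[k] - p2[k]
    b = d1[0] * d2[0] + d1[1] * d2[1] + d1[2] * d2[2]
    c = d1[0] * r[0] + d1[1] * r[1] + d1[2] * r[2]
    f = d2[0] * r[0] + d2[1] * r[1] + d2[2] * r[2]
    denom = 1.0 - b * b
    if denom > 1e-12:
        s = (b * f - c) / denom
    else:
        s = 0.0
    if s > hl1:
        s = hl1
    elif s < -hl1:
        s = -hl1
    t = f + b * s
    if t > hl2:
        t = hl2
        s = b * t - c
        if s > hl1:
            s = hl1
        elif s < -hl1:
            s = -hl1
    elif t < -hl2:
        t = -hl2
        s = b * t - c
        if s > hl1:
            s = hl1
        elif s < -hl1:
            s = -hl1
    return s, t


@njit(**NJIT_OPTS)
def capsule_capsule(p1, d1, hl1, r1, p2, d2, hl2, r2):
    """Return (hit, point, normal, depth); normal points from capsule 2 to 1."""
    s, t = segment_closest_params(p1, d1, hl1, p2, d2, hl2)
    c1 = np.empty(3)
    c2 = np.empty(3)
    for k in range(3):
        c1[k] = p1[k] + s * d1[k]
        c2[k] = p2[k] + t * d2[k]
    dvec = np.empty(3)
    for k in range(3):
        dvec[k] = c1[k] - c2[k]
    dist = np.sqrt(dvec[0] ** 2 + dvec[1] ** 2 + dvec[2] ** 2)
    rsum = r1 + r2
    point = np.zeros(3)
    normal = np.zeros(3)
    if dist >= rsum:
        return False, point, normal, 0.0
    if dist > 1e-12:
        for k in range(3):
            normal[k] = dvec[k] / dist
    else:
        # coincident axes: deterministic fallback, perpendicular of smallest index
        ref = np.zeros(3)
        if abs(d1[0]) < 0.9:
            ref[0] = 1.0
        else:
            ref[1] = 1.0
        nn = cross3(d1, ref)
        nrm = np.sqrt(nn[0] ** 2 + nn[1] ** 2 + nn[2] ** 2)
        for k in range(3):
            normal[k] = nn[k] / nrm
    depth = rsum - dist
    for k in range(3):
        point[k] = 0.5 * (c1[k] - r1 * normal[k] + c2[k] + r2 * normal[k])
    return True, point, normal, depth


@njit(**NJIT_OPTS)
def capsule_plane(p, d, hl, r):
    """Capsule vs plane z=0; normal +z. Returns (hit, point, normal, depth)."""
    z1 = p[2] - hl * d[2]
    z2 = p[2] + hl * d[2]
    point = np.zeros(3)
    normal = np.zeros(3)
    normal[2] = 1.0
    if z1 <= z2:
        s = -hl
        zlow = z1
    else:
        s = hl
        zlow = z2
    if zlow - r >= 0.0:
        return False, point, normal, 0.0
    depth = r - zlow
    for k in range(3):
        point[k] = p[k] + s * d[k]
    point[2] = zlow - r + 0.5 * depth
    return True, point, normal, depth


@njit(**NJIT_OPTS)
def capsule_sphere(p, d, hl, r, c, R):
    """Capsule vs sphere; normal from sphere to capsule."""
    rel = np.empty(3)
    for k in range(3):
        rel[k] = c[k] - p[k]
    s = rel[0] * d[0] + rel[1] * d[1] + rel[2] * d[2]
    if s > hl:
        s = hl
    elif s < -hl:
        s = -hl
    cp = np.empty(3)
    for k in range(3):
        cp[k] = p[k] + s * d[k]
    dvec = np.empty(3)
    for k in range(3):
        dvec[k] = cp[k] - c[k]
    dist = np.sqrt(dvec[0] ** 2 + dvec[1] ** 2 + dvec[2] ** 2)
    point = np.zeros(3)
    normal = np.zeros(3)
    if dist >= r + R:
        return False, point, normal, 0.0
    if dist > 1e-12:
        for k in range(3):
            normal[k] = dvec[k] / dist
    else:
        normal[2] = 1.0
    depth = r + R - dist
    for k in range(3):
        point[k] = 0.5 * (cp[k] - r * normal[k] + c[k] + (R) * normal[k])
    return True, point, normal, depth


@njit(**NJIT_OPTS)
def sphere_plane(c, R):
    point = np.zeros(3)
    normal = np.zeros(3)
    normal[2] = 1.0
    if c[2] - R >= 0.0:
        return False, point, normal, 0.0
    depth = R - c[2]
    point[0] = c[0]
    point[1] = c[1]
    point[2] = c[2] - R + 0.5 * depth
    return True, point, normal, depth


# ---------------------------------------------------------------------------
# broad phase: uniform spatial hash over cylinder capsules
# ---------------------------------------------------------------------------


@njit(**NJIT_OPTS)
def broad_phase_pairs(pos, n_cyl, cell, n_ex, pairs_out):
    """Candidate cylinder pairs within one cell neighbourhood.

    cell must be >= the largest pairwise contact reach so that the 27-cell
    stencil is a superset of contacting pairs.  Chain neighbours with
    |i - j| <= n_ex are excluded (their capsule caps overlap permanently
    whenever the straight-chain endpoint gap (|i-j|-1) b is below 2r).
    Returns the pair count.
    """
    K = np.int64(1 << 20)
    keys = np.empty(n_cyl, dtype=np.int64)
    for i in range(n_cyl):
        ix = np.int64(np.floor(pos[i, 0] / cell)) + K
        iy = np.int64(np.floor(pos[i, 1] / cell)) + K
        iz = np.int64(np.floor(pos[i, 2] / cell)) + K
        keys[i] = (ix << 42) | (iy << 21) | iz
    order = np.argsort(keys)
    skeys = keys[order]
    np_pairs = 0
    one = np.int64(1)
    for i in range(n_cyl):
        ix = np.int64(np.floor(pos[i, 0] / cell)) + K
        iy = np.int64(np.floor(pos[i, 1] / cell)) + K
        iz = np.int64(np.floor(pos[i, 2] / cell)) + K
        for dx in range(-1, 2):
            for dy in range(-1, 2):
                for dz in range(-1, 2):
                    key = ((ix + dx) << 42) | ((iy + dy) << 21) | (iz + dz)
                    lo = np.searchsorted(skeys, key)
                    j = lo
                    while j < n_cyl and skeys[j] == key:
                        jj = order[j]
                        if jj > i + n_ex:  # skip self/near-chain pairs
                            pairs_out[np_pairs, 0] = i
                            pairs_out[np_pairs, 1] = jj
                            np_pairs += 1
                        j += 1
    return np_pairs


# ---------------------------------------------------------------------------
# collision detection for the full scene
# ---------------------------------------------------------------------------


@njit(**NJIT_OPTS)
def detect_contacts(pos, R, radius, half_len, n_cyl, has_bead, plane_on,
                    cell, n_ex, pairs_buf,
                    con_b1, con_b2, con_pt, con_n, con_depth, max_con):
    """Fill contact arrays; returns number of contacts.

    Exclusions: chain-adjacent cylinder pairs, (first cylinder, plane),
    (last cylinder, bead).  con_b2 = -1 encodes the static plane.
    """
    nc = 0
    npair = broad_phase_pairs(pos, n_cyl, cell, n_ex, pairs_buf)
    for ip in range(npair):
        i = pairs_buf[ip, 0]
        j = pairs_buf[ip, 1]
        hit, pt, nrm, dep = capsule_capsule(
            pos[i], R[i][:, 2], half_len[i], radius[i],
            pos[j], R[j][:, 2], half_len[j], radius[j])
        if hit and nc < max_con:
            con_b1[nc] = i
            con_b2[nc] = j
            for k in range(3):
                con_pt[nc, k] = pt[k]
                con_n[nc, k] = nrm[k]
            con_depth[nc] = dep
            nc += 1
    if plane_on:
        for i in range(1, n_cyl):  # first cylinder is anchored to the plane
            hit, pt, nrm, dep = capsule_plane(pos[i], R[i][:, 2], half_len[i],
                                              radius[i])
            if hit and nc < max_con:
                con_b1[nc] = i
                con_b2[nc] = -1
                for k in range(3):
                    con_pt[nc, k] = pt[k]
                    con_n[nc, k] = nrm[k]
                con_depth[nc] = dep
                nc += 1
    if has_bead:
        ib = n_cyl
        for i in range(n_cyl - 1):  # last cylinder is attached to the bead
            hit, pt, nrm, dep = capsule_sphere(pos[i], R[i][:, 2], half_len[i],
                                               radius[i], pos[ib], radius[ib])
            if hit and nc < max_con:
                con_b1[nc] = i
                con_b2[nc] = ib
                for k in range(3):
                    con_pt[nc, k] = pt[k]
                    con_n[nc, k] = nrm[k]
                con_depth[nc] = dep
                nc += 1
        if plane_on:
            hit, pt, nrm, dep = sphere_plane(pos[ib], radius[ib])
            if hit and nc < max_con:
                con_b1[nc] = ib
                con_b2[nc] = -1
                for k in range(3):
                    con_pt[nc, k] = pt[k]
                    con_n[nc, k] = nrm[k]
                con_depth[nc] = dep
                nc += 1
    return nc


# ---------------------------------------------------------------------------
# constraint rows
# ---------------------------------------------------------------------------


@njit(**NJIT_OPTS)
def build_joint_rows(pos, quat, R, jkind, ja, jb, anc_a, anc_b, jq0,
                     psi, omega_clamp,
                     rbA, rbB, JA, JB, Cerr, kvel, lo_b):
    """Fill permanent-joint rows; returns the number of rows written."""
    nj = jkind.shape[0]
    r = 0
    for j in range(nj):
        kind = jkind[j]
        a = ja[j]
        b = jb[j]
        if kind == 0 or kind == 1:
            # ball part: world anchor positions and lever arms
            la = np.empty(3)
            pa = np.empty(3)
            for k in range(3):
                s = 0.0
                for kk in range(3):
                    s += R[a, k, kk] * anc_a[j, kk]
                la[k] = s
                pa[k] = pos[a, k] + s
            lb = np.zeros(3)
            pb = np.empty(3)
            if b >= 0:
                for k in range(3):
                    s = 0.0
                    for kk in range(3):
                        s += R[b, k, kk] * anc_b[j, kk]
                    lb[k] = s
                    pb[k] = pos[b, k] + s
            else:
                for k in range(3):
                    pb[k] = anc_b[j, k]
            for k in range(3):
                rbA[r + k] = a
                rbB[r + k] = b
                Cerr[r + k] = pa[k] - pb[k]
                kvel[r + k] = 0.0
                lo_b[r + k] = -1.0e300
                for c in range(6):
                    JA[r + k, c] = 0.0
                    JB[r + k, c] = 0.0
                JA[r + k, k] = 1.0
                if b >= 0:
                    JB[r + k, k] = -1.0
            # angular blocks: -skew(la) on a, +skew(lb) on b
            JA[r + 0, 4] = la[2]
            JA[r + 0, 5] = -la[1]
            JA[r + 1, 3] = -la[2]
            JA[r + 1, 5] = la[0]
            JA[r + 2, 3] = la[1]
            JA[r + 2, 4] = -la[0]
            if b >= 0:
                JB[r + 0, 4] = -lb[2]
                JB[r + 0, 5] = lb[1]
                JB[r + 1, 3] = lb[2]
                JB[r + 1, 5] = -lb[0]
                JB[r + 2, 3] = -lb[1]
                JB[r + 2, 4] = lb[0]
            r += 3
            if kind == 1:
                # orientation rows: q_a = q_b (x) q0  (or q_a = q0 vs world)
                if b >= 0:
                    qt = quat_mul(quat[b], jq0[j])
                else:
                    qt = jq0[j].copy()
                qe = quat_mul(quat[a], quat_conj(qt))
                ce = rotvec_from_quat(qe)
                for k in range(3):
                    rbA[r + k] = a
                    rbB[r + k] = b
                    Cerr[r + k] = ce[k]
                    kvel[r + k] = 0.0
                    lo_b[r + k] = -1.0e300
                    for c in range(6):
                        JA[r + k, c] = 0.0
                        JB[r + k, c] = 0.0
                    JA[r + k, 3 + k] = 1.0
                    if b >= 0:
                        JB[r + k, 3 + k] = -1.0
                r += 3
        elif kind == 2:
            # bead orientation clamp: target Rz(psi) (x) q0, driven at omega_clamp
            qz = np.empty(4)
            qz[0] = np.cos(0.5 * psi)
            qz[1] = 0.0
            qz[2] = 0.0
            qz[3] = np.sin(0.5 * psi)
            qt = quat_mul(qz, jq0[j])
            qe = quat_mul(quat[a], quat_conj(qt))
            ce = rotvec_from_quat(qe)
            for k in range(3):
                rbA[r + k] = a
                rbB[r + k] = -1
                Cerr[r + k] = ce[k]
                kvel[r + k] = 0.0
                lo_b[r + k] = -1.0e300
                for c in range(6):
                    JA[r + k, c] = 0.0
                    JB[r + k, c] = 0.0
                JA[r + k, 3 + k] = 1.0
            kvel[r + 2] = omega_clamp
            r += 3
        else:
            # x/y lock: bead material z axis stays along world z
            az = np.empty(3)
            for k in range(3):
                az[k] = R[a, k, 2]
            # rows: C = (a.ex, a.ey); J_ang = (a x ex)^T, (a x ey)^T
            ex = np.zeros(3)
            ex[0] = 1.0
            ey = np.zeros(3)
            ey[1] = 1.0
            j1 = cross3(az, ex)
            j2 = cross3(az, ey)
            for k in range(2):
                rbA[r + k] = a
                rbB[r + k] = -1
                kvel[r + k] = 0.0
                lo_b[r + k] = -1.0e300
                for c in range(6):
                    JA[r + k, c] = 0.0
                    JB[r + k, c] = 0.0
            Cerr[r] = az[0]
            Cerr[r + 1] = az[1]
            for k in range(3):
                JA[r, 3 + k] = j1[k]
                JA[r + 1, 3 + k] = j2[k]
            r += 2
    return r


@njit(**NJIT_OPTS)
def build_contact_rows(con_b1, con_b2, con_pt, con_n, con_depth, ncon, pos,
                       r0, rbA, rbB, JA, JB, Cerr, kvel, lo_b):
    """Append one non-penetration row per contact (lambda >= 0)."""
    for ic in range(ncon):
        r = r0 + ic
        b1 = con_b1[ic]
        b2 = con_b2[ic]
        rbA[r] = b1
        rbB[r] = b2
        kvel[r] = 0.0
        lo_b[r] = 0.0
        Cerr[r] = -con_depth[ic]
        r1 = np.empty(3)
        for k in range(3):
            r1[k] = con_pt[ic, k] - pos[b1, k]
        rxn1 = cross3(r1, con_n[ic])
        for k in range(3):
            JA[r, k] = con_n[ic, k]
            JA[r, 3 + k] = rxn1[k]
            JB[r, k] = 0.0
            JB[r, 3 + k] = 0.0
        if b2 >= 0:
            r2 = np.empty(3)
            for k in range(3):
                r2[k] = con_pt[ic, k] - pos[b2, k]
            rxn2 = cross3(r2, con_n[ic])
            for k in range(3):
                JB[r, k] = -con_n[ic, k]
                JB[r, 3 + k] = -rxn2[k]


# ---------------------------------------------------------------------------
# system assembly
# ---------------------------------------------------------------------------


@njit(**NJIT_OPTS)
def row_dot_u(r, rbA, rbB, JA, JB, vel, omg):
    s = 0.0
    a = rbA[r]
    b = rbB[r]
    if a >= 0:
        for k in range(3):
            s += JA[r, k] * vel[a, k] + JA[r, 3 + k] * omg[a, k]
    if b >= 0:
        for k in range(3):
            s += JB[r, k] * vel[b, k] + JB[r, 3 + k] * omg[b, k]
    return s


@njit(**NJIT_OPTS)
def row_pair_wprod(r, s, rbA, rbB, JA, JB, inv_mass, Iinv):
    """(J W^-1 J^T)_{rs}: sum over bodies shared by rows r and s."""
    out = 0.0
    for side_r in range(2):
        br = rbA[r] if side_r == 0 else rbB[r]
        if br < 0:
            continue
        Jr = JA if side_r == 0 else JB
        for side_s in range(2):
            bs = rbA[s] if side_s == 0 else rbB[s]
            if bs != br:
                continue
            Js = JA if side_s == 0 else JB
            acc = 0.0
            for k in range(3):
                acc += Jr[r, k] * Js[s, k] * inv_mass[br]
            for k in range(3):
                tmp = 0.0
                for kk in range(3):
                    tmp += Iinv[br, k, kk] * Js[s, 3 + kk]
                acc += Jr[r, 3 + k] * tmp
            out += acc
    return out


@njit(**NJIT_OPTS)
def assemble_banded(m, hb, rbA, rbB, JA, JB, inv_mass, Iinv, cfm_dt, ab):
    """Lower band storage ab[i-j, j] = A[i, j] for 0 <= i-j <= hb."""
    for j in range(m):
        for d in range(hb + 1):
            ab[d, j] = 0.0
    for rr in range(m):
        jlo = rr - hb
        if jlo < 0:
            jlo = 0
        for ss in range(jlo, rr + 1):
            v = row_pair_wprod(rr, ss, rbA, rbB, JA, JB, inv_mass, Iinv)
            if rr == ss:
                v += cfm_dt
            ab[rr - ss, ss] = v


@njit(**NJIT_OPTS)
def band_cholesky_solve(ab, hb, m, rhs, lam):
    """Solve A lam = rhs with A in lower-band storage (overwrites ab with L)."""
    for j in range(m):
        klo = j - hb
        if klo < 0:
            klo = 0
        s = ab[0, j]
        for k in range(klo, j):
            s -= ab[j - k, k] * ab[j - k, k]
        if s <= 0.0:
            return False
        ab[0, j] = np.sqrt(s)
        imax = j + hb
        if imax > m - 1:
            imax = m - 1
        for i in range(j + 1, imax + 1):
            s = ab[i - j, j]
            klo2 = i - hb
            if klo2 < klo:
                klo2 = klo
            if klo2 < 0:
                klo2 = 0
            for k in range(klo2, j):
                s -= ab[i - k, k] * ab[j - k, k]
            ab[i - j, j] = s / ab[0, j]
    # forward: L y = rhs
    for i in range(m):
        s = rhs[i]
        klo = i - hb
        if klo < 0:
            klo = 0
        for k in range(klo, i):
            s -= ab[i - k, k] * lam[k]
        lam[i] = s / ab[0, i]
    # backward: L^T x = y
    for i in range(m - 1, -1, -1):
        s = lam[i]
        imax = i + hb
        if imax > m - 1:
            imax = m - 1
        for k in range(i + 1, imax + 1):
            s -= ab[k - i, i] * lam[k]
        lam[i] = s / ab[0, i]
    return True


@njit(**NJIT_OPTS)
def assemble_dense(m, rbA, rbB, JA, JB, inv_mass, Iinv, cfm_dt, A):
    for i in range(m):
        for j in range(m):
            A[i, j] = 0.0
    for rr in range(m):
        for ss in range(rr + 1):
            # quick reject: no shared body
            share = ((rbA[rr] >= 0 and (rbA[rr] == rbA[ss] or rbA[rr] == rbB[ss]))
                     or (rbB[rr] >= 0 and (rbB[rr] == rbA[ss] or rbB[rr] == rbB[ss])))
            if not share:
                continue
            v = row_pair_wprod(rr, ss, rbA, rbB, JA, JB, inv_mass, Iinv)
            A[rr, ss] = v
            A[ss, rr] = v
        A[rr, rr] += cfm_dt
    return A


@njit(**NJIT_OPTS)
def solve_sor_dense(A, rhs, lo, m, omega, n_iter, lam):
    for i in range(m):
        lam[i] = 0.0
    for _ in range(n_iter):
        for i in range(m):
            s = rhs[i]
            for j in range(m):
                s -= A[i, j] * lam[j]
            li = lam[i] + omega * s / A[i, i]
            if li < lo[i]:
                li = lo[i]
            lam[i] = li
    return lam


@njit(**NJIT_OPTS)
def solve_active_set(A, rhs, lo, m, lam):
    """Direct mixed-LCP solve: equality rows free, bounded rows lo=0 active set.

    Returns True on success.  A must be SPD.
    """
    bounded = np.empty(m, dtype=np.bool_)
    active = np.empty(m, dtype=np.bool_)
    for i in range(m):
        bounded[i] = lo[i] > -1.0e299
        active[i] = True  # start with all rows in the solve
    max_outer = 3 * m + 10
    for _ in range(max_outer):
        # gather active set
        idx = np.empty(m, dtype=np.int64)
        na = 0
        for i in range(m):
            if active[i]:
                idx[na] = i
                na += 1
        Asub = np.empty((na, na))
        bsub = np.empty(na)
        for i in range(na):
            bsub[i] = rhs[idx[i]]
            for j in range(na):
                Asub[i, j] = A[idx[i], idx[j]]
        xsub = np.linalg.solve(Asub, bsub)
        for i in range(m):
            lam[i] = 0.0
        for i in range(na):
            lam[idx[i]] = xsub[i]
        # check primal feasibility of bounded active rows
        worst = -1
        worst_v = -1e-10
        for i in range(na):
            ii = idx[i]
            if bounded[ii] and xsub[i] < worst_v:
                worst_v = xsub[i]
                worst = ii
        if worst >= 0:
            active[worst] = False
            continue
        # check complementarity of released rows: w = (A lam - rhs) >= 0
        worst = -1
        worst_v = -1e-10
        for i in range(m):
            if bounded[i] and not active[i]:
                w = -rhs[i]
                for j in range(m):
                    w += A[i, j] * lam[j]
                if w < worst_v:
                    worst_v = w
                    worst = i
        if worst >= 0:
            active[worst] = True
            continue
        return True
    return False


@njit(**NJIT_OPTS)
def constraint_violation_metric(m, rbA, rbB, JA, JB, lam, rhs, A_used, dense,
                                lo, dt):
    """Predicted joint-separation growth |dt^2 (A lam - rhs)| with
    complementarity-aware handling of bounded rows."""
    worst = 0.0
    for i in range(m):
        w = -rhs[i]
        for j in range(m):
            w += A_used[i, j] * lam[j]
        if lo[i] > -1.0e299 and lam[i] <= 1e-14:
            if w < 0.0:
                v = -w
            else:
                v = 0.0
        else:
            v = abs(w)
        v *= dt * dt
        if v > worst:
            worst = v
    return worst


# ---------------------------------------------------------------------------
# thermostats
# ---------------------------------------------------------------------------


@njit(**NJIT_OPTS)
def add_local_langevin(vel, omg, mass, Ibody, R, gamma, kBT, dt, force, torque):
    """Friction -gamma*(M v), -gamma*(I w) plus FDT-matched Gaussian noise.

    Noise is generated per principal axis in the body frame (variance
    2 gamma kBT I_k / dt) and rotated to the world frame; draw order is fixed
    by body index for reproducibility.
    """
    nb = vel.shape[0]
    for i in range(nb):
        sl = np.sqrt(2.0 * gamma * kBT * mass[i] / dt)
        for k in range(3):
            force[i, k] += -gamma * mass[i] * vel[i, k] + sl * np.random.standard_normal()
        # world-frame I w  = R diag(Ib) R^T w
        wb = np.empty(3)
        for k in range(3):
            s = 0.0
            for kk in range(3):
                s += R[i, kk, k] * omg[i, kk]
            wb[k] = s
        tq_b = np.empty(3)
        for k in range(3):
            tq_b[k] = -gamma * Ibody[i, k] * wb[k] + \
                np.sqrt(2.0 * gamma * kBT * Ibody[i, k] / dt) * np.random.standard_normal()
        for k in range(3):
            s = 0.0
            for kk in range(3):
                s += R[i, k, kk] * tq_b[kk]
            torque[i, k] += s
    return


@njit(**NJIT_OPTS)
def kinetic_energy(vel, omg, mass, R, Ibody):
    nb = vel.shape[0]
    K = 0.0
    for i in range(nb):
        K += 0.5 * mass[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
        for k in range(3):
            s = 0.0
            for kk in range(3):
                s += R[i, kk, k] * omg[i, kk]
            K += 0.5 * Ibody[i, k] * s * s
    return K


@njit(**NJIT_OPTS)
def svr_alpha(K, ndof, kBT, gamma, dt):
    """Stochastic-velocity-rescaling factor (exact OU update of K over dt)."""
    if K < 1e-300:
        return 1.0
    c = np.exp(-gamma * dt)
    kbar_per_dof = 0.5 * kBT
    r1 = np.random.standard_normal()
    if ndof > 1:
        s2 = 2.0 * np.random.gamma(0.5 * (ndof - 1))
    else:
        s2 = 0.0
    fac = (1.0 - c) * kbar_per_dof / K
    a2 = c + fac * (r1 * r1 + s2) + 2.0 * r1 * np.sqrt(c * fac)
    if a2 < 0.0:
        a2 = 0.0
    alpha = np.sqrt(a2)
    # sign flip (astronomically rare in practice)
    if r1 + np.sqrt(c / fac) < 0.0:
        alpha = -alpha
    return alpha


# ---------------------------------------------------------------------------
# main step loop
# ---------------------------------------------------------------------------


@njit(**NJIT_OPTS)
def run_loop(pos, quat, vel, omg, mass, Ibody, radius, half_len,
             n_cyl, has_bead,
             jkind, ja, jb, anc_a, anc_b, jq0,
             g_b, g_t, tw_cum,
             thermo_mode, gamma, kBT, ndof,
             erp, cfm, sor_omega, sor_iters, accept_tol, force_direct,
             collisions_on, plane_on, cell, n_ex,
             dt, n_steps,
             fz_bead, torque_z, tip_force,
             psi0, omega_clamp,
             stride, rec_t, rec_zend, rec_ree, rec_ekin, rec_maxc,
             rec_ncon, rec_sigma_angle, rec_twist, rec_maxdepth, rec_solver,
             record_frames, frec_pos, frec_quat,
             bead_angle_state, t_state):
    """Advance n_steps; record every `stride` steps.  Returns status code
    (0 ok, 1 NaN abort, 2 solver failure)."""
    nb = pos.shape[0]
    # row capacity
    m_perm = 0
    for j in range(jkind.shape[0]):
        if jkind[j] == 0:
            m_perm += 3
        elif jkind[j] == 1:
            m_perm += 6
        elif jkind[j] == 2:
            m_perm += 3
        else:
            m_perm += 2
    max_con = 8 * nb + 8
    m_max = m_perm + max_con
    rbA = np.empty(m_max, dtype=np.int64)
    rbB = np.empty(m_max, dtype=np.int64)
    JA = np.zeros((m_max, 6))
    JB = np.zeros((m_max, 6))
    Cerr = np.zeros(m_max)
    kvel = np.zeros(m_max)
    lo_b = np.zeros(m_max)
    lam = np.zeros(m_max)
    rhs = np.zeros(m_max)
    # banded storage for the contact-free path
    # half bandwidth from permanent joint structure
    hb = 5
    r0j = np.empty(jkind.shape[0] + 1, dtype=np.int64)
    r0j[0] = 0
    for j in range(jkind.shape[0]):
        nrj = 3
        if jkind[j] == 1:
            nrj = 6
        elif jkind[j] == 2:
            nrj = 3
        elif jkind[j] == 3:
            nrj = 2
        r0j[j + 1] = r0j[j] + nrj
    for j in range(jkind.shape[0] - 1):
        span = r0j[j + 2] - 1 - r0j[j]
        if span > hb:
            hb = span
    ab = np.zeros((hb + 1, m_perm))
    Adense = np.zeros((m_max, m_max))
    pairs_buf = np.empty((nb * 32 + 64, 2), dtype=np.int64)
    con_b1 = np.empty(max_con, dtype=np.int64)
    con_b2 = np.empty(max_con, dtype=np.int64)
    con_pt = np.empty((max_con, 3))
    con_n = np.empty((max_con, 3))
    con_depth = np.empty(max_con)

    Rm = np.empty((nb, 3, 3))
    Iinv = np.empty((nb, 3, 3))
    inv_mass = np.empty(nb)
    for i in range(nb):
        inv_mass[i] = 1.0 / mass[i]
    force = np.zeros((nb, 3))
    torque = np.zeros((nb, 3))
    vfree = np.empty((nb, 3))
    wfree = np.empty((nb, 3))
    cfm_dt = cfm / dt
    irec = 0
    status = 0

    for istep in range(n_steps):
        t_local = t_state[0]
        compute_frames(quat, Rm)
        world_inertia_inv(Rm, Ibody, Iinv)
        # ---- external forces -------------------------------------------
        for i in range(nb):
            for k in range(3):
                force[i, k] = 0.0
                torque[i, k] = 0.0
        add_elastic_torques(Rm, n_cyl, g_b, g_t, torque)
        # gyroscopic term  -w x (I w)
        for i in range(nb):
            Iw = np.empty(3)
            for k in range(3):
                s = 0.0
                for kk in range(3):
                    s += Rm[i, kk, k] * omg[i, kk]
                Iw[k] = Ibody[i, k] * s
            Iww = np.empty(3)
            for k in range(3):
                s = 0.0
                for kk in range(3):
                    s += Rm[i, k, kk] * Iw[kk]
                Iww[k] = s
            gy = cross3(omg[i], Iww)
            for k in range(3):
                torque[i, k] -= gy[k]
        if has_bead:
            force[n_cyl, 2] += fz_bead
            torque[n_cyl, 2] += torque_z
        elif tip_force:
            # stretching force applied at the free tip of the last cylinder
            i = n_cyl - 1
            tipv = np.empty(3)
            for k in range(3):
                tipv[k] = half_len[i] * Rm[i, k, 2]
            force[i, 2] += fz_bead
            tq = cross3(tipv, np.array([0.0, 0.0, fz_bead]))
            for k in range(3):
                torque[i, k] += tq[k]
        if thermo_mode == 1:
            add_local_langevin(vel, omg, mass, Ibody, Rm, gamma, kBT, dt,
                               force, torque)
        # ---- collisions -------------------------------------------------
        ncon = 0
        maxdepth = 0.0
        if collisions_on:
            ncon = detect_contacts(pos, Rm, radius, half_len, n_cyl, has_bead,
                                   plane_on, cell, n_ex, pairs_buf,
                                   con_b1, con_b2, con_pt, con_n, con_depth,
                                   max_con)
            for ic in range(ncon):
                if con_depth[ic] > maxdepth:
                    maxdepth = con_depth[ic]
        # ---- constraint rows -------------------------------------------
        psi = psi0 + omega_clamp * t_local
        m_joint = build_joint_rows(pos, quat, Rm, jkind, ja, jb, anc_a, anc_b,
                                   jq0, psi, omega_clamp,
                                   rbA, rbB, JA, JB, Cerr, kvel, lo_b)
        build_contact_rows(con_b1, con_b2, con_pt, con_n, con_depth, ncon,
                           pos, m_joint, rbA, rbB, JA, JB, Cerr, kvel, lo_b)
        m = m_joint + ncon
        maxc = 0.0
        for r in range(m_joint):
            if abs(Cerr[r]) > maxc:
                maxc = abs(Cerr[r])
        # ---- unconstrained velocity update ------------------------------
        for i in range(nb):
            for k in range(3):
                vfree[i, k] = vel[i, k] + dt * force[i, k] * inv_mass[i]
            for k in range(3):
                s = 0.0
                for kk in range(3):
                    s += Iinv[i, k, kk] * torque[i, kk]
                wfree[i, k] = omg[i, k] + dt * s
        solver_used = 0
        if m > 0:
            for r in range(m):
                rhs[r] = kvel[r] / dt - erp * Cerr[r] / (dt * dt) \
                    - row_dot_u(r, rbA, rbB, JA, JB, vfree, wfree) / dt
            if ncon == 0 and not force_direct:
                assemble_banded(m, hb, rbA, rbB, JA, JB, inv_mass, Iinv,
                                cfm_dt, ab)
                ok = band_cholesky_solve(ab, hb, m, rhs[:m], lam)
                if not ok:
                    status = 2
                    break
                solver_used = 0
            else:
                assemble_dense(m, rbA, rbB, JA, JB, inv_mass, Iinv, cfm_dt,
                               Adense)
                if force_direct:
                    ok = solve_active_set(Adense, rhs, lo_b, m, lam)
                    solver_used = 2
                    if not ok:
                        status = 2
                        break
                else:
                    solve_sor_dense(Adense, rhs, lo_b, m, sor_omega,
                                    sor_iters, lam)
                    solver_used = 1
                    viol = constraint_violation_metric(
                        m, rbA, rbB, JA, JB, lam, rhs, Adense, True, lo_b, dt)
                    if viol > accept_tol:
                        ok = solve_active_set(Adense, rhs, lo_b, m, lam)
                        solver_used = 2
                        if not ok:
                            status = 2
                            break
            # apply constraint impulses
            for r in range(m):
                a = rbA[r]
                b = rbB[r]
                if a >= 0:
                    for k in range(3):
                        vfree[a, k] += dt * inv_mass[a] * JA[r, k] * lam[r]
                    for k in range(3):
                        s = 0.0
                        for kk in range(3):
                            s += Iinv[a, k, kk] * JA[r, 3 + kk]
                        wfree[a, k] += dt * s * lam[r]
                if b >= 0:
                    for k in range(3):
                        vfree[b, k] += dt * inv_mass[b] * JB[r, k] * lam[r]
                    for k in range(3):
                        s = 0.0
                        for kk in range(3):
                            s += Iinv[b, k, kk] * JB[r, 3 + kk]
                        wfree[b, k] += dt * s * lam[r]
        # ---- commit velocities, positions, orientations -----------------
        bad = False
        for i in range(nb):
            for k in range(3):
                if not np.isfinite(vfree[i, k]) or not np.isfinite(wfree[i, k]):
                    bad = True
        if bad:
            status = 1
            break
        for i in range(nb):
            for k in range(3):
                vel[i, k] = vfree[i, k]
                omg[i, k] = wfree[i, k]
                pos[i, k] += dt * vel[i, k]
            quat[i] = exp_map_update(quat[i], omg[i], dt)
        # ---- global thermostat: exact rescale of the updated velocities --
        if thermo_mode == 2:
            compute_frames(quat, Rm)
            K = kinetic_energy(vel, omg, mass, Rm, Ibody)
            alpha = svr_alpha(K, ndof, kBT, gamma, dt)
            for i in range(nb):
                for k in range(3):
                    vel[i, k] *= alpha
                    omg[i, k] *= alpha
        # ---- bookkeeping -------------------------------------------------
        compute_frames(quat, Rm)
        update_cumulative_twists(Rm, n_cyl, tw_cum)
        if has_bead:
            # bead_angle_state: [cumulative angle, previous yaw, init flag]
            yaw = np.arctan2(Rm[n_cyl, 1, 0], Rm[n_cyl, 0, 0])
            if bead_angle_state[2] > 0.5:
                bead_angle_state[0] += wrap_angle(yaw - bead_angle_state[1])
            else:
                bead_angle_state[2] = 1.0
            bead_angle_state[1] = yaw
        t_state[0] += dt
        if stride > 0 and (istep + 1) % stride == 0:
            K = kinetic_energy(vel, omg, mass, Rm, Ibody)
            # chain end vertex (tip of the last cylinder)
            i = n_cyl - 1
            zend = pos[i, 2] + half_len[i] * Rm[i, 2, 2]
            ex = pos[i, 0] + half_len[i] * Rm[i, 0, 2]
            ey = pos[i, 1] + half_len[i] * Rm[i, 1, 2]
            x0 = pos[0, 0] - half_len[0] * Rm[0, 0, 2]
            y0 = pos[0, 1] - half_len[0] * Rm[0, 1, 2]
            z0 = pos[0, 2] - half_len[0] * Rm[0, 2, 2]
            ree = np.sqrt((ex - x0) ** 2 + (ey - y0) ** 2 + (zend - z0) ** 2)
            tw = 0.0
            for jj in range(n_cyl - 1):
                tw += tw_cum[jj]
            if irec < rec_t.shape[0]:
                rec_t[irec] = t_state[0]
                rec_zend[irec] = zend
                rec_ree[irec] = ree
                rec_ekin[irec] = K
                rec_maxc[irec] = maxc
                rec_ncon[irec] = ncon
                rec_sigma_angle[irec] = bead_angle_state[0]
                rec_twist[irec] = tw
                rec_maxdepth[irec] = maxdepth
                rec_solver[irec] = solver_used
                if record_frames:
                    for i2 in range(nb):
                        for k in range(3):
                            frec_pos[irec, i2, k] = pos[i2, k]
                        for k in range(4):
                            frec_quat[irec, i2, k] = quat[i2, k]
                irec += 1
    return status


@njit(**NJIT_OPTS)
def seed_rng(seed):
    np.random.seed(seed)
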