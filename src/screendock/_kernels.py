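"""Compiled numerical kernels for pose geometry and scoring.

These are the innermost loops of the search: applying a genome to ligand
coordinates, trilinear grid interpolation, and the pairwise internal
energy.  They are compiled with numba in nopython mode (no fastmath, so
results are bit-reproducible) and release the GIL so concurrent GA runs can
overlap.

The genome vector layout is ``[tx, ty, tz, qw, qx, qy, qz, tor_1..tor_T]``
with torsions in degrees relative to the input conformation.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

OUT_OF_GRID_PENALTY = 1.0e5  # kcal/mol per atom outside the box
COULOMB_K = 332.0636  # kcal Å / (mol e^2)
MIN_PAIR_DISTANCE = 0.01  # Å floor to keep internal terms finite


@njit(cache=False, nogil=True)
def trilinear_kernel(values, ox, oy, oz, spacing, npts, px, py, pz):
    """Trilinear blend of the 8 lattice corners surrounding (px,py,pz);
    returns the out-of-grid penalty for points outside the box."""
    fx = (px - ox) / spacing
    fy = (py - oy) / spacing
    fz = (pz - oz) / spacing
    if fx < 0.0 or fy < 0.0 or fz < 0.0 or fx > npts or fy > npts or fz > npts:
        return OUT_OF_GRID_PENALTY
    ix = int(math.floor(fx))
    iy = int(math.floor(fy))
    iz = int(math.floor(fz))
    if ix >= npts:
        ix = npts - 1
    if iy >= npts:
        iy = npts - 1
    if iz >= npts:
        iz = npts - 1
    tx = fx - ix
    ty = fy - iy
    tz = fz - iz
    c000 = values[ix, iy, iz]
    c100 = values[ix + 1, iy, iz]
    c010 = values[ix, iy + 1, iz]
    c110 = values[ix + 1, iy + 1, iz]
    c001 = values[ix, iy, iz + 1]
    c101 = values[ix + 1, iy, iz + 1]
    c011 = values[ix, iy + 1, iz + 1]
    c111 = values[ix + 1, iy + 1, iz + 1]
    c00 = c000 * (1.0 - tx) + c100 * tx
    c10 = c010 * (1.0 - tx) + c110 * tx
    c01 = c001 * (1.0 - tx) + c101 * tx
    c11 = c011 * (1.0 - tx) + c111 * tx
    c0 = c00 * (1.0 - ty) + c10 * ty
    c1 = c01 * (1.0 - ty) + c11 * ty
    return c0 * (1.0 - tz) + c1 * tz


@njit(cache=False, nogil=True)
def apply_state_kernel(vec, base, root_centroid, tor_a, tor_b, tor_moved, out):
    """Apply a genome vector to base coordinates.

    Torsions are applied root-outward (parse order), each rotating its
    moved-set about the current proximal->distal bond axis by the gene angle
    (right-hand rule looking from proximal to distal).  The whole body is
    then rotated by the genome quaternion about the root-group centroid and
    translated so that centroid lands at the genome translation.
    """
    n = base.shape[0]
    ntor = tor_a.shape[0]
    for i in range(n):
        out[i, 0] = base[i, 0]
        out[i, 1] = base[i, 1]
        out[i, 2] = base[i, 2]
    for t in range(ntor):
        angle = vec[7 + t] * math.pi / 180.0
        if angle == 0.0:
            continue
        a = tor_a[t]
        b = tor_b[t]
        axx = out[b, 0] - out[a, 0]
        axy = out[b, 1] - out[a, 1]
        axz = out[b, 2] - out[a, 2]
        norm = math.sqrt(axx * axx + axy * axy + axz * axz)
        if norm == 0.0:
            continue
        axx /= norm
        axy /= norm
        axz /= norm
        c = math.cos(angle)
        s = math.sin(angle)
        for i in range(n):
            if not tor_moved[t, i]:
                continue
            vx = out[i, 0] - out[a, 0]
            vy = out[i, 1] - out[a, 1]
            vz = out[i, 2] - out[a, 2]
            # Rodrigues rotation about (axx,axy,axz)
            dot = axx * vx + axy * vy + axz * vz
            crx = axy * vz - axz * vy
            cry = axz * vx - axx * vz
            crz = axx * vy - axy * vx
            rx = vx * c + crx * s + axx * dot * (1.0 - c)
            ry = vy * c + cry * s + axy * dot * (1.0 - c)
            rz = vz * c + crz * s + axz * dot * (1.0 - c)
            out[i, 0] = out[a, 0] + rx
            out[i, 1] = out[a, 1] + ry
            out[i, 2] = out[a, 2] + rz
    # rigid-body rotation (unit quaternion, renormalized defensively)
    qw = vec[3]
    qx = vec[4]
    qy = vec[5]
    qz = vec[6]
    qn = math.sqrt(qw * qw + qx * qx + qy * qy + qz * qz)
    if qn > 0.0:
        qw /= qn
        qx /= qn
        qy /= qn
        qz /= qn
    r00 = 1.0 - 2.0 * (qy * qy + qz * qz)
    r01 = 2.0 * (qx * qy - qz * qw)
    r02 = 2.0 * (qx * qz + qy * qw)
    r10 = 2.0 * (qx * qy + qz * qw)
    r11 = 1.0 - 2.0 * (qx * qx + qz * qz)
    r12 = 2.0 * (qy * qz - qx * qw)
    r20 = 2.0 * (qx * qz - qy * qw)
    r21 = 2.0 * (qy * qz + qx * qw)
    r22 = 1.0 - 2.0 * (qx * qx + qy * qy)
    cx = root_centroid[0]
    cy = root_centroid[1]
    cz = root_centroid[2]
    tx = vec[0]
    ty = vec[1]
    tz = vec[2]
    for i in range(n):
        vx = out[i, 0] - cx
        vy = out[i, 1] - cy
        vz = out[i, 2] - cz
        out[i, 0] = r00 * vx + r01 * vy + r02 * vz + tx
        out[i, 1] = r10 * vx + r11 * vy + r12 * vz + ty
        out[i, 2] = r20 * vx + r21 * vy + r22 * vz + tz


@njit(cache=False, nogil=True)
def apply_delta_kernel(vec, delta, out):
    """Perturb a genome vector by a local-search delta
    ``[dt(3), rotation-vector(3), dtorsions(T)]``; the quaternion is
    composed with the rotation vector's axis-angle quaternion and
    renormalized, torsions are wrapped into (-180, 180]."""
    n = vec.shape[0]
    for i in range(n):
        out[i] = vec[i]
    out[0] = vec[0] + delta[0]
    out[1] = vec[1] + delta[1]
    out[2] = vec[2] + delta[2]
    rx = delta[3]
    ry = delta[4]
    rz = delta[5]
    angle = math.sqrt(rx * rx + ry * ry + rz * rz)
    if angle > 0.0:
        half = 0.5 * angle
        s = math.sin(half) / angle
        dw = math.cos(half)
        dx = rx * s
        dy = ry * s
        dz = rz * s
        qw = vec[3]
        qx = vec[4]
        qy = vec[5]
        qz = vec[6]
        nw = dw * qw - dx * qx - dy * qy - dz * qz
        nx = dw * qx + dx * qw + dy * qz - dz * qy
        ny = dw * qy - dx * qz + dy * qw + dz * qx
        nz = dw * qz + dx * qy - dy * qx + dz * qw
        norm = math.sqrt(nw * nw + nx * nx + ny * ny + nz * nz)
        out[3] = nw / norm
        out[4] = nx / norm
        out[5] = ny / norm
        out[6] = nz / norm
    for t in range(n - 7):
        v = vec[7 + t] + delta[6 + t]
        v = (v + 180.0) % 360.0 - 180.0
        if v == -180.0:
            v = 180.0
        out[7 + t] = v


@njit(cache=False, nogil=True)
def intermolecular_kernel(coords, charges, map_index, maps, e_idx, d_idx,
                          ox, oy, oz, spacing, npts):
    """Grid score: per atom, affinity + q*electrostatic + |q|*desolvation,
    each trilinearly interpolated; atoms outside the box contribute the
    out-of-grid penalty once."""
    total = 0.0
    n = coords.shape[0]
    for i in range(n):
        px = coords[i, 0]
        py = coords[i, 1]
        pz = coords[i, 2]
        fx = (px - ox) / spacing
        fy = (py - oy) / spacing
        fz = (pz - oz) / spacing
        if (fx < 0.0 or fy < 0.0 or fz < 0.0
                or fx > npts or fy > npts or fz > npts):
            total += OUT_OF_GRID_PENALTY
            continue
        q = charges[i]
        total += trilinear_kernel(maps[map_index[i]], ox, oy, oz,
                                  spacing, npts, px, py, pz)
        total += q * trilinear_kernel(maps[e_idx], ox, oy, oz,
                                      spacing, npts, px, py, pz)
        total += abs(q) * trilinear_kernel(maps[d_idx], ox, oy, oz,
                                           spacing, npts, px, py, pz)
    return total


@njit(cache=False, nogil=True)
def internal_kernel(coords, charges, pair_i, pair_j, pair_eps, pair_sig):
    """12-6 Lennard-Jones plus distance-dependent-dielectric Coulomb
    (eps_r = 4r) summed over precomputed eligible pairs."""
    total = 0.0
    for k in range(pair_i.shape[0]):
        i = pair_i[k]
        j = pair_j[k]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r < MIN_PAIR_DISTANCE:
            r = MIN_PAIR_DISTANCE
        sr = pair_sig[k] / r
        sr6 = sr * sr * sr * sr * sr * sr
        total += 4.0 * pair_eps[k] * (sr6 * sr6 - sr6)
        total += COULOMB_K * charges[i] * charges[j] / (4.0 * r * r)
    return total


@njit(cache=False, nogil=True)
def score_pose_kernel(vec, base, root_centroid, tor_a, tor_b, tor_moved,
                      charges, map_index, maps, e_idx, d_idx,
                      ox, oy, oz, spacing, npts,
                      pair_i, pair_j, pair_eps, pair_sig, scratch):
    """Full pose score; returns (intermolecular, internal)."""
    apply_state_kernel(vec, base, root_centroid, tor_a, tor_b, tor_moved,
                       scratch)
    inter = intermolecular_kernel(scratch, charges, map_index, maps,
                                  e_idx, d_idx, ox, oy, oz, spacing, npts)
    intra = internal_kernel(scratch, charges, pair_i, pair_j,
                            pair_eps, pair_sig)
    return inter, intra


@njit(cache=False, nogil=True)
def score_population_kernel(pop, base, root_centroid, tor_a, tor_b, tor_moved,
                            charges, map_index, maps, e_idx, d_idx,
                            ox, oy, oz, spacing, npts,
                            pair_i, pair_j, pair_eps, pair_sig,
                            scratch, out_inter, out_intra):
    for p in range(pop.shape[0]):
        inter, intra = score_pose_kernel(
            pop[p], base, root_centroid, tor_a, tor_b, tor_moved,
            charges, map_index, maps, e_idx, d_idx,
            ox, oy, oz, spacing, npts,
            pair_i, pair_j, pair_eps, pair_sig, scratch)
        out_inter[p] = inter
        out_intra[p] = intra
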