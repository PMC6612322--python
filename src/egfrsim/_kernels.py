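"""Numba kernels for the hot Brownian-Dynamics loops.

All kernels are deterministic: every random number they consume is drawn
beforehand from a numpy Generator and passed in as an array, so bit-level
reproducibility is governed entirely by the seed plumbing in the callers.

Species codes used throughout: 0=Ras, 1=Raf, 2=ERK, 3=TF.
"""

from __future__ import annotations

import numpy as np
from numba import njit

SP_RAS = 0
SP_RAF = 1
SP_ERK = 2
SP_TF = 3

_MAX_REFLECT = 64


@njit(cache=True, inline="always")
def _reflect_scale(rho: float, r_in: float, r_out: float) -> float:
    """Return the signed factor mapping radius ``rho`` into ``[r_in, r_out]``.

    Mirror reflection across whichever spherical boundary is violated,
    iterated so that steps larger than the shell thickness are folded back.
    A negative factor means the reflected ray passes through the centre.
    """
    s = rho
    for _ in range(_MAX_REFLECT):
        a = abs(s)
        if a > r_out:
            s = (2.0 * r_out - a) * (1.0 if s >= 0 else -1.0)
        elif a < r_in:
            s = (2.0 * r_in - a) * (1.0 if s >= 0 else -1.0)
        else:
            return s / rho
    # Pathological step size: clamp to the nearer boundary.
    a = abs(s)
    tgt = r_out if a > r_out else r_in
    return tgt / rho


@njit(cache=True)
def reflect_shell_inplace(q: np.ndarray, r_in: float, r_out: float) -> None:
    """Reflect centred points ``q`` (n, 3) into the shell ``[r_in, r_out]``."""
    n = q.shape[0]
    for i in range(n):
        x, y, z = q[i, 0], q[i, 1], q[i, 2]
        rho = np.sqrt(x * x + y * y + z * z)
        if r_in <= rho <= r_out:
            continue
        if rho == 0.0:
            # direction undefined; place on the inner boundary
            q[i, 0] = r_in
            continue
        f = _reflect_scale(rho, r_in, r_out)
        q[i, 0] = x * f
        q[i, 1] = y * f
        q[i, 2] = z * f


@njit(cache=True)
def step_interior(
    pos: np.ndarray,        # (n, 3) cell-local coordinates, modified in place
    species: np.ndarray,    # (n,) int8
    active: np.ndarray,     # (n,) bool — states at step entry (synchronous update)
    erk_free: np.ndarray,   # (n,) bool — ERK allowed in the whole cell
    disp: np.ndarray,       # (n, 3) pre-drawn Brownian displacements
    r_nuc: float,
    r_cell: float,
    rec_c: np.ndarray,      # (m, 3) receptor inner-sphere centres (cell-local)
    rec_on: np.ndarray,     # (m,) bool
    d2_rec: float,          # squared Ras–receptor reaction distance
    d2_pp: float,           # squared protein–protein reaction distance
    new_idx: np.ndarray,    # (n,) int64 output buffer
) -> int:
    """One BD step of a cell interior: diffuse, reflect, fire activations.

    Returns the number of newly activated molecules; their indices are
    written to ``new_idx``.  Activation uses the states held at entry, so a
    molecule switched on in this step does not activate others until the
    next step.  Switch-offs are handled by the caller.
    """
    n = pos.shape[0]
    m = rec_c.shape[0]
    r_nuc2 = r_nuc * r_nuc

    # (a) diffuse and reflect into each molecule's diffusion domain
    for i in range(n):
        x = pos[i, 0] + disp[i, 0]
        y = pos[i, 1] + disp[i, 1]
        z = pos[i, 2] + disp[i, 2]
        sp = species[i]
        if sp == SP_TF:
            r_lo, r_hi = 0.0, r_nuc
        elif sp == SP_ERK and (active[i] or erk_free[i]):
            r_lo, r_hi = 0.0, r_cell
        else:
            r_lo, r_hi = r_nuc, r_cell
        rho2 = x * x + y * y + z * z
        if rho2 > r_hi * r_hi or rho2 < r_lo * r_lo:
            rho = np.sqrt(rho2)
            if rho == 0.0:
                x = r_lo
            else:
                f = _reflect_scale(rho, r_lo, r_hi)
                x *= f
                y *= f
                z *= f
        pos[i, 0] = x
        pos[i, 1] = y
        pos[i, 2] = z
        # an inactive ERK that has left the nucleus becomes cytoplasm-confined
        if sp == SP_ERK and erk_free[i] and not active[i]:
            if x * x + y * y + z * z >= r_nuc2:
                erk_free[i] = False

    # gather activator positions (states at entry)
    n_ras = 0
    n_raf = 0
    n_erk = 0
    ras_on = np.empty(n, dtype=np.int64)
    raf_on = np.empty(n, dtype=np.int64)
    erk_on = np.empty(n, dtype=np.int64)
    for i in range(n):
        if active[i]:
            sp = species[i]
            if sp == SP_RAS:
                ras_on[n_ras] = i
                n_ras += 1
            elif sp == SP_RAF:
                raf_on[n_raf] = i
                n_raf += 1
            elif sp == SP_ERK:
                erk_on[n_erk] = i
                n_erk += 1

    # (b) bimolecular activations on reaction-radius overlap
    n_new = 0
    for i in range(n):
        if active[i]:
            continue
        sp = species[i]
        hit = False
        xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
        if sp == SP_RAS:
            for k in range(m):
                if not rec_on[k]:
                    continue
                dx = xi - rec_c[k, 0]
                dy = yi - rec_c[k, 1]
                dz = zi - rec_c[k, 2]
                if dx * dx + dy * dy + dz * dz <= d2_rec:
                    hit = True
                    break
        elif sp == SP_RAF:
            for k in range(n_ras):
                j = ras_on[k]
                dx = xi - pos[j, 0]
                dy = yi - pos[j, 1]
                dz = zi - pos[j, 2]
                if dx * dx + dy * dy + dz * dz <= d2_pp:
                    hit = True
                    break
        elif sp == SP_ERK:
            for k in range(n_raf):
                j = raf_on[k]
                dx = xi - pos[j, 0]
                dy = yi - pos[j, 1]
                dz = zi - pos[j, 2]
                if dx * dx + dy * dy + dz * dz <= d2_pp:
                    hit = True
                    break
        else:  # TF
            for k in range(n_erk):
                j = erk_on[k]
                dx = xi - pos[j, 0]
                dy = yi - pos[j, 1]
                dz = zi - pos[j, 2]
                if dx * dx + dy * dy + dz * dz <= d2_pp:
                    hit = True
                    break
        if hit:
            new_idx[n_new] = i
            n_new += 1
    return n_new


@njit(cache=True)
def step_egf(
    pos: np.ndarray,       # (k, 3) free-EGF positions, modified in place
    disp: np.ndarray,      # (k, 3) pre-drawn displacements
    r_dom: float,
    cell_c: np.ndarray,    # (c, 3) cell centres
    cell_r: np.ndarray,    # (c,) cell radii
) -> None:
    """Diffuse free EGF; reflect at the outer domain boundary and off cells."""
    k = pos.shape[0]
    c = cell_c.shape[0]
    for i in range(k):
        x = pos[i, 0] + disp[i, 0]
        y = pos[i, 1] + disp[i, 1]
        z = pos[i, 2] + disp[i, 2]
        for _ in range(8):
            clean = True
            rho2 = x * x + y * y + z * z
            if rho2 > r_dom * r_dom:
                rho = np.sqrt(rho2)
                f = _reflect_scale(rho, 0.0, r_dom)
                x *= f
                y *= f
                z *= f
                clean = False
            for j in range(c):
                dx = x - cell_c[j, 0]
                dy = y - cell_c[j, 1]
                dz = z - cell_c[j, 2]
                rj = cell_r[j]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < rj * rj:
                    d = np.sqrt(d2)
                    if d == 0.0:
                        # degenerate: eject radially in +x
                        dx, d = rj, rj
                        dy = 0.0
                        dz = 0.0
                    s = (2.0 * rj - d) / d
                    x = cell_c[j, 0] + dx * s
                    y = cell_c[j, 1] + dy * s
                    z = cell_c[j, 2] + dz * s
                    clean = False
            if clean:
                break
        pos[i, 0] = x
        pos[i, 1] = y
        pos[i, 2] = z


@njit(cache=True)
def overlap_pairs(
    egf_pos: np.ndarray,   # (k, 3)
    rec_pos: np.ndarray,   # (m, 3) receptor outer-sphere centres
    rec_off: np.ndarray,   # (m,) bool — candidate (inactive) receptors
    d2_bind: float,
    out_e: np.ndarray,     # output buffers, length >= k*m worst case
    out_r: np.ndarray,
    out_d2: np.ndarray,
) -> int:
    """Collect all (EGF, off-receptor) pairs whose reaction radii overlap."""
    cnt = 0
    for i in range(egf_pos.shape[0]):
        xi, yi, zi = egf_pos[i, 0], egf_pos[i, 1], egf_pos[i, 2]
        for j in range(rec_pos.shape[0]):
            if not rec_off[j]:
                continue
            dx = xi - rec_pos[j, 0]
            dy = yi - rec_pos[j, 1]
            dz = zi - rec_pos[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 <= d2_bind:
                out_e[cnt] = i
                out_r[cnt] = j
                out_d2[cnt] = d2
                cnt += 1
    return cnt


@njit(cache=True)
def any_near(
    egf_pos: np.ndarray, cell_c: np.ndarray, cell_r: np.ndarray, reach: float
) -> bool:
    """Early-exit test: is any particle within ``reach`` of any cell surface?"""
    for i in range(egf_pos.shape[0]):
        for j in range(cell_c.shape[0]):
            dx = egf_pos[i, 0] - cell_c[j, 0]
            dy = egf_pos[i, 1] - cell_c[j, 1]
            dz = egf_pos[i, 2] - cell_c[j, 2]
            lim = cell_r[j] + reach
            if dx * dx + dy * dy + dz * dz <= lim * lim:
                return True
    return False


@njit(cache=True)
def pairwise_forces(
    pos: np.ndarray,      # (c, 3)
    radii: np.ndarray,    # (c,) current cell radii
    nuc_radii: np.ndarray,  # (c,) incompressible radii
    K: float,
    forces: np.ndarray,   # (c, 3) output, zeroed by caller
) -> float:
    """Accumulate pairwise repulsive forces; return min(h_ij - (h0 - h1)).

    The force law diverges as cells approach hard-core contact
    ``h_ij -> h0 - h1``; the returned margin lets the caller monitor the
    hard-core invariant.  Distances inside the core are clamped just
    outside it to keep the force finite.
    """
    c = pos.shape[0]
    min_margin = 1.0e30
    for i in range(c):
        for j in range(i + 1, c):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            h = np.sqrt(dx * dx + dy * dy + dz * dz)
            h0 = radii[i] + radii[j]
            if h >= h0:
                continue
            core = h0 - (nuc_radii[i] + nuc_radii[j])
            margin = h - core
            if margin < min_margin:
                min_margin = margin
            if margin < 1.0e-9:
                h = core + 1.0e-9
                margin = 1.0e-9
            f = K * (h0 - h) / margin
            if h == 0.0:
                continue
            ux, uy, uz = dx / h, dy / h, dz / h
            forces[i, 0] += f * ux
            forces[i, 1] += f * uy
            forces[i, 2] += f * uz
            forces[j, 0] -= f * ux
            forces[j, 1] -= f * uy
            forces[j, 2] -= f * uz
    return min_margin
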