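"""Numba force and integration kernels.

All kernels work on plain numpy arrays in reduced units (m = kBT = 1).
`nb_kind` encodes the non-bonded role of each particle:
0 = mobile bead (sigma_pp/eps_pp), 1 = wall bead (sigma_pw/eps_pw against
mobile beads, inert among themselves), 2 = excluded from non-bonded terms
entirely (tether anchors).

The electrostatic solver implemented here is the damped shifted-force (DSF)
real-space Coulomb sum: both the energy and the force go continuously to
zero at the cutoff.  `rc <= 0` disables electrostatics.
"""

import math

import numpy as np
from numba import njit

WCA_CUT = 2.0 ** (1.0 / 6.0)
TWO_OVER_SQRTPI = 2.0 / math.sqrt(math.pi)


@njit(cache=True, inline="always")
def _mi(d, L):
    # minimum image for wrapped coordinates (|d| <= L)
    if d > 0.5 * L:
        d -= L
    elif d < -0.5 * L:
        d += L
    return d


@njit(cache=True)
def compute_forces(pos, charge, nb_kind, bonds, box,
                   eps_pp, sig_pp, eps_pw, sig_pw,
                   lam_b, alpha, rc,
                   k_bond, b0,
                   hw, pore_r, efield, field_on,
                   wall_on, head_idx, bar_eps, bar_sig,
                   excl_vol, F):
    """Fill F with forces; return the total potential energy."""
    n = pos.shape[0]
    Lx = box[0]
    Ly = box[1]
    Lz = box[2]
    for i in range(n):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0
    U = 0.0

    # DSF shift constants
    use_coul = rc > 0.0
    u_shift = 0.0
    f_shift = 0.0
    rc2 = 0.0
    if use_coul:
        erfc_rc = math.erfc(alpha * rc)
        u_shift = erfc_rc / rc
        f_shift = (erfc_rc / (rc * rc)
                   + TWO_OVER_SQRTPI * alpha * math.exp(-(alpha * rc) ** 2) / rc)
        rc2 = rc * rc
        # Wolf self term (constant; aligns the DSF energy with Ewald)
        q2 = 0.0
        for i in range(n):
            q2 += charge[i] * charge[i]
        U -= lam_b * (0.5 * u_shift + 0.5 * TWO_OVER_SQRTPI * alpha) * q2

    cut_pp = WCA_CUT * sig_pp
    cut_pw = WCA_CUT * sig_pw
    max_cut2 = max(cut_pp, cut_pw) ** 2
    if use_coul and rc2 > max_cut2:
        max_cut2 = rc2

    for i in range(n - 1):
        ki = nb_kind[i]
        if ki == 2:
            continue
        qi = charge[i]
        for j in range(i + 1, n):
            kj = nb_kind[j]
            if kj == 2:
                continue
            if ki == 1 and kj == 1:
                continue  # wall beads inert among themselves
            dx = _mi(pos[i, 0] - pos[j, 0], Lx)
            dy = _mi(pos[i, 1] - pos[j, 1], Ly)
            dz = _mi(pos[i, 2] - pos[j, 2], Lz)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > max_cut2:
                continue
            wall_pair = (ki == 1) or (kj == 1)
            if wall_pair:
                sig = sig_pw
                eps = eps_pw
                cut = cut_pw
            else:
                sig = sig_pp
                eps = eps_pp
                cut = cut_pp
            fr = 0.0  # force / r along the separation vector
            if (excl_vol or wall_pair) and r2 < cut * cut:
                inv_r2 = 1.0 / r2
                sr2 = sig * sig * inv_r2
                sr6 = sr2 * sr2 * sr2
                U += 4.0 * eps * (sr6 * sr6 - sr6) + eps
                fr += 24.0 * eps * (2.0 * sr6 * sr6 - sr6) * inv_r2
            if use_coul:
                qq = qi * charge[j]
                if qq != 0.0 and r2 < rc2:
                    r = math.sqrt(r2)
                    erfc_r = math.erfc(alpha * r)
                    pref = lam_b * qq
                    U += pref * (erfc_r / r - u_shift + f_shift * (r - rc))
                    fmag = pref * (erfc_r / r2
                                   + TWO_OVER_SQRTPI * alpha
                                   * math.exp(-(alpha * r) ** 2) / r
                                   - f_shift)
                    fr += fmag / r
            if fr != 0.0:
                F[i, 0] += fr * dx
                F[i, 1] += fr * dy
                F[i, 2] += fr * dz
                F[j, 0] -= fr * dx
                F[j, 1] -= fr * dy
                F[j, 2] -= fr * dz

    # harmonic bonds
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = _mi(pos[i, 0] - pos[j, 0], Lx)
        dy = _mi(pos[i, 1] - pos[j, 1], Ly)
        dz = _mi(pos[i, 2] - pos[j, 2], Lz)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        stretch = r - b0
        U += 0.5 * k_bond * stretch * stretch
        if r > 0.0:
            fr = -k_bond * stretch / r
            F[i, 0] += fr * dx
            F[i, 1] += fr * dy
            F[i, 2] += fr * dz
            F[j, 0] -= fr * dx
            F[j, 1] -= fr * dy
            F[j, 2] -= fr * dz

    # analytic membrane wall, pore driving field, head barrier
    cut_wall = WCA_CUT * sig_pw
    cut_bar = WCA_CUT * bar_sig
    for i in range(n):
        if nb_kind[i] != 0:
            continue
        x = pos[i, 0]
        y = pos[i, 1]
        z = pos[i, 2]
        rr = math.sqrt(y * y + z * z)
        if wall_on:
            dxw = abs(x) - hw
            if dxw < cut_wall:  # beyond this the slab cannot be within reach
                dx_out = dxw if dxw > 0.0 else 0.0
                dr_in = pore_r - rr if pore_r > rr else 0.0
                d = math.sqrt(dx_out * dx_out + dr_in * dr_in)
                if d < cut_wall:
                    if d < 1.0e-9:
                        d = 1.0e-9
                    sr2 = (sig_pw / d) ** 2
                    sr6 = sr2 * sr2 * sr2
                    U += 4.0 * eps_pw * (sr6 * sr6 - sr6) + eps_pw
                    dU = -24.0 * eps_pw * (2.0 * sr6 * sr6 - sr6) / d
                    # F = -dU/dd * grad(d)
                    if dx_out > 0.0:
                        sgn = 1.0 if x > 0.0 else -1.0
                        F[i, 0] += -dU * dx_out * sgn / d
                    if dr_in > 0.0 and rr > 1.0e-12:
                        frad = -dU * (-dr_in) / d  # d(d)/dr = -dr_in/d
                        F[i, 1] += frad * y / rr
                        F[i, 2] += frad * z / rr
        if field_on and efield != 0.0 and rr < pore_r:
            # potential q E clamp(x, -hw, hw): uniform field confined to the
            # pore channel, constant potential on either side of the slab
            xx = x
            if xx > hw:
                xx = hw
            elif xx < -hw:
                xx = -hw
            U += charge[i] * efield * xx
            if -hw <= x <= hw:
                F[i, 0] += -charge[i] * efield
        if i == head_idx:
            d = x - hw
            if d < cut_bar:
                if d < 1.0e-9:
                    d = 1.0e-9
                sr2 = (bar_sig / d) ** 2
                sr6 = sr2 * sr2 * sr2
                U += 4.0 * bar_eps * (sr6 * sr6 - sr6) + bar_eps
                F[i, 0] += 24.0 * bar_eps * (2.0 * sr6 * sr6 - sr6) / d
    return U


@njit(cache=True)
def integrate_chunk(pos, vel, F, mobile, charge, nb_kind, bonds, box, noise,
                    dt, gamma,
                    eps_pp, sig_pp, eps_pw, sig_pw,
                    lam_b, alpha, rc,
                    k_bond, b0,
                    hw, pore_r, efield, field_on,
                    wall_on, head_idx, bar_eps, bar_sig,
                    excl_vol):
    """Velocity-Verlet with Langevin friction and noise forces.

    `noise` has shape (nsteps, n, 3) and already carries the
    fluctuation-dissipation amplitude sqrt(2 gamma kBT / dt) per component.
    The same random force acts through both half-kicks of a step.
    Returns (U, max displacement in one step).
    """
    nsteps = noise.shape[0]
    n = pos.shape[0]
    half = 0.5 * dt
    maxdisp2 = 0.0
    U = 0.0
    for s in range(nsteps):
        for i in range(n):
            if not mobile[i]:
                continue
            d2 = 0.0
            for d in range(3):
                a = F[i, d] - gamma * vel[i, d] + noise[s, i, d]
                vel[i, d] += half * a
                step = dt * vel[i, d]
                d2 += step * step
                p = pos[i, d] + step
                L = box[d]
                if p >= 0.5 * L:
                    p -= L
                elif p < -0.5 * L:
                    p += L
                pos[i, d] = p
            if d2 > maxdisp2:
                maxdisp2 = d2
        U = compute_forces(pos, charge, nb_kind, bonds, box,
                           eps_pp, sig_pp, eps_pw, sig_pw,
                           lam_b, alpha, rc, k_bond, b0,
                           hw, pore_r, efield, field_on,
                           wall_on, head_idx, bar_eps, bar_sig,
                           excl_vol, F)
        for i in range(n):
            if not mobile[i]:
                continue
            for d in range(3):
                a = F[i, d] - gamma * vel[i, d] + noise[s, i, d]
                vel[i, d] += half * a
    return U, math.sqrt(maxdisp2)
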