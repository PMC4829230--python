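"""Numba-compiled inner loops.

All kernels operate on plain float64 arrays. Concentrations are in uM,
"amounts" are concentration x volume in uM*um^3 (1 uM*um^3 = 1e-21 mol);
lengths in um; kernel-internal time in minutes unless noted.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def ftcs_substeps(C, lam, n_sub):
    """Explicit forward-time centered-space diffusion, no-flux boundaries.

    ``C`` is modified in place; ``lam = D*dt_sub/dx**2`` must be <= 0.25.
    No-flux is imposed by clamping neighbor indices (mirror), which keeps
    the scheme exactly conservative: every pairwise difference enters two
    updates with opposite signs.
    """
    nx, ny = C.shape
    work = np.empty_like(C)
    for _ in range(n_sub):
        for i in range(nx):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < nx - 1 else nx - 1
            for j in range(ny):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < ny - 1 else ny - 1
                c = C[i, j]
                work[i, j] = c + lam * (
                    C[im, j] + C[ip, j] + C[i, jm] + C[i, jp] - 4.0 * c
                )
        C[:, :] = work
    return C


@njit(cache=True)
def swim_step(pos, steps, thetas, Lx, Ly, dx, occ, cap):
    """One motility update for all cells, sequential in cell index.

    ``steps`` are pre-drawn step lengths (um), ``thetas`` directions.
    Projected positions beyond a boundary are mirror-reflected about it
    (overshoot d -> final position d inside), per axis independently.
    A move into an element already holding >= ``cap`` cells is rejected
    and the cell stays put. ``occ`` (element occupancy counts, shape of
    the grid) is kept consistent in place.
    """
    n = pos.shape[0]
    for k in range(n):
        x = pos[k, 0] + steps[k] * np.cos(thetas[k])
        y = pos[k, 1] + steps[k] * np.sin(thetas[k])
        # mirror reflection, looped for (pathological) multi-crossings
        for _ in range(64):
            if x < 0.0:
                x = -x
            elif x > Lx:
                x = 2.0 * Lx - x
            else:
                break
        for _ in range(64):
            if y < 0.0:
                y = -y
            elif y > Ly:
                y = 2.0 * Ly - y
            else:
                break
        if x < 0.0 or x > Lx or y < 0.0 or y > Ly:
            continue  # give up on a degenerate draw; cell stays
        i0 = int(pos[k, 0] / dx)
        j0 = int(pos[k, 1] / dx)
        i1 = int(x / dx)
        j1 = int(y / dx)
        nx, ny = occ.shape
        if i1 >= nx:
            i1 = nx - 1
        if j1 >= ny:
            j1 = ny - 1
        if (i1 != i0 or j1 != j0) and occ[i1, j1] >= cap:
            continue  # density cap: rejected moves leave the cell in place
        occ[i0, j0] -= 1
        occ[i1, j1] += 1
        pos[k, 0] = x
        pos[k, 1] = y
    return pos


@njit(cache=True)
def lsr_cells_step(
    Ai, Ap, M, T, basal, K_synth, V_ydgG, elem_idx, C, dt_min,
    K_b, k_phos, d_Ap, alpha0, alpha1, k2, hill, d_M, k_T, d_T,
    V_ind, K_ind, V_cell, V_elem, n_sub0,
):
    """Advance every Lsr cell by one engine step of ``dt_min`` minutes.

    Cells exchange AI-2 with their grid element through ``C`` (flattened
    element concentrations, uM), sequentially in cell index so that the
    supply limit (import cannot exceed element content) is well defined.
    Each cell takes ``n_sub0`` Euler sub-steps; a sub-step that would
    drive any intracellular state negative or change it by more than 50%
    is retried at half the step (rejected, not clipped).
    """
    n = Ai.shape[0]
    for k in range(n):
        e = elem_idx[k]
        remaining = dt_min
        h = dt_min / n_sub0
        guard = 0
        while remaining > 1e-12 and guard < 100000:
            guard += 1
            if h > remaining:
                h = remaining
            Ae = C[e]
            ai = Ai[k]
            ap = Ap[k]
            m = M[k]
            t = T[k]
            imp_b = basal[k] * Ae / (K_b + Ae)
            imp_i = V_ind * t * Ae / (K_ind + Ae)
            exp_f = V_ydgG[k] * ai
            phos = k_phos * ai
            aph = ap ** hill
            trans = alpha0 + alpha1 * aph / (k2 ** hill + aph)
            dai = K_synth[k] + imp_b + imp_i - exp_f - phos
            dap = phos - d_Ap * ap
            dm = trans - d_M * m
            dt_ = k_T * m - d_T * t
            # reject-and-halve guard on intracellular states
            bad = False
            for val, dval in ((ai, dai), (ap, dap), (m, dm), (t, dt_)):
                new = val + h * dval
                if new < 0.0:
                    bad = True
                    break
                if val > 1e-12 and abs(h * dval) > 0.5 * val:
                    bad = True
                    break
            if bad and h > dt_min / 4096.0:
                h *= 0.5
                continue
            # exchange with the element, supply-limited on import
            secrete = exp_f * h * V_cell                  # amount to element
            want = (imp_b + imp_i) * h * V_cell           # amount from element
            avail = C[e] * V_elem + secrete
            if want > avail:
                got = avail
            else:
                got = want
            C[e] = (C[e] * V_elem + secrete - got) / V_elem
            # intracellular update; import scaled by what was actually got
            scale = got / want if want > 0.0 else 0.0
            Ai[k] = ai + h * (K_synth[k] + (imp_b + imp_i) * scale - exp_f - phos)
            if Ai[k] < 0.0:
                Ai[k] = 0.0
            Ap[k] = ap + h * dap
            M[k] = m + h * dm
            T[k] = t + h * dt_
            remaining -= h
            if h < dt_min / n_sub0:
                h *= 2.0
    return C


@njit(cache=True)
def lux_cells_step(
    AHL_in, synth_rate, t_since, crossed, r_basal, elem_idx, C, dt_min,
    threshold, r_max, ramp, conductivity, V_cell, V_elem, n_sub0,
):
    """Advance every LuxIR cell by one engine step of ``dt_min`` minutes.

    Synthesis at the cell's current rate, linear ramp after the first
    threshold crossing (latched), and conductance-driven membrane
    exchange with the local element, supply-limited on inflow.
    """
    n = AHL_in.shape[0]
    for k in range(n):
        e = elem_idx[k]
        h = dt_min / n_sub0
        for _ in range(n_sub0):
            if crossed[k] == 1:
                t_since[k] += h
                frac = t_since[k] / ramp
                if frac > 1.0:
                    frac = 1.0
                synth_rate[k] = r_basal[k] + (r_max - r_basal[k]) * frac
            a = AHL_in[k] + synth_rate[k] * h
            Ae = C[e]
            flux = conductivity * (a - Ae) * h  # uM, cell basis; + = out
            if flux > a:
                flux = a
            amount = flux * V_cell
            if amount < 0.0:
                avail = C[e] * V_elem
                if -amount > avail:
                    amount = -avail
                    flux = amount / V_cell
            C[e] = (C[e] * V_elem + amount) / V_elem
            AHL_in[k] = a - flux
            if crossed[k] == 0 and AHL_in[k] > threshold:
                crossed[k] = 1
                t_since[k] = 0.0
    return C
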