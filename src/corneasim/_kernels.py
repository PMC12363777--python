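"""Numba kernels: Metropolis pixel-copy dynamics, incremental energy change,
ADI reaction-diffusion substeps, and full-lattice bookkeeping scans.

All kernels are deterministic given the numba RNG state (seeded through
:func:`seed_rng`) and operate on plain numpy arrays so the Python layer owns
every piece of state.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .types import MEDIUM, TEAR, LIMB, MEMB

# Moore neighborhood (copy attempts, contact energy)
_DX8 = np.array([1, -1, 0, 0, 1, 1, -1, -1], dtype=np.int64)
_DY8 = np.array([0, 0, 1, -1, 1, -1, 1, -1], dtype=np.int64)
# von Neumann neighborhood (surface faces)
_DX4 = np.array([1, -1, 0, 0], dtype=np.int64)
_DY4 = np.array([0, 0, 1, -1], dtype=np.int64)


@njit(cache=True)
def seed_rng(seed):
    """Seed numba's internal RNG (independent of numpy's global state)."""
    np.random.seed(seed)


@njit(cache=True)
def _spring_energy(dx, dy, rest, k):
    d = np.sqrt(dx * dx + dy * dy)
    return k * (d - rest) ** 2


@njit(cache=True)
def _links_dh(os_, ot, x, y, vol, sumx, sumy, lptr, lother, lrest, lk):
    """Energy change of all COM-distance springs touching either affected cell.

    The invading cell ``os_`` gains pixel (x, y); ``ot`` loses it.  A link
    whose endpoint drops to volume 0 is treated as removed (its old energy
    vanishes).
    """
    vs = vol[os_]
    vt = vol[ot]
    ocx_s = sumx[os_] / vs
    ocy_s = sumy[os_] / vs
    ncx_s = (sumx[os_] + x) / (vs + 1.0)
    ncy_s = (sumy[os_] + y) / (vs + 1.0)
    ocx_t = sumx[ot] / vt
    ocy_t = sumy[ot] / vt
    t_dies = vt == 1
    ncx_t = 0.0
    ncy_t = 0.0
    if not t_dies:
        ncx_t = (sumx[ot] - x) / (vt - 1.0)
        ncy_t = (sumy[ot] - y) / (vt - 1.0)
    dh = 0.0
    for i in range(lptr[os_], lptr[os_ + 1]):
        b = lother[i]
        if b == ot:
            dh -= _spring_energy(ocx_s - ocx_t, ocy_s - ocy_t, lrest[i], lk[i])
            if not t_dies:
                dh += _spring_energy(ncx_s - ncx_t, ncy_s - ncy_t, lrest[i], lk[i])
        else:
            bx = sumx[b] / vol[b]
            by = sumy[b] / vol[b]
            dh -= _spring_energy(ocx_s - bx, ocy_s - by, lrest[i], lk[i])
            dh += _spring_energy(ncx_s - bx, ncy_s - by, lrest[i], lk[i])
    for i in range(lptr[ot], lptr[ot + 1]):
        b = lother[i]
        if b == os_:
            continue  # counted above
        bx = sumx[b] / vol[b]
        by = sumy[b] / vol[b]
        dh -= _spring_energy(ocx_t - bx, ocy_t - by, lrest[i], lk[i])
        if not t_dies:
            dh += _spring_energy(ncx_t - bx, ncy_t - by, lrest[i], lk[i])
    return dh


@njit(cache=True)
def delta_h(grid, ctype, vol, tv, surf, tsurf, sumx, sumy,
            J, lamv, lams, mu, conc, use_conc,
            lptr, lother, lrest, lk, n_links,
            sx, sy, x, y):
    """Incremental energy change of copying owner of (sx, sy) onto (x, y).

    Terms: contact (Moore neighborhood), volume and surface constraints for
    the two affected cells, chemotaxis of the invading cell on ``conc``, and
    COM-distance springs.  Callers guarantee distinct, non-frozen owners.
    """
    H, W = grid.shape
    ot = grid[y, x]
    os_ = grid[sy, sx]
    tt_o = ctype[ot]
    tt_s = ctype[os_]
    dh = 0.0
    # contact energy over the target pixel's Moore neighborhood
    for k in range(8):
        nx = x + _DX8[k]
        ny = y + _DY8[k]
        if nx < 0 or nx >= W or ny < 0 or ny >= H:
            continue
        on = grid[ny, nx]
        tn = ctype[on]
        if on != os_:
            dh += J[tt_s, tn]
        if on != ot:
            dh -= J[tt_o, tn]
    # volume constraints
    vs = vol[os_]
    vt = vol[ot]
    dh += lamv[tt_s] * ((vs + 1.0 - tv[os_]) ** 2 - (vs - tv[os_]) ** 2)
    dh += lamv[tt_o] * ((vt - 1.0 - tv[ot]) ** 2 - (vt - tv[ot]) ** 2)
    # surface constraints (4-neighbor faces; lattice border counts as a face)
    if lams[tt_s] != 0.0 or lams[tt_o] != 0.0:
        ds_s = 0
        ds_t = 0
        for k in range(4):
            nx = x + _DX4[k]
            ny = y + _DY4[k]
            if nx < 0 or nx >= W or ny < 0 or ny >= H:
                ds_s += 1
                ds_t -= 1
            else:
                on = grid[ny, nx]
                ds_s += 1 if on != os_ else -1
                ds_t += 1 if on == ot else -1
        ss = surf[os_]
        st = surf[ot]
        dh += lams[tt_s] * ((ss + ds_s - tsurf[os_]) ** 2 - (ss - tsurf[os_]) ** 2)
        dh += lams[tt_o] * ((st + ds_t - tsurf[ot]) ** 2 - (st - tsurf[ot]) ** 2)
    # chemotaxis of the invading cell
    if use_conc and mu[tt_s] != 0.0:
        dh -= mu[tt_s] * (conc[y, x] - conc[sy, sx])
    if n_links > 0 and (lptr[os_ + 1] > lptr[os_] or lptr[ot + 1] > lptr[ot]):
        dh += _links_dh(os_, ot, x, y, vol, sumx, sumy, lptr, lother, lrest, lk)
    return dh


@njit(cache=True)
def _surface_deltas(grid, os_, ot, x, y):
    H, W = grid.shape
    ds_s = 0
    ds_t = 0
    for k in range(4):
        nx = x + _DX4[k]
        ny = y + _DY4[k]
        if nx < 0 or nx >= W or ny < 0 or ny >= H:
            ds_s += 1
            ds_t -= 1
        else:
            on = grid[ny, nx]
            ds_s += 1 if on != os_ else -1
            ds_t += 1 if on == ot else -1
    return ds_s, ds_t


@njit(cache=True)
def metropolis_sweep(grid, ctype, vol, tv, surf, tsurf, sumx, sumy, alive,
                     J, lamv, lams, temperature, mu, conc, use_conc,
                     frozen, lptr, lother, lrest, lk, n_links, n_attempts):
    """One Monte Carlo Step: ``n_attempts`` pixel-copy attempts.

    A draw landing on a frozen-owner pixel is redrawn without being counted;
    degenerate attempts (identical owners, frozen source, off-lattice
    neighbor) consume an attempt.  Accepts when ΔH ≤ 0, otherwise with
    probability exp(−ΔH/T).  Volumes, surfaces and COM sums are updated
    incrementally; a cell reaching volume 0 is flagged dead.
    """
    H, W = grid.shape
    attempts = 0
    flips = 0
    draws = 0
    max_draws = 50 * n_attempts + 1000
    while attempts < n_attempts and draws < max_draws:
        draws += 1
        x = np.random.randint(0, W)
        y = np.random.randint(0, H)
        ot = grid[y, x]
        if frozen[ctype[ot]]:
            continue
        attempts += 1
        k = np.random.randint(0, 8)
        sx = x + _DX8[k]
        sy = y + _DY8[k]
        if sx < 0 or sx >= W or sy < 0 or sy >= H:
            continue
        os_ = grid[sy, sx]
        if os_ == ot:
            continue
        if frozen[ctype[os_]]:
            continue
        dh = delta_h(grid, ctype, vol, tv, surf, tsurf, sumx, sumy,
                     J, lamv, lams, mu, conc, use_conc,
                     lptr, lother, lrest, lk, n_links, sx, sy, x, y)
        if dh > 0.0 and np.random.random() >= np.exp(-dh / temperature):
            continue
        ds_s, ds_t = _surface_deltas(grid, os_, ot, x, y)
        grid[y, x] = os_
        vol[os_] += 1
        vol[ot] -= 1
        sumx[os_] += x
        sumy[os_] += y
        sumx[ot] -= x
        sumy[ot] -= y
        surf[os_] += ds_s
        surf[ot] += ds_t
        if vol[ot] == 0:
            alive[ot] = False
        flips += 1
    return flips


@njit(cache=True)
def accept_decisions(dh, temperature, n):
    """Replay the Metropolis acceptance rule n times for a fixed ΔH.

    Uses the same RNG the sweep kernel uses, so logged decisions reflect the
    production acceptance path.  Returns the number of acceptances.
    """
    acc = 0
    for _ in range(n):
        if dh <= 0.0 or np.random.random() < np.exp(-dh / temperature):
            acc += 1
    return acc


@njit(cache=True)
def refresh_stats(grid, vol, sumx, sumy, surf):
    """Full-lattice rescan of per-cell volume, COM sums and boundary faces."""
    H, W = grid.shape
    vol[:] = 0
    sumx[:] = 0
    sumy[:] = 0
    surf[:] = 0
    for y in range(H):
        for x in range(W):
            c = grid[y, x]
            vol[c] += 1
            sumx[c] += x
            sumy[c] += y
            s = 0
            for k in range(4):
                nx = x + _DX4[k]
                ny = y + _DY4[k]
                if nx < 0 or nx >= W or ny < 0 or ny >= H:
                    s += 1
                elif grid[ny, nx] != c:
                    s += 1
            surf[c] += s


@njit(cache=True)
def contact_scan(grid, ctype, nbr_mask, aepbm):
    """Per-cell neighbor-type bitmask and basement-membrane contact area.

    ``nbr_mask[c]`` gets bit ``1 << t`` for every type t adjacent to cell c
    (Moore neighborhood, same order as the contact energy).  ``aepbm[c]``
    counts the cell's pixels having at least one LIMB or MEMB neighbor —
    the contact-area A_EpBM of the basal-maintenance rule.
    """
    H, W = grid.shape
    nbr_mask[:] = 0
    aepbm[:] = 0
    for y in range(H):
        for x in range(W):
            c = grid[y, x]
            if c == 0:
                continue
            touch = False
            for k in range(8):
                nx = x + _DX8[k]
                ny = y + _DY8[k]
                if nx < 0 or nx >= W or ny < 0 or ny >= H:
                    continue
                o2 = grid[ny, nx]
                if o2 != c:
                    t2 = ctype[o2]
                    nbr_mask[c] |= np.int64(1) << np.int64(t2)
                    if t2 == LIMB or t2 == MEMB:
                        touch = True
            if touch:
                aepbm[c] += 1


@njit(cache=True)
def field_cell_sums(grid, conc, sums):
    """Accumulate field concentration per owner (for per-cell averages)."""
    H, W = grid.shape
    sums[:] = 0.0
    for y in range(H):
        for x in range(W):
            sums[grid[y, x]] += conc[y, x]


@njit(cache=True)
def renormalize_tear(grid, ctype, tear_id, thickness):
    """Rebuild the tear band: per column, tear fills from the epithelial (or
    membrane) surface up to max(surface + thickness, tissue-median level),
    medium (air) above.  Only TEAR/MEDIUM pixels are reassigned; wall columns
    and the top lattice row are untouched.  Returns per-column surface y.
    """
    H, W = grid.shape
    tops = np.zeros(W - 2, dtype=np.int64)
    for x in range(1, W - 1):
        top = 0
        for y in range(H - 2, -1, -1):
            t = ctype[grid[y, x]]
            if t != TEAR and t != MEDIUM:
                top = y
                break
        tops[x - 1] = top
    level = int(np.median(tops)) + thickness
    for x in range(1, W - 1):
        top = tops[x - 1]
        tear_top = top + thickness
        if level > tear_top:
            tear_top = level
        if tear_top > H - 2:
            tear_top = H - 2
        for y in range(top + 1, H - 1):
            o = grid[y, x]
            t = ctype[o]
            if t == TEAR or t == MEDIUM:
                grid[y, x] = tear_id if y <= tear_top else 0
    return tops


@njit(cache=True)
def _thomas(a, b, c, d, n, cp, dp):
    """Solve a tridiagonal system in place; result returned in dp[:n]."""
    cp[0] = c[0] / b[0]
    dp[0] = d[0] / b[0]
    for i in range(1, n):
        m = b[i] - a[i] * cp[i - 1]
        cp[i] = c[i] / m
        dp[i] = (d[i] - a[i] * dp[i - 1]) / m
    for i in range(n - 2, -1, -1):
        dp[i] -= cp[i] * dp[i + 1]


@njit(cache=True)
def adi_substep(conc, fw, fe, fs, fn, fixed, fixed_val, r):
    """One Peaceman–Rachford ADI substep of the diffusion operator.

    x-implicit/y-explicit half step followed by y-implicit/x-explicit half
    step, with harmonic-mean face conductances (fw/fe/fs/fn) and Dirichlet
    pixels held at ``fixed_val`` via identity rows.  ``r`` = dt/2.
    """
    H, W = conc.shape
    n = max(W, H)
    a = np.empty(n)
    b = np.empty(n)
    c = np.empty(n)
    d = np.empty(n)
    cp = np.empty(n)
    dp = np.empty(n)
    half = np.empty_like(conc)
    # --- x-implicit / y-explicit half step (reads old conc only) ---
    for y in range(H):
        for x in range(W):
            if fixed[y, x]:
                a[x] = 0.0
                b[x] = 1.0
                c[x] = 0.0
                d[x] = fixed_val[y, x]
            else:
                a[x] = -r * fw[y, x]
                c[x] = -r * fe[y, x]
                b[x] = 1.0 + r * (fw[y, x] + fe[y, x])
                rhs = conc[y, x]
                if y > 0:
                    rhs += r * fs[y, x] * (conc[y - 1, x] - conc[y, x])
                if y < H - 1:
                    rhs += r * fn[y, x] * (conc[y + 1, x] - conc[y, x])
                d[x] = rhs
        _thomas(a, b, c, d, W, cp, dp)
        for x in range(W):
            half[y, x] = dp[x]
    # --- y-implicit / x-explicit half step (reads the half-step field) ---
    for x in range(W):
        for y in range(H):
            if fixed[y, x]:
                a[y] = 0.0
                b[y] = 1.0
                c[y] = 0.0
                d[y] = fixed_val[y, x]
            else:
                a[y] = -r * fs[y, x]
                c[y] = -r * fn[y, x]
                b[y] = 1.0 + r * (fs[y, x] + fn[y, x])
                rhs = half[y, x]
                if x > 0:
                    rhs += r * fw[y, x] * (half[y, x - 1] - half[y, x])
                if x < W - 1:
                    rhs += r * fe[y, x] * (half[y, x + 1] - half[y, x])
                d[y] = rhs
        _thomas(a, b, c, d, H, cp, dp)
        for y in range(H):
            conc[y, x] = dp[y]
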