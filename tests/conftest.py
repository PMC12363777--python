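"""Shared fixtures: small hand-built lattice states, a brute-force energy
oracle, and the session-scoped simulation campaigns used by the acceptance
tests (three seeded 45-day homeostasis runs; a day-18 homeostatic base for
injury branches)."""

from __future__ import annotations

import numpy as np
import pytest

from corneasim import scenario
from corneasim.config import default_config
from corneasim.potts import CellTable, LatticeState, PottsParams
from corneasim.types import (
    BASAL, LIMB, MEMB, N_TYPES, STEM, STROMA, SUPER, TEAR, WALL, WING,
)

SEEDS = (1, 2, 3)
HOMEO_DAYS = 45


# --------------------------------------------------------------------------
# small constructed states
# --------------------------------------------------------------------------

def make_state(width, height, blocks):
    """Build a LatticeState from (type, y0, y1, x0, x1) blocks; the first
    block may cover everything (later blocks overwrite).  Returns (state,
    ids) with ids parallel to blocks."""
    st = LatticeState(width, height)
    ids = []
    for ctype, y0, y1, x0, x1 in blocks:
        cid = st.table.new_cell(ctype)
        st.owner_grid[y0:y1, x0:x1] = cid
        ids.append(cid)
    st.refresh_stats()
    for cid in ids:
        st.table.target_volume[cid] = float(st.table.volume[cid])
        st.table.target_surface[cid] = float(st.table.surface[cid])
    return st, ids


def uniform_params(n_cell_types=N_TYPES, J=4.0, lam_v=2.0, lam_s=0.0,
                   T=10.0, mu=0.0):
    Jm = np.full((N_TYPES, N_TYPES), float(J))
    lv = np.zeros(N_TYPES)
    ls = np.zeros(N_TYPES)
    m = np.zeros(N_TYPES)
    for t in (STEM, BASAL, WING, SUPER):
        lv[t] = lam_v
        ls[t] = lam_s
        m[t] = mu
    return PottsParams(J=Jm, lambda_volume=lv, lambda_surface=ls,
                       temperature=T, chemotaxis_mu=m)


def brute_force_energy(state: LatticeState, params: PottsParams) -> float:
    """Independent global Hamiltonian: contact over unordered Moore-neighbor
    pairs with distinct owners, plus volume/surface constraints and link
    springs, all recomputed from the raw grid."""
    grid = state.owner_grid
    t = state.table
    H, W = grid.shape
    e = 0.0
    # each unordered pair once: E, S, SE, SW offsets
    for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):
        b = np.roll(np.roll(grid, -dy, axis=0), -dx, axis=1)
        valid = np.ones_like(grid, dtype=bool)
        if dy > 0:
            valid[H - dy:, :] = False
        if dx > 0:
            valid[:, W - dx:] = False
        if dx < 0:
            valid[:, :-dx] = False
        pa = grid[valid]
        pb = b[valid]
        diff = pa != pb
        e += params.J[t.ctype[pa[diff]], t.ctype[pb[diff]]].sum()
    # constraints from a fresh rescan
    vol = np.bincount(grid.ravel(), minlength=t.capacity)
    surf = np.zeros(t.capacity)
    for dy, dx in ((0, 1), (0, -1), (1, 0), (-1, 0)):
        nb = np.roll(np.roll(grid, -dy, axis=0), -dx, axis=1)
        inside = np.ones_like(grid, dtype=bool)
        if dy == 1:
            inside[H - 1:, :] = False
        if dy == -1:
            inside[:1, :] = False
        if dx == 1:
            inside[:, W - 1:] = False
        if dx == -1:
            inside[:, :1] = False
        faces = (grid != nb) & inside
        np.add.at(surf, grid[faces], 1)
        np.add.at(surf, grid[~inside], 1)  # lattice border counts as a face
    for cid in range(1, t.next_id):
        if vol[cid] == 0:
            continue
        tt = t.ctype[cid]
        e += params.lambda_volume[tt] * (vol[cid] - t.target_volume[cid]) ** 2
        e += params.lambda_surface[tt] * (surf[cid] - t.target_surface[cid]) ** 2
    for ln in params.links:
        va, vb = vol[ln.cell_a], vol[ln.cell_b]
        if va == 0 or vb == 0:
            continue
        ys, xs = np.nonzero(grid == ln.cell_a)
        ca = np.array([xs.mean(), ys.mean()])
        ys, xs = np.nonzero(grid == ln.cell_b)
        cb = np.array([xs.mean(), ys.mean()])
        d = np.hypot(*(ca - cb))
        e += ln.stiffness * (d - ln.rest_length) ** 2
    return float(e)


def random_two_cell_state(rng, size=8):
    """Random fully-tiled configuration of two epithelial cells on a small
    lattice (no medium, so every pixel-copy attempt is between live cells)."""
    st = LatticeState(size, size)
    a = st.table.new_cell(BASAL)
    b = st.table.new_cell(WING)
    split = rng.integers(1, size - 1)
    st.owner_grid[:, :split] = a
    st.owner_grid[:, split:] = b
    # roughen the interface
    for _ in range(3 * size):
        y = rng.integers(0, size)
        x = rng.integers(max(1, split - 2), min(size - 1, split + 2))
        st.owner_grid[y, x] = a if rng.random() < 0.5 else b
    # both cells must survive the roughening
    if not np.all(np.bincount(st.owner_grid.ravel(), minlength=3)[1:3] > 0):
        return random_two_cell_state(rng, size)
    st.refresh_stats()
    for cid in (a, b):
        st.table.target_volume[cid] = st.table.volume[cid] + rng.integers(-5, 6)
        st.table.target_surface[cid] = st.table.surface[cid] + rng.integers(-4, 5)
    return st, (a, b)


# --------------------------------------------------------------------------
# session-scoped campaigns (shared by the acceptance tests)
# --------------------------------------------------------------------------

@pytest.fixture(scope="session")
def homeo_runs():
    """Three seeded homeostasis runs of 45 simulated days from the day-0
    limbal-stem-cell seed, with default calibrated parameters."""
    runs = []
    for seed in SEEDS:
        cfg = default_config()
        cfg.run.run_mcs = HOMEO_DAYS * cfg.rules.day_to_mcs
        runs.append(scenario.run(cfg, seed=seed))
    return runs


@pytest.fixture(scope="session")
def injury_base():
    """One homeostatic run to day 18 whose simulation is the common base
    state for injury branches; the result carries the pre-injury history
    used to form stable baselines."""
    cfg = default_config()
    cfg.run.run_mcs = 18 * cfg.rules.day_to_mcs
    return scenario.run(cfg, seed=SEEDS[0])
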