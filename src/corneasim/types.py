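"""Cell-type codes and lattice conventions shared by every module.

The lattice is a 2D array indexed ``grid[y, x]`` with ``y`` increasing from
the stromal (inner) side toward the tear film and air (outer side), matching
the anatomical orientation of a sagittal corneal section.  Cell IDs are
positive integers; ID 0 is the medium (air) pseudo-cell.
"""

from __future__ import annotations

import numpy as np

# --- cell type codes -------------------------------------------------------
MEDIUM = 0   # air above the tear film
TEAR = 1     # tear film compartment (EGF source)
STEM = 2     # limbal epithelial stem cell (LESC)
BASAL = 3    # basal cell
WING = 4     # wing cell
SUPER = 5    # superficial cell
LIMB = 6     # limbal (low-stiffness) segment of the epithelial basement membrane
MEMB = 7     # central (high-stiffness) segment of the epithelial basement membrane
STROMA = 8   # stroma, passive spatial constraint
WALL = 9     # lateral boundary wall
DAMG = 10    # destroyed basement membrane (no regeneration)

N_TYPES = 11

TYPE_NAMES = {
    MEDIUM: "MEDIUM",
    TEAR: "TEAR",
    STEM: "STEM",
    BASAL: "BASAL",
    WING: "WING",
    SUPER: "SUPER",
    LIMB: "LIMB",
    MEMB: "MEMB",
    STROMA: "STROMA",
    WALL: "WALL",
    DAMG: "DAMG",
}
TYPE_CODES = {v: k for k, v in TYPE_NAMES.items()}

#: epithelial (living, mobile) cell types, in differentiation order
EPITHELIAL = (STEM, BASAL, WING, SUPER)

#: types that never gain or lose pixels during Metropolis dynamics
FROZEN_TYPES = (MEDIUM, LIMB, MEMB, STROMA, WALL, DAMG)

#: allowed forward type transitions (differentiation DAG)
TRANSITIONS = {STEM: BASAL, BASAL: WING, WING: SUPER}

FROZEN_MASK = np.zeros(N_TYPES, dtype=np.bool_)
for _t in FROZEN_TYPES:
    FROZEN_MASK[_t] = True

EPITHELIAL_MASK = np.zeros(N_TYPES, dtype=np.bool_)
for _t in EPITHELIAL:
    EPITHELIAL_MASK[_t] = True

# --- neighborhoods ---------------------------------------------------------
# 2nd-order (Moore, 8-neighbor) offsets: copy-attempt selection + contact energy
NEIGH8_DX = np.array([1, -1, 0, 0, 1, 1, -1, -1], dtype=np.int64)
NEIGH8_DY = np.array([0, 0, 1, -1, 1, -1, 1, -1], dtype=np.int64)
# 1st-order (von Neumann, 4-neighbor) offsets: surface (boundary-face) count
NEIGH4_DX = np.array([1, -1, 0, 0], dtype=np.int64)
NEIGH4_DY = np.array([0, 0, 1, -1], dtype=np.int64)

# --- physical conversions --------------------------------------------------
PIXEL_UM = 2.0          # μm per voxel edge (4 μm² per voxel)
MCS_MINUTES = 6.0       # one Monte Carlo Step = 6 minutes of biological time
DAY_TO_MCS = 240        # MCS per simulated day
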