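"""Per-pixel scalar fields (EGF, toxicant) with cell-type-dependent diffusion.

The field obeys  ∂c/∂t = ∇·(D(x,y) ∇c) − kd·c + Ω  where D is looked up from
the owner cell's type (the tight-junction barrier of the superficial layer is
a low-D region), kd is a global first-order decay, and Ω is realized as
Dirichlet clamps (the tear film holds EGF at its source value) plus
instantaneous deposits (chemical injury).

Boundary conditions follow the confined-domain setup: zero concentration at
the top and bottom lattice rows, no flux through the lateral wall columns
(walls carry D = 0).  Time integration is a Peaceman–Rachford ADI scheme with
harmonic-mean face conductances and exact exponential decay splitting; the
scheme is unconditionally stable for the D = 186 voxel²/MCS bulk coefficient.
Decay contract: with D = 0 and no sources, one MCS multiplies the field by
exp(−kd) (continuous-time integration, not a single forward-Euler step).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from . import _kernels
from .potts import LatticeState
from .types import LIMB, MEMB, SUPER, TEAR, WALL

__all__ = [
    "ScalarField",
    "average_over_cell",
    "diffusion_coefficient_map",
    "relax_to_steady_state",
    "step_field",
    "update_cell_averages",
]

#: cell-type-specific diffusion coefficients (voxel²/MCS); unlisted types
#: take the field's global coefficient.  WALL carries 0 to realize the
#: lateral no-flux boundary "implemented through wall cells".
DEFAULT_DIFFUSION_BY_TYPE = {SUPER: 20.0, MEMB: 20.0, LIMB: 0.0, WALL: 0.0}


@dataclass
class ScalarField:
    """A named concentration field living on the simulation lattice."""

    name: str
    conc: np.ndarray
    decay_rate: float = 0.5                 # kd, per MCS
    global_diffusion: float = 186.0         # D for unlisted cell types
    diffusion_by_type: dict = dc_field(
        default_factory=lambda: dict(DEFAULT_DIFFUSION_BY_TYPE))
    clamp_type: Optional[int] = TEAR        # Dirichlet-clamped owner type
    clamp_value: float = 1.0
    dirichlet_top_bottom: bool = True       # zero conc at rows 0 and H-1
    no_flux_all: bool = False               # conservation test mode
    n_substeps: int = 10

    @classmethod
    def zeros(cls, state: LatticeState, name: str = "EGF", **kw) -> "ScalarField":
        return cls(name=name, conc=np.zeros((state.height, state.width)), **kw)

    def total_mass(self) -> float:
        return float(self.conc.sum())


def diffusion_coefficient_map(state: LatticeState,
                              fld: ScalarField) -> np.ndarray:
    """Per-pixel diffusion coefficient from the owner cell's type."""
    from .types import N_TYPES
    lut = np.full(N_TYPES, fld.global_diffusion, dtype=np.float64)
    for t, d in fld.diffusion_by_type.items():
        lut[t] = d
    return lut[state.type_grid()]


def _face_conductances(dmap: np.ndarray, no_flux_all: bool):
    """Harmonic-mean conductances at the four faces of every pixel."""
    H, W = dmap.shape
    fw = np.zeros((H, W))
    fe = np.zeros((H, W))
    fs = np.zeros((H, W))
    fn = np.zeros((H, W))

    def harm(a, b):
        s = a + b
        out = np.zeros_like(a)
        nz = s > 0
        out[nz] = 2.0 * a[nz] * b[nz] / s[nz]
        return out

    fx = harm(dmap[:, :-1], dmap[:, 1:])   # face between x and x+1
    fy = harm(dmap[:-1, :], dmap[1:, :])   # face between y and y+1
    fe[:, :-1] = fx
    fw[:, 1:] = fx
    fn[:-1, :] = fy
    fs[1:, :] = fy
    # lattice border faces carry no flux (confined system)
    return fw, fe, fs, fn


def _fixed_masks(state: LatticeState, fld: ScalarField):
    H, W = fld.conc.shape
    fixed = np.zeros((H, W), dtype=np.bool_)
    val = np.zeros((H, W))
    if fld.dirichlet_top_bottom and not fld.no_flux_all:
        fixed[0, :] = True
        fixed[H - 1, :] = True
    if fld.clamp_type is not None:
        m = state.type_grid() == fld.clamp_type
        fixed |= m
        val[m] = fld.clamp_value
    return fixed, val


def step_field(fld: ScalarField, state: LatticeState, n_mcs: int = 1,
               dmap: Optional[np.ndarray] = None) -> ScalarField:
    """Advance the field by ``n_mcs`` Monte Carlo Steps in place.

    Each MCS is split into ``n_substeps`` ADI substeps with symmetric
    (Strang) decay halves; clamps and boundary rows are re-imposed after
    every substep.  Tiny negative overshoots of the implicit scheme near
    sharp deposits are clipped to zero to preserve the non-negativity
    invariant.
    """
    if dmap is None:
        dmap = diffusion_coefficient_map(state, fld)
    fw, fe, fs, fn = _face_conductances(dmap, fld.no_flux_all)
    fixed, val = _fixed_masks(state, fld)
    dt = 1.0 / fld.n_substeps
    half_decay = np.exp(-fld.decay_rate * dt / 2.0)
    c = fld.conc
    for _ in range(n_mcs * fld.n_substeps):
        if fld.decay_rate:
            c *= half_decay
            c[fixed] = val[fixed]
        _kernels.adi_substep(c, fw, fe, fs, fn, fixed, val, dt / 2.0)
        if fld.decay_rate:
            c *= half_decay
        c[fixed] = val[fixed]
        np.maximum(c, 0.0, out=c)
    if np.any(c < 0):  # pragma: no cover - guarded by the clip above
        raise RuntimeError("negative concentration after field step")
    return fld


def relax_to_steady_state(fld: ScalarField, state: LatticeState,
                          tol: float = 1e-6, max_mcs: int = 400) -> int:
    """Iterate MCS-sized steps until the field stops changing; returns the
    number of steps taken."""
    dmap = diffusion_coefficient_map(state, fld)
    for i in range(max_mcs):
        prev = fld.conc.copy()
        step_field(fld, state, dmap=dmap)
        scale = max(float(np.abs(fld.conc).max()), 1e-12)
        if np.abs(fld.conc - prev).max() < tol * scale:
            return i + 1
    return max_mcs


def average_over_cell(fld: ScalarField, state: LatticeState,
                      cell_id: int) -> float:
    """Arithmetic mean of the field over the cell's pixels."""
    t = state.table
    if cell_id <= 0 or cell_id >= t.next_id or not t.alive[cell_id]:
        raise KeyError(f"cell {cell_id} is not alive")
    ys, xs = state.pixels_of(cell_id)
    return float(fld.conc[ys, xs].mean())


def update_cell_averages(fld: ScalarField, state: LatticeState) -> None:
    """Store the per-cell mean field value into the registry (egf_avg)."""
    t = state.table
    sums = np.zeros(t.capacity)
    _kernels.field_cell_sums(state.owner_grid, fld.conc, sums)
    n = t.next_id
    vol = t.volume[:n].astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(vol > 0, sums[:n] / vol, 0.0)
    t.egf_avg[:n] = avg
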