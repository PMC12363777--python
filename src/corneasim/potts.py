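"""Cellular Potts (GGH) engine: lattice state, energy parameters, incremental
Hamiltonian evaluation and Metropolis pixel-copy dynamics.

The effective energy is

    H = Σ_faces J(τ,τ') + Σ_cells λ_V (V − V_t)² + Σ_cells λ_S (S − S_t)²
        + Σ_links k (d − rest)²

with an additional chemotaxis work term −μ_τ (c_target − c_source) applied per
copy attempt (a ΔH-only term, as is standard for CPM chemotaxis).  Copy
attempts are accepted when they lower the energy, or with Boltzmann
probability exp(−ΔH/T) when they raise it.  One Monte Carlo Step performs as
many attempts as there are non-frozen lattice sites and corresponds to six
minutes of biological time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np

from . import _kernels
from .types import (
    EPITHELIAL_MASK,
    FROZEN_MASK,
    MEDIUM,
    N_TYPES,
    PIXEL_UM,
    TYPE_NAMES,
)

__all__ = [
    "CellRecord",
    "CellTable",
    "LatticeState",
    "LinkSpring",
    "PottsParams",
    "compute_pressure",
    "delta_hamiltonian",
    "metropolis_mcs",
]


@dataclass
class LinkSpring:
    """COM-distance spring between two cells (hemidesmosome proxy)."""

    cell_a: int
    cell_b: int
    rest_length: float
    stiffness: float
    breakable: bool = False
    max_length: float = np.inf


@dataclass
class PottsParams:
    """Energy parameters of the Potts Hamiltonian.

    ``J`` is the symmetric contact-energy table over type pairs;
    ``lambda_volume``/``lambda_surface`` the per-type constraint stiffnesses;
    ``chemotaxis_mu`` the per-type response to the EGF field (positive values
    bias movement up-gradient).  All arrays are indexed by cell-type code.
    """

    J: np.ndarray
    lambda_volume: np.ndarray
    lambda_surface: np.ndarray
    temperature: float
    chemotaxis_mu: np.ndarray
    links: list[LinkSpring] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=np.float64)
        self.lambda_volume = np.asarray(self.lambda_volume, dtype=np.float64)
        self.lambda_surface = np.asarray(self.lambda_surface, dtype=np.float64)
        self.chemotaxis_mu = np.asarray(self.chemotaxis_mu, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.J.shape != (N_TYPES, N_TYPES):
            raise ValueError(f"J must be {N_TYPES}x{N_TYPES}")
        if not np.allclose(self.J, self.J.T):
            raise ValueError("contact energy table J must be symmetric")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if np.any(self.lambda_volume < 0) or np.any(self.lambda_surface < 0):
            raise ValueError("constraint stiffnesses must be non-negative")

    def link_csr(self, capacity: int):
        """Compact the live link list into per-cell CSR arrays for kernels."""
        counts = np.zeros(capacity + 1, dtype=np.int64)
        for ln in self.links:
            counts[ln.cell_a + 1] += 1
            counts[ln.cell_b + 1] += 1
        ptr = np.cumsum(counts)
        n = int(ptr[-1])
        other = np.zeros(n, dtype=np.int64)
        rest = np.zeros(n, dtype=np.float64)
        stiff = np.zeros(n, dtype=np.float64)
        cursor = ptr[:-1].copy()
        for ln in self.links:
            for a, b in ((ln.cell_a, ln.cell_b), (ln.cell_b, ln.cell_a)):
                i = cursor[a]
                other[i] = b
                rest[i] = ln.rest_length
                stiff[i] = ln.stiffness
                cursor[a] += 1
        return ptr, other, rest, stiff


class CellRecord:
    """View of one agent in the registry (lightweight proxy into CellTable)."""

    __slots__ = ("_t", "id")

    def __init__(self, table: "CellTable", cid: int):
        self._t = table
        self.id = cid

    @property
    def type(self) -> int:
        return int(self._t.ctype[self.id])

    @property
    def type_name(self) -> str:
        return TYPE_NAMES[self.type]

    @property
    def volume(self) -> int:
        return int(self._t.volume[self.id])

    @property
    def target_volume(self) -> float:
        return float(self._t.target_volume[self.id])

    @target_volume.setter
    def target_volume(self, v: float) -> None:
        self._t.target_volume[self.id] = v

    @property
    def surface(self) -> int:
        return int(self._t.surface[self.id])

    @property
    def target_surface(self) -> float:
        return float(self._t.target_surface[self.id])

    @property
    def com(self) -> tuple[float, float]:
        v = self._t.volume[self.id]
        if v == 0:
            return (np.nan, np.nan)
        return (self._t.sum_x[self.id] / v, self._t.sum_y[self.id] / v)

    @property
    def age(self) -> int:
        return int(self._t.age[self.id])

    @property
    def egf_avg(self) -> float:
        return float(self._t.egf_avg[self.id])

    @property
    def pressure(self) -> float:
        return float(self._t.pressure[self.id])

    @property
    def dying(self) -> bool:
        return bool(self._t.dying[self.id])

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Cell {self.id} {self.type_name} V={self.volume}>"


class CellTable:
    """Struct-of-arrays registry of cells, indexed by cell ID.

    Index 0 is the medium pseudo-cell (type MEDIUM, never alive).  Arrays grow
    by doubling; dead IDs are never reused, so an ID identifies one cell for
    the whole run (the property cell-lineage tracking relies on).
    """

    def __init__(self, capacity: int = 256):
        self.capacity = capacity
        self.ctype = np.zeros(capacity, dtype=np.int8)
        self.volume = np.zeros(capacity, dtype=np.int64)
        self.target_volume = np.zeros(capacity, dtype=np.float64)
        self.surface = np.zeros(capacity, dtype=np.int64)
        self.target_surface = np.zeros(capacity, dtype=np.float64)
        self.sum_x = np.zeros(capacity, dtype=np.int64)
        self.sum_y = np.zeros(capacity, dtype=np.int64)
        self.age = np.zeros(capacity, dtype=np.int64)
        self.egf_avg = np.zeros(capacity, dtype=np.float64)
        self.pressure = np.zeros(capacity, dtype=np.float64)
        self.alive = np.zeros(capacity, dtype=np.bool_)
        self.dying = np.zeros(capacity, dtype=np.bool_)
        self.parent = np.zeros(capacity, dtype=np.int64)
        self.next_id = 1

    def _grow(self, need: int) -> None:
        if need < self.capacity:
            return
        new_cap = self.capacity
        while new_cap <= need:
            new_cap *= 2
        for name in ("ctype", "volume", "target_volume", "surface",
                     "target_surface", "sum_x", "sum_y", "age", "egf_avg",
                     "pressure", "alive", "dying", "parent"):
            old = getattr(self, name)
            new = np.zeros(new_cap, dtype=old.dtype)
            new[: self.capacity] = old
            setattr(self, name, new)
        self.capacity = new_cap

    def new_cell(self, ctype: int, target_volume: float = 0.0,
                 parent: int = 0) -> int:
        cid = self.next_id
        self.next_id += 1
        self._grow(cid)
        self.ctype[cid] = ctype
        self.target_volume[cid] = target_volume
        self.alive[cid] = True
        self.dying[cid] = False
        self.age[cid] = 0
        self.parent[cid] = parent
        return cid

    def kill(self, cid: int) -> None:
        self.alive[cid] = False
        self.dying[cid] = False

    def live_ids(self) -> np.ndarray:
        return np.nonzero(self.alive[: self.next_id])[0]


class _CellMapping(Mapping):
    """Read-only id → CellRecord mapping over live cells."""

    def __init__(self, table: CellTable):
        self._table = table

    def __getitem__(self, cid: int) -> CellRecord:
        if cid <= 0 or cid >= self._table.next_id or not self._table.alive[cid]:
            raise KeyError(cid)
        return CellRecord(self._table, cid)

    def __iter__(self) -> Iterator[int]:
        return iter(int(i) for i in self._table.live_ids())

    def __len__(self) -> int:
        return int(self._table.alive[: self._table.next_id].sum())


class LatticeState:
    """Pixel→cell-ID grid plus the live-cell registry.

    Invariants: the grid is a partition (every pixel has exactly one owner);
    each live cell's bookkept volume equals its pixel count; volume-0 cells
    are removed from the registry.
    """

    def __init__(self, width: int = 200, height: int = 90,
                 pixel_um: float = PIXEL_UM):
        self.width = width
        self.height = height
        self.pixel_um = pixel_um
        self.owner_grid = np.zeros((height, width), dtype=np.int64)
        self.table = CellTable()
        self.mcs_counter = 0

    # -- registry views ----------------------------------------------------
    @property
    def cells(self) -> Mapping:
        return _CellMapping(self.table)

    @property
    def dims(self) -> tuple[int, int]:
        return (self.width, self.height)

    def cell(self, cid: int) -> CellRecord:
        return CellRecord(self.table, cid)

    def type_grid(self) -> np.ndarray:
        return self.table.ctype[self.owner_grid]

    def ids_of_type(self, *types: int) -> np.ndarray:
        t = self.table
        live = t.live_ids()
        sel = np.isin(t.ctype[live], np.asarray(types, dtype=np.int8))
        return live[sel]

    def counts_by_type(self) -> dict[int, int]:
        t = self.table
        live = t.live_ids()
        out: dict[int, int] = {}
        for code in range(N_TYPES):
            out[code] = int(np.count_nonzero(t.ctype[live] == code))
        return out

    def epithelial_ids(self) -> np.ndarray:
        t = self.table
        live = t.live_ids()
        return live[EPITHELIAL_MASK[t.ctype[live]]]

    def pixels_of(self, cid: int) -> tuple[np.ndarray, np.ndarray]:
        """(ys, xs) of the pixels owned by cid (full-grid scan)."""
        return np.nonzero(self.owner_grid == cid)

    # -- bookkeeping -------------------------------------------------------
    def refresh_stats(self) -> None:
        """Recompute per-cell volume, COM sums and boundary faces by rescan,
        and purge cells whose pixel count reached zero."""
        t = self.table
        _kernels.refresh_stats(self.owner_grid, t.volume, t.sum_x, t.sum_y,
                               t.surface)
        gone = np.nonzero((t.volume[: t.next_id] == 0) & t.alive[: t.next_id])[0]
        for cid in gone:
            t.kill(int(cid))

    def n_active_sites(self) -> int:
        return int(np.count_nonzero(~FROZEN_MASK[self.type_grid()]))

    def check_invariants(self) -> None:
        """Raise if the partition/bookkeeping invariants are violated."""
        t = self.table
        vol = np.bincount(self.owner_grid.ravel(), minlength=t.capacity)
        mism = np.nonzero(vol[: t.next_id] != t.volume[: t.next_id])[0]
        if len(mism):
            raise AssertionError(f"volume bookkeeping mismatch for ids {mism[:5]}")
        zombie = np.nonzero(t.alive[: t.next_id] & (vol[: t.next_id] == 0))[0]
        if len(zombie):
            raise AssertionError(f"volume-0 cells still registered: {zombie[:5]}")
        orphan_ids = np.unique(self.owner_grid)
        orphan_ids = orphan_ids[orphan_ids > 0]
        dead = orphan_ids[~t.alive[orphan_ids]]
        if len(dead):
            raise AssertionError(f"pixels owned by dead cells: {dead[:5]}")


def compute_pressure(cell: CellRecord, params: PottsParams) -> float:
    """Effective internal pressure of a growth-competent cell.

    P = max(0, λ_V · (V_target − V)): the Lagrange-multiplier force of the
    volume constraint, clamped so that overshoot does not read as crowding.
    A crowded cell that cannot reach its target volume reports high pressure.
    """
    lam = params.lambda_volume[cell.type]
    return max(0.0, float(lam * (cell.target_volume - cell.volume)))


def update_pressures(state: LatticeState, params: PottsParams) -> None:
    """Vectorized pressure update for every live cell."""
    t = state.table
    n = t.next_id
    lam = params.lambda_volume[t.ctype[:n]]
    p = lam * (t.target_volume[:n] - t.volume[:n])
    np.maximum(p, 0.0, out=p)
    p[~t.alive[:n]] = 0.0
    t.pressure[:n] = p


def _field_conc(fields) -> tuple[np.ndarray, bool]:
    """Pick the chemotactic field (named 'EGF', else the first one)."""
    if not fields:
        return np.zeros((1, 1)), False
    for f in fields:
        if getattr(f, "name", "") == "EGF":
            return f.conc, True
    return fields[0].conc, True


def delta_hamiltonian(state: LatticeState, params: PottsParams,
                      fields: Sequence, source_px: tuple[int, int],
                      target_px: tuple[int, int]) -> float:
    """Exact incremental energy change of copying the source pixel's owner
    onto the target pixel.

    Raises ValueError for off-lattice pixels, identical owners, non-adjacent
    pixels, or frozen owners (frozen types reject copies in both directions).
    """
    sx, sy = source_px
    x, y = target_px
    for (px, py) in ((sx, sy), (x, y)):
        if not (0 <= px < state.width and 0 <= py < state.height):
            raise ValueError(f"pixel {(px, py)} out of bounds")
    if max(abs(sx - x), abs(sy - y)) != 1:
        raise ValueError("source and target must be lattice neighbors")
    ot = state.owner_grid[y, x]
    os_ = state.owner_grid[sy, sx]
    if os_ == ot:
        raise ValueError("source and target owners are identical")
    t = state.table
    if FROZEN_MASK[t.ctype[ot]] or FROZEN_MASK[t.ctype[os_]]:
        raise ValueError("copy attempts involving frozen types are rejected")
    conc, use_conc = _field_conc(fields)
    lptr, lother, lrest, lk = params.link_csr(t.capacity)
    return float(_kernels.delta_h(
        state.owner_grid, t.ctype, t.volume, t.target_volume, t.surface,
        t.target_surface, t.sum_x, t.sum_y,
        params.J, params.lambda_volume, params.lambda_surface,
        params.chemotaxis_mu, conc, use_conc,
        lptr, lother, lrest, lk, len(params.links), sx, sy, x, y))


def metropolis_mcs(state: LatticeState, params: PottsParams,
                   fields: Sequence = (), rng: Optional[object] = None,
                   n_attempts: Optional[int] = None) -> int:
    """Perform one Monte Carlo Step in place; returns accepted flip count.

    The kernel consumes numba's internal RNG stream; seed it once per run
    with :func:`corneasim.potts.seed_kernel` for reproducibility.
    """
    t = state.table
    if n_attempts is None:
        n_attempts = state.n_active_sites()
    conc, use_conc = _field_conc(fields)
    lptr, lother, lrest, lk = params.link_csr(t.capacity)
    flips = _kernels.metropolis_sweep(
        state.owner_grid, t.ctype, t.volume, t.target_volume, t.surface,
        t.target_surface, t.sum_x, t.sum_y, t.alive,
        params.J, params.lambda_volume, params.lambda_surface,
        params.temperature, params.chemotaxis_mu, conc, use_conc,
        FROZEN_MASK, lptr, lother, lrest, lk, len(params.links),
        n_attempts)
    # purge cells emptied during the sweep
    n = t.next_id
    emptied = np.nonzero((t.volume[:n] == 0) & t.dying[:n])[0]
    for cid in emptied:
        t.kill(int(cid))
    state.mcs_counter += 1
    return int(flips)


def seed_kernel(seed: int) -> None:
    """Seed the Metropolis kernel's RNG stream."""
    _kernels.seed_rng(int(seed) & 0x7FFFFFFF)
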