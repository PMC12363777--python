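"""Biological rule engine, applied once per MCS: EGF- and density-regulated
growth, volume-triggered mitosis, contact-triggered differentiation, and
probabilistic sloughing of tear-exposed superficial cells.

Growth of stem and basal cells advances the target volume by

    dV_t/dMCS = δ · [km_d⁴ / (km_d⁴ + P⁴)] · [E⁴ / (km_E⁴ + E⁴)]

where E is the cell's mean EGF and P its crowding pressure.  δ is calibrated
from the 8-hour minimum doubling interval: 25 px gained in 80 MCS, i.e.
0.3125 px/MCS.  Differentiation is deterministic and immediate:

    STEM → BASAL   when the cell no longer touches the limbal membrane;
    BASAL → WING   when its basement-membrane contact area drops to ≤ ω px;
    WING → SUPER   when it touches tear film and another wing cell and none
                   of {BASAL, central membrane, STEM}.

Superficial cells in tear contact slough with probability 1/(3·DaytoMCS)
per MCS, giving a geometric lifetime of mean 3 days.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from . import _kernels
from .fields import ScalarField
from .potts import LatticeState, PottsParams, update_pressures
from .types import (
    BASAL,
    DAY_TO_MCS,
    LIMB,
    MEMB,
    N_TYPES,
    STEM,
    SUPER,
    TEAR,
    WING,
)

__all__ = [
    "ContactData",
    "RuleParams",
    "apply_growth",
    "attempt_mitosis",
    "differentiate",
    "growth_density",
    "growth_egf",
    "mitosis_sweep",
    "slough",
]


@dataclass
class RuleParams:
    """Parameters of the cell behavior rules.

    ``km_egf``/``km_density`` are per-type Hill half-saturation constants
    (indexable arrays; only STEM and BASAL entries are consulted).  Stem
    cells are slow-cycling, so their EGF half-saturation sits above the
    basal one (calibrated, not printed in the source text).
    """

    km_egf: np.ndarray = dc_field(default_factory=lambda: _per_type(
        {STEM: 0.60, BASAL: 0.45}))
    km_density: np.ndarray = dc_field(default_factory=lambda: _per_type(
        {STEM: 8.0, BASAL: 8.0}))
    hill_n: int = 4
    delta_max: float = 25.0 / 80.0          # px/MCS; 8 h minimum doubling
    init_volume: int = 25                   # px (100 μm²)
    mitosis_volume: int = 50                # px (200 μm²)
    omega_contact_basal: int = 5            # px, A_EpBM threshold
    day_to_mcs: int = DAY_TO_MCS
    slough_prob_per_mcs: float = 1.0 / (3 * DAY_TO_MCS)

    def __post_init__(self) -> None:
        self.km_egf = np.asarray(self.km_egf, dtype=np.float64)
        self.km_density = np.asarray(self.km_density, dtype=np.float64)
        if self.hill_n != 4:
            raise ValueError("both Hill exponents are fixed at 4")
        if self.mitosis_volume != 2 * self.init_volume:
            raise ValueError("mitosis volume must be twice the initial volume")
        if not (0.0 < self.slough_prob_per_mcs < 1.0):
            raise ValueError("slough probability must be in (0, 1)")


def _per_type(values: dict) -> np.ndarray:
    arr = np.full(N_TYPES, np.nan)
    for t, v in values.items():
        arr[t] = v
    return arr


# --------------------------------------------------------------------------
# growth (Hill activation by EGF, Hill inhibition by pressure)
# --------------------------------------------------------------------------

def growth_egf(egf_avg, km: float, n: int = 4):
    """EGF-dependent growth fraction E^n/(km^n + E^n) ∈ [0, 1]."""
    e = np.asarray(egf_avg, dtype=np.float64)
    if np.any(e < 0):
        raise ValueError("EGF concentration must be non-negative")
    en = e ** n
    out = en / (km ** n + en)
    return float(out) if np.isscalar(egf_avg) else out


def growth_density(pressure, km: float, n: int = 4):
    """Density-inhibition fraction km^n/(km^n + P^n) ∈ [0, 1], decreasing."""
    p = np.asarray(pressure, dtype=np.float64)
    if np.any(p < 0):
        raise ValueError("pressure must be non-negative")
    kn = km ** n
    out = kn / (kn + p ** n)
    return float(out) if np.isscalar(pressure) else out


def apply_growth(state: LatticeState, fld: ScalarField, rules: RuleParams,
                 potts: PottsParams) -> None:
    """Advance target volumes of live, non-dying STEM and BASAL cells by
    δ · G_density(P) · G_EGF(E).  Other types are non-proliferative."""
    update_pressures(state, potts)
    t = state.table
    n = t.next_id
    grow = (t.alive[:n] & ~t.dying[:n]
            & ((t.ctype[:n] == STEM) | (t.ctype[:n] == BASAL)))
    ids = np.nonzero(grow)[0]
    if len(ids) == 0:
        return
    tt = t.ctype[ids]
    km_e = rules.km_egf[tt]
    km_d = rules.km_density[tt]
    e = t.egf_avg[ids]
    p = t.pressure[ids]
    ge = e ** rules.hill_n / (km_e ** rules.hill_n + e ** rules.hill_n)
    gd = km_d ** rules.hill_n / (km_d ** rules.hill_n + p ** rules.hill_n)
    t.target_volume[ids] += rules.delta_max * ge * gd
    # keep the (optional) surface constraint target consistent with growth
    t.target_surface[ids] = 4.0 * np.sqrt(t.target_volume[ids])


# --------------------------------------------------------------------------
# mitosis
# --------------------------------------------------------------------------

def attempt_mitosis(state: LatticeState, cid: int, rng: np.random.Generator):
    """Split one STEM/BASAL cell of volume ≥ 50 px along a cleavage plane
    through its COM; returns (daughter_a, daughter_b) ids or None.

    Stem cells divide with a vertical plane so the daughters separate along
    the x axis (centripetal direction); basal cells use a uniformly random
    plane orientation.  Pixels are ranked by their signed projection on the
    plane normal and split at the median, so the daughters' volumes differ by
    at most one pixel; both daughters inherit the parent type and their
    target volumes are reset to their actual volumes.
    """
    t = state.table
    ctype = int(t.ctype[cid])
    if ctype not in (STEM, BASAL):
        return None
    if t.volume[cid] < 50 or t.dying[cid] or not t.alive[cid]:
        return None
    ys, xs = state.pixels_of(cid)
    if ctype == STEM:
        nx_, ny_ = 1.0, 0.0
    else:
        theta = rng.uniform(0.0, np.pi)
        nx_, ny_ = np.cos(theta), np.sin(theta)
    proj = xs * nx_ + ys * ny_
    # stable secondary key keeps the split deterministic for tied projections
    order = np.lexsort((ys, xs, proj))
    half = len(order) // 2
    ia, ib = order[:half], order[half:]
    da = t.new_cell(ctype, parent=cid)
    db = t.new_cell(ctype, parent=cid)
    state.owner_grid[ys[ia], xs[ia]] = da
    state.owner_grid[ys[ib], xs[ib]] = db
    t.kill(cid)
    # local bookkeeping (full refresh happens at the end of the MCS pipeline)
    for d, idx in ((da, ia), (db, ib)):
        t.volume[d] = len(idx)
        t.sum_x[d] = int(xs[idx].sum())
        t.sum_y[d] = int(ys[idx].sum())
        t.target_volume[d] = float(len(idx))
        t.target_surface[d] = 4.0 * np.sqrt(float(len(idx)))
    t.volume[cid] = 0
    return da, db


def mitosis_sweep(state: LatticeState, rules: RuleParams,
                  rng: np.random.Generator) -> list[tuple[int, int, int]]:
    """Divide every eligible cell; returns (parent, daughter_a, daughter_b)."""
    t = state.table
    n = t.next_id
    ready = np.nonzero(
        t.alive[:n] & ~t.dying[:n]
        & ((t.ctype[:n] == STEM) | (t.ctype[:n] == BASAL))
        & (t.volume[:n] >= rules.mitosis_volume))[0]
    events = []
    for cid in ready:
        out = attempt_mitosis(state, int(cid), rng)
        if out is not None:
            events.append((int(cid), out[0], out[1]))
    return events


# --------------------------------------------------------------------------
# differentiation and sloughing
# --------------------------------------------------------------------------

class ContactData:
    """Snapshot of the neighbor relation used by differentiation/sloughing."""

    def __init__(self, state: LatticeState):
        t = state.table
        self.nbr_mask = np.zeros(t.capacity, dtype=np.int64)
        self.aepbm = np.zeros(t.capacity, dtype=np.int64)
        _kernels.contact_scan(state.owner_grid, t.ctype, self.nbr_mask,
                              self.aepbm)

    def touches(self, cid, type_code: int):
        return (self.nbr_mask[cid] >> type_code) & 1 == 1


def differentiate(state: LatticeState, rules: RuleParams,
                  contacts: ContactData | None = None) -> list[tuple[int, int, int]]:
    """Apply the three deterministic transitions simultaneously from one
    snapshot of the neighbor relation; returns (cell, old_type, new_type)."""
    if contacts is None:
        contacts = ContactData(state)
    t = state.table
    n = t.next_id
    live = t.alive[:n] & ~t.dying[:n]
    mask = contacts.nbr_mask[:n]
    events: list[tuple[int, int, int]] = []

    stem = np.nonzero(live & (t.ctype[:n] == STEM)
                      & ((mask >> LIMB) & 1 == 0))[0]
    basal = np.nonzero(live & (t.ctype[:n] == BASAL)
                       & (contacts.aepbm[:n] <= rules.omega_contact_basal))[0]
    wing_ok = ((mask >> TEAR) & 1 == 1) & ((mask >> WING) & 1 == 1) \
        & ((mask >> BASAL) & 1 == 0) & ((mask >> MEMB) & 1 == 0) \
        & ((mask >> STEM) & 1 == 0)
    wing = np.nonzero(live & (t.ctype[:n] == WING) & wing_ok)[0]

    for cid in stem:
        events.append((int(cid), STEM, BASAL))
    for cid in basal:
        events.append((int(cid), BASAL, WING))
    for cid in wing:
        events.append((int(cid), WING, SUPER))
    t.ctype[stem] = BASAL
    t.ctype[basal] = WING
    t.ctype[wing] = SUPER
    return events


def slough(state: LatticeState, rules: RuleParams, rng: np.random.Generator,
           tear_id: int, contacts: ContactData | None = None) -> list[int]:
    """Remove tear-contacting superficial cells with probability 1/(3·DaytoMCS)
    per MCS; their pixels become tear film.  Returns sloughed cell ids."""
    if contacts is None:
        contacts = ContactData(state)
    t = state.table
    # cells created after the contact snapshot have no entry (and are
    # daughters of proliferative types, never superficial)
    n = min(t.next_id, len(contacts.nbr_mask))
    cand = np.nonzero(t.alive[:n] & (t.ctype[:n] == SUPER)
                      & ((contacts.nbr_mask[:n] >> TEAR) & 1 == 1))[0]
    if len(cand) == 0:
        return []
    u = rng.random(len(cand))
    gone = cand[u < rules.slough_prob_per_mcs]
    for cid in gone:
        ys, xs = state.pixels_of(int(cid))
        state.owner_grid[ys, xs] = tear_id
        t.volume[tear_id] += len(ys)
        t.sum_x[tear_id] += int(xs.sum())
        t.sum_y[tear_id] += int(ys.sum())
        t.volume[cid] = 0
        t.kill(int(cid))
    return [int(c) for c in gone]
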