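"""Injury mechanisms: instantaneous circular ablation and chemical exposure
via a diffusing toxicant with threshold-triggered death, plus depth
classification (slight / mild / moderate).

Ablation removes every epithelial cell whose center of mass lies inside a
disc and hands the vacated pixels to the tear film (reflecting increased
tear production).  Chemical exposure deposits a Gaussian droplet (or a
uniform surface dose) into a toxicant field that then diffuses and decays;
cells whose mean exposure exceeds the kill threshold die by shrinkage
(target volume set to zero), and basement-membrane pixels above threshold
are permanently destroyed — opening the moderate-injury, recurrent-erosion
pathway.  Injury depth is classified by the deepest structure hit:
slight = superficial/wing only, mild = reaches basal cells, moderate =
breaches the membrane / reaches the stroma.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .fields import ScalarField
from .potts import LatticeState
from .types import (
    BASAL,
    DAMG,
    EPITHELIAL_MASK,
    LIMB,
    MEMB,
    STEM,
    SUPER,
    TEAR,
    TYPE_NAMES,
    WING,
)

__all__ = [
    "InjuryReport",
    "InjurySpec",
    "ablate",
    "apply_chemical",
    "kill_by_concentration",
]

SLIGHT, MILD, MODERATE = "slight", "mild", "moderate"


@dataclass
class InjurySpec:
    """One injury event.

    mode: 'ablation' (disc removal), 'chemical_droplet' (Gaussian deposit of
    ``amplitude`` a.u. at ``center``; sigma → 0 collapses to a single-pixel
    point deposit) or 'chemical_uniform' (adds ``amplitude`` to every tear
    pixel adjacent to the epithelial surface).  ``apply_at`` is the MCS at
    which the event fires.
    """

    mode: str = "chemical_droplet"
    center: tuple[int, int] = (100, 75)
    radius: float = 0.0
    amplitude: float = 750.0
    sigma: float = 0.0
    kill_threshold: float = 0.1
    apply_at: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("ablation", "chemical_droplet", "chemical_uniform"):
            raise ValueError(f"unknown injury mode {self.mode!r}")
        if self.amplitude < 0 or self.radius < 0:
            raise ValueError("amplitude and radius must be non-negative")
        if self.kill_threshold <= 0:
            raise ValueError("kill threshold must be positive")


@dataclass
class InjuryReport:
    """Tally of structures destroyed by one injury (possibly over many MCS)."""

    killed_by_type: dict = dc_field(default_factory=dict)
    membrane_pixels_destroyed: int = 0

    def record(self, type_code: int, count: int = 1) -> None:
        name = TYPE_NAMES[type_code]
        self.killed_by_type[name] = self.killed_by_type.get(name, 0) + count

    def merge(self, other: "InjuryReport") -> None:
        for k, v in other.killed_by_type.items():
            self.killed_by_type[k] = self.killed_by_type.get(k, 0) + v
        self.membrane_pixels_destroyed += other.membrane_pixels_destroyed

    @property
    def deepest_layer_hit(self) -> str | None:
        if self.membrane_pixels_destroyed > 0:
            return "EpBM/STROMA"
        for code, label in ((BASAL, "BASAL"), (STEM, "BASAL"),
                            (WING, "WING"), (SUPER, "SUPER")):
            if self.killed_by_type.get(TYPE_NAMES[code], 0) > 0:
                return label
        return None

    @property
    def classification(self) -> str | None:
        deepest = self.deepest_layer_hit
        if deepest is None:
            return None
        if deepest == "EpBM/STROMA":
            return MODERATE
        if deepest == "BASAL":
            return MILD
        return SLIGHT


def ablate(state: LatticeState, spec: InjurySpec,
           tear_id: int) -> InjuryReport:
    """Remove epithelial cells whose COM lies inside the disc; pixels become
    tear film.  Frozen structures are untouched."""
    if spec.mode != "ablation":
        raise ValueError("spec.mode must be 'ablation'")
    cx, cy = spec.center
    if not (0 <= cx - spec.radius and cx + spec.radius < state.width
            and 0 <= cy - spec.radius and cy + spec.radius < state.height):
        raise ValueError("ablation disc extends outside the lattice")
    report = InjuryReport()
    t = state.table
    for cid in state.epithelial_ids():
        v = t.volume[cid]
        if v == 0:
            continue
        comx = t.sum_x[cid] / v
        comy = t.sum_y[cid] / v
        if (comx - cx) ** 2 + (comy - cy) ** 2 <= spec.radius ** 2:
            ys, xs = state.pixels_of(int(cid))
            state.owner_grid[ys, xs] = tear_id
            report.record(int(t.ctype[cid]))
            t.volume[cid] = 0
            t.kill(int(cid))
    state.refresh_stats()
    return report


def apply_chemical(toxicant: ScalarField, spec: InjurySpec,
                   state: LatticeState | None = None) -> ScalarField:
    """Deposit the chemical dose into the toxicant field (instantaneous).

    Droplet: adds amplitude·exp(−‖p−center‖²/(2σ²)); with σ → 0 the whole
    amplitude lands on the center pixel (the printed point-exposure mode).
    Uniform: adds the amplitude to every tear pixel bordering the epithelium
    (requires ``state``).  The field subsequently evolves by its own
    diffusion/decay dynamics.
    """
    if spec.mode not in ("chemical_droplet", "chemical_uniform"):
        raise ValueError("spec.mode must be a chemical mode")
    H, W = toxicant.conc.shape
    if spec.mode == "chemical_droplet":
        cx, cy = spec.center
        if spec.sigma <= 0:
            toxicant.conc[cy, cx] += spec.amplitude
        else:
            yy, xx = np.mgrid[0:H, 0:W]
            r2 = (xx - cx) ** 2.0 + (yy - cy) ** 2.0
            toxicant.conc += spec.amplitude * np.exp(-r2 / (2.0 * spec.sigma ** 2))
    else:
        if state is None:
            raise ValueError("uniform exposure needs the lattice state")
        tg = state.type_grid()
        tear = tg == TEAR
        epith = EPITHELIAL_MASK[tg]
        near = np.zeros_like(epith)
        near[:-1, :] |= epith[1:, :]
        near[1:, :] |= epith[:-1, :]
        near[:, :-1] |= epith[:, 1:]
        near[:, 1:] |= epith[:, :-1]
        toxicant.conc[tear & near] += spec.amplitude
    return toxicant


def kill_by_concentration(state: LatticeState, toxicant: ScalarField,
                          kill_threshold: float,
                          damaged_id: int) -> InjuryReport:
    """Mark epithelial cells whose mean toxicant exposure exceeds the
    threshold as dying (target volume → 0; removal happens by shrinkage),
    and permanently destroy membrane pixels whose local concentration
    exceeds it (converted to the passive damaged state ``damaged_id``).
    """
    report = InjuryReport()
    t = state.table
    # per-cell mean exposure
    sums = np.zeros(t.capacity)
    from . import _kernels
    _kernels.field_cell_sums(state.owner_grid, toxicant.conc, sums)
    n = t.next_id
    vol = t.volume[:n].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_tox = np.where(vol > 0, sums[:n] / vol, 0.0)
    doomed = np.nonzero(t.alive[:n] & ~t.dying[:n]
                        & EPITHELIAL_MASK[t.ctype[:n]]
                        & (mean_tox > kill_threshold))[0]
    for cid in doomed:
        t.dying[cid] = True
        t.target_volume[cid] = 0.0
        report.record(int(t.ctype[cid]))
    # membrane destruction (no regeneration)
    tg = state.type_grid()
    memb = ((tg == MEMB) | (tg == LIMB)) & (toxicant.conc > kill_threshold)
    ndest = int(memb.sum())
    if ndest:
        state.owner_grid[memb] = damaged_id
        report.membrane_pixels_destroyed = ndest
        state.refresh_stats()
        state.table.alive[damaged_id] = True
    return report
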