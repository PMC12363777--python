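"""Scenario orchestration: day-0 tissue assembly, the per-MCS pipeline, and
seeded replicate campaigns.

The fixed per-MCS pipeline is: field update → growth → differentiation →
mitosis → sloughing → Metropolis dynamics, followed by renormalization of
the tear band.  Scheduled injuries (ablation or chemical deposition) fire at
the top of their MCS, and concentration-triggered death is evaluated every
MCS while the toxicant field is live.  Each replicate owns one master seed
from which the rule-engine Generator and the Metropolis kernel stream are
derived, so trajectories are bit-reproducible per seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from . import _kernels
from .config import SimConfig, default_config
from .fields import (
    ScalarField,
    relax_to_steady_state,
    step_field,
    update_cell_averages,
)
from .injury import InjuryReport, InjurySpec, ablate, apply_chemical, \
    kill_by_concentration
from .potts import LatticeState, PottsParams, metropolis_mcs, seed_kernel
from .rules import ContactData, RuleParams, differentiate, mitosis_sweep, \
    slough, apply_growth
from .types import (
    BASAL,
    DAMG,
    LIMB,
    MEMB,
    N_TYPES,
    STEM,
    STROMA,
    SUPER,
    TEAR,
    TYPE_NAMES,
    WALL,
    WING,
)

__all__ = ["CellSample", "RunResult", "Simulation", "build_initial_state",
           "run", "run_replicates"]


@dataclass
class CellSample:
    """Per-cell snapshot at one sampled MCS (id, type, COM)."""

    mcs: int
    ids: np.ndarray
    ctype: np.ndarray
    com_x: np.ndarray
    com_y: np.ndarray
    volume: np.ndarray

    def counts(self) -> dict[str, int]:
        out = {}
        for code in (STEM, BASAL, WING, SUPER):
            out[TYPE_NAMES[code]] = int(np.count_nonzero(self.ctype == code))
        return out


@dataclass
class RunResult:
    """Outputs of one seeded run: sampled trajectories, events, final state."""

    config: SimConfig
    seed: int
    samples: list = dc_field(default_factory=list)
    events: list = dc_field(default_factory=list)
    injury_reports: list = dc_field(default_factory=list)
    snapshots: list = dc_field(default_factory=list)
    state: Optional[LatticeState] = None
    pixel_um: float = 2.0
    sim: Optional["Simulation"] = None

    @property
    def day_to_mcs(self) -> int:
        return self.config.rules.day_to_mcs

    def sample_days(self) -> np.ndarray:
        return np.array([s.mcs for s in self.samples]) / self.day_to_mcs


def _rule_params(cfg: SimConfig) -> RuleParams:
    km_e = np.full(N_TYPES, np.nan)
    km_e[STEM] = cfg.rules.km_egf_stem
    km_e[BASAL] = cfg.rules.km_egf_basal
    km_d = np.full(N_TYPES, np.nan)
    km_d[STEM] = cfg.rules.km_density_stem
    km_d[BASAL] = cfg.rules.km_density_basal
    return RuleParams(
        km_egf=km_e, km_density=km_d, hill_n=cfg.rules.hill_n,
        delta_max=cfg.rules.delta_max, init_volume=cfg.rules.init_volume,
        mitosis_volume=cfg.rules.mitosis_volume,
        omega_contact_basal=cfg.rules.omega_contact_basal,
        day_to_mcs=cfg.rules.day_to_mcs,
        slough_prob_per_mcs=1.0 / (3 * cfg.rules.day_to_mcs))


def _potts_params(cfg: SimConfig) -> PottsParams:
    p = cfg.potts
    return PottsParams(
        J=p.j_table(),
        lambda_volume=p.per_type(p.lambda_volume),
        lambda_surface=p.per_type(p.lambda_surface),
        temperature=p.temperature,
        chemotaxis_mu=p.per_type(p.chemotaxis_mu))


class Simulation:
    """Owns the lattice, fields, parameters and RNG streams of one run."""

    def __init__(self, config: Optional[SimConfig] = None,
                 seed: Optional[int] = None):
        self.config = (config or default_config()).validate()
        self.seed = int(self.config.run.seed if seed is None else seed)
        self.potts = _potts_params(self.config)
        self.rules = _rule_params(self.config)
        self.state = LatticeState(self.config.geometry.width,
                                  self.config.geometry.height,
                                  self.config.geometry.pixel_um)
        self.tear_id = 0
        self.damaged_id = 0
        self.egf: Optional[ScalarField] = None
        self.toxicant: Optional[ScalarField] = None
        self.toxicant_active = False
        self.pending_reports: list = []
        self.reseed(self.seed)
        self._build()

    # -- randomness --------------------------------------------------------
    def reseed(self, seed: int) -> None:
        """Derive the two substreams (rule engine, Metropolis kernel) from
        one master seed.  The kernel stream is re-derived per MCS from
        (master seed, MCS counter), so cloned/interleaved simulations stay
        independent even though numba's RNG state is global."""
        self.seed = int(seed)
        ss = np.random.SeedSequence(self.seed)
        child_rules, child_kernel = ss.spawn(2)
        self.rng = np.random.Generator(np.random.PCG64(child_rules))
        self._kernel_seed = int(child_kernel.generate_state(1)[0]) & 0x7FFFFFFF

    # -- construction -------------------------------------------------------
    def _build(self) -> None:
        g = self.config.geometry
        state = self.state
        t = state.table
        grid = state.owner_grid
        W, H = g.width, g.height
        ym = g.stroma_rows                      # membrane row
        wall = t.new_cell(WALL)
        stroma = t.new_cell(STROMA)
        limb = t.new_cell(LIMB)
        memb = t.new_cell(MEMB)
        self.tear_id = t.new_cell(TEAR)
        # pre-allocated id for destroyed membrane pixels; registered as a
        # live cell only once an injury gives it pixels
        self.damaged_id = t.new_cell(DAMG)
        grid[:, 0] = wall
        grid[:, W - 1] = wall
        grid[:ym, 1:W - 1] = stroma
        grid[ym, 1:g.limbal_width] = limb
        grid[ym, g.limbal_width:W - 1] = memb
        # stem seeds: two stacked rows of blocks on the limbal membrane
        # segment (a crypt-like packing; the upper row loses limbal contact
        # at the first step and converts, seeding the basal sheet)
        b = g.stem_block
        for row in range(g.stem_rows):
            x = 1
            while x + b <= g.limbal_width:
                cid = t.new_cell(STEM, target_volume=float(b * b))
                y0 = ym + 1 + row * b
                grid[y0:y0 + b, x:x + b] = cid
                x += b
        # tear band + air above
        _kernels.renormalize_tear(grid, t.ctype, self.tear_id,
                                  g.tear_thickness)
        state.refresh_stats()
        # EGF field relaxed to its tear-clamped steady configuration
        e = self.config.egf
        self.egf = ScalarField(
            name="EGF", conc=np.zeros((H, W)), decay_rate=e.kd,
            global_diffusion=e.d_global,
            diffusion_by_type=e.diffusion_by_type(),
            clamp_type=TEAR, clamp_value=e.clamp_value,
            n_substeps=e.n_substeps)
        relax_to_steady_state(self.egf, state, tol=1e-5, max_mcs=120)
        update_cell_averages(self.egf, state)

    def _injury_specs(self) -> list[tuple[int, InjurySpec]]:
        out = []
        for ic in self.config.injuries:
            spec = InjurySpec(
                mode=ic.mode, center=tuple(ic.center), radius=ic.radius,
                amplitude=ic.amplitude, sigma=ic.sigma,
                kill_threshold=self.config.toxicant.kill_threshold,
                apply_at=int(round(ic.apply_at_day *
                                   self.config.rules.day_to_mcs)))
            out.append((spec.apply_at, spec))
        return out

    def _ensure_toxicant(self) -> ScalarField:
        if self.toxicant is None:
            tx = self.config.toxicant
            self.toxicant = ScalarField(
                name="toxicant",
                conc=np.zeros_like(self.egf.conc),
                decay_rate=tx.kd, global_diffusion=tx.d_global,
                diffusion_by_type=tx.diffusion_by_type(),
                clamp_type=None, n_substeps=tx.n_substeps)
        return self.toxicant

    # -- the per-MCS pipeline ------------------------------------------------
    def step(self, injuries: Optional[list] = None) -> None:
        state = self.state
        t = state.table
        mcs = state.mcs_counter
        # 1. fields
        step_field(self.egf, state)
        update_cell_averages(self.egf, state)
        if self.toxicant_active:
            step_field(self.toxicant, state)
        # 2. scheduled injuries
        if injuries:
            for at, spec in injuries:
                if at != mcs:
                    continue
                if spec.mode == "ablation":
                    rep = ablate(state, spec, self.tear_id)
                    self.pending_reports.append((mcs, rep))
                else:
                    apply_chemical(self._ensure_toxicant(), spec, state)
                    self.toxicant_active = True
                    self.pending_reports.append((mcs, InjuryReport()))
        # 3. concentration-triggered death
        if self.toxicant_active:
            rep = kill_by_concentration(
                state, self.toxicant, self.config.toxicant.kill_threshold,
                self.damaged_id)
            if self.pending_reports:
                self.pending_reports[-1][1].merge(rep)
            if self.toxicant.conc.max() < 1e-3 * \
                    self.config.toxicant.kill_threshold:
                self.toxicant_active = False
        # 4. growth
        apply_growth(state, self.egf, self.rules, self.potts)
        # 5-7. differentiation, mitosis, sloughing
        contacts = ContactData(state)
        self.last_events = {
            "diff": differentiate(state, self.rules, contacts),
            "mitosis": mitosis_sweep(state, self.rules, self.rng),
            "slough": slough(state, self.rules, self.rng, self.tear_id,
                             contacts=contacts),
        }
        # 8. Metropolis dynamics (kernel stream derived per MCS)
        state.refresh_stats()
        seed_kernel((self._kernel_seed * 1000003 + mcs + 1) & 0x7FFFFFFF)
        metropolis_mcs(state, self.potts, [self.egf])
        # 9. renormalize the tear band, refresh bookkeeping, age cells
        _kernels.renormalize_tear(state.owner_grid, t.ctype, self.tear_id,
                                  self.config.geometry.tear_thickness)
        state.refresh_stats()
        t.age[: t.next_id][t.alive[: t.next_id]] += 1

    def sample(self) -> CellSample:
        t = self.state.table
        ids = self.state.epithelial_ids()
        v = t.volume[ids].astype(np.int32)
        with np.errstate(invalid="ignore", divide="ignore"):
            cx = np.where(v > 0, t.sum_x[ids] / np.maximum(v, 1), np.nan)
            cy = np.where(v > 0, t.sum_y[ids] / np.maximum(v, 1), np.nan)
        return CellSample(
            mcs=self.state.mcs_counter, ids=ids.astype(np.int32),
            ctype=t.ctype[ids].copy(),
            com_x=cx.astype(np.float32), com_y=cy.astype(np.float32),
            volume=v)

    def clone(self, seed: Optional[int] = None) -> "Simulation":
        """Deep-copy the simulation (for branching injury scenarios from a
        shared homeostatic base state); optionally reseed the branch."""
        other = copy.copy(self)
        other.state = copy.deepcopy(self.state)
        other.egf = copy.deepcopy(self.egf)
        other.toxicant = copy.deepcopy(self.toxicant)
        other.pending_reports = list(self.pending_reports)
        other.config = copy.deepcopy(self.config)
        other.potts = _potts_params(other.config)
        other.rules = _rule_params(other.config)
        if seed is not None:
            other.reseed(seed)
        return other


def build_initial_state(config: Optional[SimConfig] = None) -> LatticeState:
    """Day-0 state: stroma, split basement membrane, limbal stem seeds, tear
    film and air — no basal/wing/superficial cells yet."""
    return Simulation(config, seed=0).state


def run(config: Optional[SimConfig] = None, seed: Optional[int] = None,
        sim: Optional[Simulation] = None, run_mcs: Optional[int] = None,
        injuries: Optional[list] = None,
        check_invariants: bool = False) -> RunResult:
    """Execute the per-MCS pipeline for the configured run length.

    Pass ``sim`` to continue a prepared simulation (e.g. an injured branch
    of a homeostatic base run); otherwise a fresh day-0 simulation is built.
    ``injuries`` overrides the config's schedule with explicit
    (apply_at_mcs, InjurySpec) pairs.
    """
    if sim is None:
        sim = Simulation(config, seed=seed)
    cfg = sim.config
    n_mcs = cfg.run.run_mcs if run_mcs is None else int(run_mcs)
    if injuries is None:
        injuries = sim._injury_specs()
    res = RunResult(config=cfg, seed=sim.seed, state=sim.state,
                    pixel_um=cfg.geometry.pixel_um)
    res.samples.append(sim.sample())
    start = sim.state.mcs_counter
    for i in range(n_mcs):
        sim.step(injuries=injuries)
        mcs = sim.state.mcs_counter
        for kind, evs in sim.last_events.items():
            for ev in evs:
                res.events.append((mcs, kind, ev))
        if mcs % cfg.run.sample_every == 0 or i == n_mcs - 1:
            res.samples.append(sim.sample())
        if cfg.run.snapshot_every and mcs % cfg.run.snapshot_every == 0:
            res.snapshots.append((mcs, sim.state.owner_grid.copy(),
                                  sim.state.table.ctype[: sim.state.table.next_id].copy()))
        if check_invariants and mcs % 50 == 0:
            sim.state.check_invariants()
    res.injury_reports = list(sim.pending_reports)
    res.sim = sim
    return res


@dataclass
class ReplicateSummary:
    """Aggregate of n seeded replicates: per-MCS mean ± SD of counts and
    thickness, plus each replicate's stability time."""

    results: list
    counts_mean: "object" = None
    counts_sd: "object" = None
    stability_days: list = dc_field(default_factory=list)


def run_replicates(config: Optional[SimConfig] = None, n: Optional[int] = None,
                   seeds: Optional[list] = None) -> ReplicateSummary:
    from . import metrics as _metrics
    import pandas as pd

    cfg = (config or default_config()).validate()
    if seeds is None:
        n = n or cfg.run.replicates
        seeds = [cfg.run.seed + i for i in range(n)]
    results = [run(copy.deepcopy(cfg), seed=s) for s in seeds]
    frames = [_metrics.counts_frame(r) for r in results]
    stacked = pd.concat(frames, keys=range(len(frames)))
    mean = stacked.groupby(level=1).mean()
    sd = stacked.groupby(level=1).std(ddof=0)
    summary = ReplicateSummary(results=results, counts_mean=mean,
                               counts_sd=sd)
    for r in results:
        summary.stability_days.append(_metrics.stability_time(r))
    return summary
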