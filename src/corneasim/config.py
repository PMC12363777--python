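"""Simulation configuration: schema, defaults, YAML round-trip, validation.

Default values fall into two classes:

* printed model constants — lattice 200×90 voxels at 4 μm²/voxel, 6 min/MCS,
  limbal zone 40 px (80 μm), EGF D_global = 186 voxel²/MCS with kd = 0.5/MCS
  and the 20/20/0 type-specific coefficients, ω_contact,basal = 5 px,
  25/50 px division volumes, DaytoMCS = 240;
* calibrated constants (tagged "calibrated, not printed") — contact
  energies, temperature, constraint stiffnesses, Hill half-saturations,
  toxicant transport and kill threshold, initial stem packing and tear
  thickness.  These were fixed once against the emergent tissue outcomes
  (stable ~50 μm stratified epithelium, uniform surface, 7/14-day turnover,
  depth-classified chemical injuries) and are not scenario dials.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import asdict, dataclass, field, fields as dc_fields
from typing import Optional

import numpy as np
import yaml

from .types import (
    BASAL,
    DAMG,
    DAY_TO_MCS,
    LIMB,
    MEDIUM,
    MEMB,
    N_TYPES,
    STEM,
    STROMA,
    SUPER,
    TEAR,
    TYPE_CODES,
    WALL,
    WING,
)

SCHEMA_VERSION = "1"


class ConfigError(ValueError):
    """Raised for schema violations; message lists the offending keys."""


def _check_keys(d: dict, allowed, where: str) -> None:
    unknown = sorted(set(d) - set(allowed))
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {unknown}")


def _from_dict(cls, d: Optional[dict], where: str):
    d = dict(d or {})
    names = [f.name for f in dc_fields(cls)]
    _check_keys(d, names, where)
    return cls(**d)


# --------------------------------------------------------------------------


@dataclass
class GeometryConfig:
    width: int = 200                 # voxels (400 μm)
    height: int = 90                 # voxels (180 μm)
    pixel_um: float = 2.0            # μm per voxel edge
    limbal_width: int = 40           # voxels (80 μm limbal zone)
    peripheral_width: Optional[int] = None   # derived unless given
    stroma_rows: int = 40            # calibrated, not printed
    tear_thickness: int = 4          # voxels (8 μm, inside the 5-10 μm range)
    stem_block: int = 5              # initial stem cells are 5x5 px blocks
    stem_rows: int = 1               # stacked seed rows (crypt-like packing)

    def validate(self) -> None:
        if self.peripheral_width is None:
            self.peripheral_width = self.width - self.limbal_width
        if self.limbal_width + self.peripheral_width != self.width:
            raise ConfigError(
                "limbal_width + peripheral_width must equal lattice width "
                f"({self.limbal_width}+{self.peripheral_width} != {self.width})")
        if self.stroma_rows + self.tear_thickness + 10 >= self.height:
            raise ConfigError("geometry leaves no room for the epithelium")
        if self.tear_thickness < 1:
            raise ConfigError("tear film must be at least 1 voxel thick")


# calibrated, not printed: symmetric contact energies (lower = more adhesive).
# Tear-membrane contact is expensive so the epithelium wets exposed basement
# membrane (centripetal sheet spreading / wound coverage), while tear-damaged
# membrane is cheap and cell-damaged adhesion poor, so re-closure over a
# destroyed membrane is unstable (recurrent-erosion pathway).
DEFAULT_CONTACT_ENERGY: dict[str, float] = {
    "default": 16.0,
    "STEM-STEM": 4.0, "STEM-BASAL": 4.0, "STEM-WING": 6.0, "STEM-SUPER": 8.0,
    "BASAL-BASAL": 4.0, "BASAL-WING": 4.0, "BASAL-SUPER": 6.0,
    "WING-WING": 4.0, "WING-SUPER": 5.0, "SUPER-SUPER": 4.0,
    "STEM-TEAR": 24.0, "BASAL-TEAR": 24.0, "WING-TEAR": 22.0,
    "SUPER-TEAR": 6.0,
    "STEM-LIMB": 1.0, "BASAL-LIMB": 2.0, "WING-LIMB": 16.0, "SUPER-LIMB": 16.0,
    "STEM-MEMB": 4.0, "BASAL-MEMB": 1.0, "WING-MEMB": 16.0, "SUPER-MEMB": 16.0,
    "STEM-DAMG": 14.5, "BASAL-DAMG": 14.5, "WING-DAMG": 14.5,
    "SUPER-DAMG": 14.5,
    "TEAR-LIMB": 30.0, "TEAR-MEMB": 30.0, "TEAR-DAMG": 6.0,
    "TEAR-STROMA": 30.0,
    "TEAR-MEDIUM": 0.0, "TEAR-WALL": 10.0,
    "STEM-WALL": 8.0, "BASAL-WALL": 8.0, "WING-WALL": 8.0,
    "SUPER-WALL": 8.0,
}


@dataclass
class PottsConfig:
    temperature: float = 15.0                       # calibrated, not printed
    contact_energy: dict = field(
        default_factory=lambda: dict(DEFAULT_CONTACT_ENERGY))
    lambda_volume: dict = field(default_factory=lambda: {
        "STEM": 2.0, "BASAL": 2.0, "WING": 2.0, "SUPER": 2.0, "TEAR": 0.0})
    lambda_surface: dict = field(default_factory=lambda: {
        "STEM": 0.5, "BASAL": 0.0, "WING": 0.0, "SUPER": 0.0})
    chemotaxis_mu: dict = field(default_factory=lambda: {"BASAL": 100.0})
    link_stiffness: float = 0.0        # hemidesmosome springs off by default

    def validate(self) -> None:
        if self.temperature <= 0:
            raise ConfigError("temperature must be positive")
        for key in self.contact_energy:
            if key == "default":
                continue
            parts = key.split("-")
            if len(parts) != 2 or any(p not in TYPE_CODES for p in parts):
                raise ConfigError(f"bad contact_energy key {key!r}")
        for d, where in ((self.lambda_volume, "lambda_volume"),
                         (self.lambda_surface, "lambda_surface"),
                         (self.chemotaxis_mu, "chemotaxis_mu")):
            for name in d:
                if name not in TYPE_CODES:
                    raise ConfigError(f"unknown cell type {name!r} in {where}")

    def j_table(self) -> np.ndarray:
        J = np.full((N_TYPES, N_TYPES), float(self.contact_energy.get(
            "default", 16.0)))
        for key, v in self.contact_energy.items():
            if key == "default":
                continue
            a, b = (TYPE_CODES[p] for p in key.split("-"))
            J[a, b] = v
            J[b, a] = v
        return J

    def per_type(self, d: dict, default: float = 0.0) -> np.ndarray:
        arr = np.full(N_TYPES, default)
        for name, v in d.items():
            arr[TYPE_CODES[name]] = v
        return arr


@dataclass
class RulesConfig:
    km_egf_stem: float = 0.14        # calibrated, not printed (slow-cycling)
    km_egf_basal: float = 0.068       # calibrated, not printed
    km_density_stem: float = 8.0     # calibrated, not printed
    km_density_basal: float = 8.0    # calibrated, not printed
    hill_n: int = 4
    delta_max: float = 25.0 / 80.0   # px/MCS from the 8 h doubling floor
    init_volume: int = 25
    mitosis_volume: int = 50
    omega_contact_basal: int = 5
    day_to_mcs: int = DAY_TO_MCS

    def validate(self) -> None:
        if self.mitosis_volume != 2 * self.init_volume:
            raise ConfigError("mitosis_volume must equal 2*init_volume")
        if self.hill_n != 4:
            raise ConfigError("the Hill exponent is fixed at 4")


@dataclass
class FieldConfig:
    d_global: float = 186.0
    kd: float = 0.5
    d_super: float = 20.0
    d_memb: float = 20.0
    d_limb: float = 0.0
    clamp_value: float = 1.0
    n_substeps: int = 10

    def validate(self) -> None:
        if min(self.d_global, self.d_super, self.d_memb, self.d_limb) < 0:
            raise ConfigError("diffusion coefficients must be non-negative")
        if self.kd < 0:
            raise ConfigError("decay rate must be non-negative")

    def diffusion_by_type(self) -> dict:
        return {SUPER: self.d_super, MEMB: self.d_memb, LIMB: self.d_limb,
                DAMG: self.d_global, WALL: 0.0}


@dataclass
class ToxicantConfig:
    d_global: float = 80.0           # calibrated, not printed
    kd: float = 0.25                 # calibrated, not printed
    d_super: float = 20.0            # same barrier logic as EGF
    d_memb: float = 20.0
    d_limb: float = 0.0
    kill_threshold: float = 0.067    # calibrated, not printed
    n_substeps: int = 20

    def validate(self) -> None:
        if self.kill_threshold <= 0:
            raise ConfigError("kill_threshold must be positive")

    def diffusion_by_type(self) -> dict:
        return {SUPER: self.d_super, MEMB: self.d_memb, LIMB: self.d_limb,
                DAMG: self.d_global, WALL: 0.0}


@dataclass
class InjuryConfig:
    mode: str = "chemical_droplet"
    center: tuple = (100, 75)
    radius: float = 0.0
    amplitude: float = 750.0
    sigma: float = 0.0
    apply_at_day: float = 18.0

    def validate(self) -> None:
        if self.mode not in ("ablation", "chemical_droplet",
                             "chemical_uniform"):
            raise ConfigError(f"unknown injury mode {self.mode!r}")
        self.center = tuple(int(v) for v in self.center)


@dataclass
class RunConfig:
    run_mcs: int = 7200              # 30 simulated days
    sample_every: int = 10           # MCS between metric samples
    snapshot_every: int = 0          # 0 = no lattice dumps
    seed: int = 1
    replicates: int = 3

    def validate(self) -> None:
        if self.run_mcs < 0 or self.sample_every < 1:
            raise ConfigError("bad run length or sampling cadence")


@dataclass
class SimConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    potts: PottsConfig = field(default_factory=PottsConfig)
    rules: RulesConfig = field(default_factory=RulesConfig)
    egf: FieldConfig = field(default_factory=FieldConfig)
    toxicant: ToxicantConfig = field(default_factory=ToxicantConfig)
    injuries: list = field(default_factory=list)
    run: RunConfig = field(default_factory=RunConfig)

    def validate(self) -> "SimConfig":
        for sec in (self.geometry, self.potts, self.rules, self.egf,
                    self.toxicant, self.run):
            sec.validate()
        for inj in self.injuries:
            inj.validate()
        return self

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = copy.deepcopy(dict(d or {}))
        d.pop("schema_version", None)
        _check_keys(d, ["geometry", "potts", "rules", "egf", "toxicant",
                        "injuries", "run"], "config")
        injuries = [_from_dict(InjuryConfig, i, "injuries[]")
                    for i in d.pop("injuries", [])]
        cfg = cls(
            geometry=_from_dict(GeometryConfig, d.get("geometry"), "geometry"),
            potts=_from_dict(PottsConfig, d.get("potts"), "potts"),
            rules=_from_dict(RulesConfig, d.get("rules"), "rules"),
            egf=_from_dict(FieldConfig, d.get("egf"), "egf"),
            toxicant=_from_dict(ToxicantConfig, d.get("toxicant"), "toxicant"),
            injuries=injuries,
            run=_from_dict(RunConfig, d.get("run"), "run"),
        )
        return cfg.validate()

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_config() -> SimConfig:
    return SimConfig().validate()


def load_config(path) -> SimConfig:
    """Parse, schema-validate and default-fill a YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return SimConfig.from_dict(raw or {})


def dump_config(cfg: SimConfig, path=None) -> str:
    text = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
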