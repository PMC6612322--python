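"""Model configuration: defaults, units, provenance, validation.

Every parameter carries a provenance tag:

* ``paper``      — value printed in the source publication for this model.
* ``calibrated`` — not printed; fixed here by calibrating the single-cell
  scenario (see docs/methods.md) and then frozen.
* ``assumed``    — generic order-of-magnitude choice, documented in
  docs/methods.md.

Units: micrometres (µm) for length, minutes (min) for time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "Config",
    "MutationProfile",
    "load_config",
    "scaled_tumour_config",
    "PROVENANCE",
]


@dataclass
class DomainConfig:
    r_domain: float = 120.0        # µm — spherical computational domain radius
    shell_thickness: float = 2.0   # µm — outer layer where EGF is introduced


@dataclass
class FieldConfig:
    d_egf: float = 600.0           # µm²/min — EGF diffusion in the matrix
    introduction_rate: float = 22.0  # particles/min
    degradation_rate: float = 1.0 / 30.0  # 1/min — mean EGF lifetime 30 min
    r_egf: float = 0.05            # µm — EGF reaction radius
    rerelease_on_unbind: bool = False  # if True, ligand re-enters the field on receptor switch-off


@dataclass
class ReceptorConfig:
    r_rec: float = 1.0             # µm — inner (G-protein) sphere radius
    r_rec_outer: float = 0.4       # µm — outer (ligand-binding) sphere radius
    k_off: float = 1.0 / 8.0       # 1/min — receptor inactivation rate (mean residence 8 min)
    n_egfr: int = 6                # receptor clusters per cell (baseline genotype)


@dataclass
class IntracellularConfig:
    n_ras: int = 200
    n_raf: int = 60
    n_erk: int = 300
    n_tf: int = 50
    d_protein: float = 0.25         # µm²/min — cytoplasmic/nuclear protein diffusion
    r_bd: float = 0.2              # µm — protein reaction radius
    k_off_ras: float = 0.1         # 1/min — spontaneous inactivation rates
    k_off_raf: float = 0.1
    k_off_erk: float = 0.1
    k_off_tf: float = 1.0 / 15.0


@dataclass
class CellConfig:
    r_cell: float = 5.0            # µm — cell radius at birth
    r_nucleus: float = 2.5         # µm — incompressible nucleus radius


@dataclass
class MechanicsConfig:
    m: float = 1.0                 # arbitrary mass unit
    mu: float = 10.0               # 1/min — friction
    K: float = 50.0                # force scale of the repulsive potential
    overdamped: bool = False       # drop the inertial term if True


@dataclass
class CycleConfig:
    cycle_mean: float = 1440.0     # min — 24 h mean cell cycle
    cycle_jitter: float = 180.0    # min — uniform perturbation, ±3 h
    g1_duration: float = 660.0     # min — 11 h G1 phase
    n_tf_star: int = 40            # TF-count threshold at the G1 checkpoint
    replenish_daughters: bool = True  # top daughters back up to the standard complement


@dataclass
class RunConfig:
    dt: float = 0.005              # min — operator-split time step
    record_every: float = 1.0      # min — sampling interval for time series


@dataclass
class MutationProfile:
    """Genotype of a cell lineage.

    K-Ras / B-Raf mutations multiply the corresponding inactivation rate by
    ``multiplier`` (quasi-permanent activation for small values);
    ``n_egfr`` overrides the baseline receptor-cluster count when set.
    """

    kras: bool = False
    braf: bool = False
    multiplier: float = 0.01
    n_egfr: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.multiplier <= 1.0):
            raise ValueError(f"mutation multiplier must be in (0, 1], got {self.multiplier!r}")
        if self.n_egfr is not None and self.n_egfr < 1:
            raise ValueError(f"n_egfr must be >= 1, got {self.n_egfr!r}")

    @property
    def label(self) -> str:
        parts = []
        if self.kras:
            parts.append("kras")
        if self.braf:
            parts.append("braf")
        if self.n_egfr is not None:
            parts.append(f"egfr{self.n_egfr}")
        return "+".join(parts) if parts else "normal"


@dataclass
class Config:
    domain: DomainConfig = field(default_factory=DomainConfig)
    field_: FieldConfig = field(default_factory=FieldConfig)
    receptors: ReceptorConfig = field(default_factory=ReceptorConfig)
    intracellular: IntracellularConfig = field(default_factory=IntracellularConfig)
    cell: CellConfig = field(default_factory=CellConfig)
    mechanics: MechanicsConfig = field(default_factory=MechanicsConfig)
    cycle: CycleConfig = field(default_factory=CycleConfig)
    run: RunConfig = field(default_factory=RunConfig)

    def validate(self) -> "Config":
        d, f, r, ic, c, m, cy, rn = (
            self.domain, self.field_, self.receptors, self.intracellular,
            self.cell, self.mechanics, self.cycle, self.run,
        )
        def _require(cond: bool, msg: str) -> None:
            if not cond:
                raise ValueError(f"invalid configuration: {msg}")

        _require(d.r_domain > 0, "domain.r_domain must be positive")
        _require(0 < d.shell_thickness < d.r_domain, "domain.shell_thickness out of range")
        _require(f.d_egf >= 0, "field.d_egf must be non-negative")
        _require(f.introduction_rate >= 0, "field.introduction_rate must be non-negative")
        _require(f.degradation_rate > 0, "field.degradation_rate must be positive")
        _require(f.r_egf > 0, "field.r_egf must be positive")
        _require(r.r_rec > 0, "receptors.r_rec must be positive")
        _require(0 < r.r_rec_outer <= r.r_rec, "receptors.r_rec_outer must be in (0, r_rec]")
        _require(r.k_off > 0, "receptors.k_off must be positive")
        _require(r.n_egfr >= 1, "receptors.n_egfr must be >= 1")
        for name in ("n_ras", "n_raf", "n_erk", "n_tf"):
            _require(getattr(ic, name) > 0, f"intracellular.{name} must be positive")
        _require(ic.d_protein >= 0, "intracellular.d_protein must be non-negative")
        _require(ic.r_bd > 0, "intracellular.r_bd must be positive")
        for name in ("k_off_ras", "k_off_raf", "k_off_erk", "k_off_tf"):
            _require(getattr(ic, name) > 0, f"intracellular.{name} must be positive")
        _require(0 < c.r_nucleus < c.r_cell, "cell.r_nucleus must satisfy 0 < r_nucleus < r_cell")
        _require(c.r_cell < d.r_domain, "cell.r_cell must be smaller than the domain")
        _require(m.m > 0 and m.mu > 0 and m.K > 0, "mechanics m, mu, K must be positive")
        _require(cy.cycle_mean > 0, "cycle.cycle_mean must be positive")
        _require(0 <= cy.cycle_jitter < cy.cycle_mean, "cycle.cycle_jitter out of range")
        _require(
            0 < cy.g1_duration < cy.cycle_mean - cy.cycle_jitter,
            "cycle.g1_duration must fit inside the shortest cycle",
        )
        _require(rn.dt > 0, "run.dt must be positive")
        _require(rn.record_every > 0, "run.record_every must be positive")
        return self

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for fld in dataclasses.fields(self):
            sec = getattr(self, fld.name)
            out[fld.name.rstrip("_")] = dataclasses.asdict(sec)
        return out


_SECTION_KEYS = {
    "domain": DomainConfig,
    "field": FieldConfig,
    "receptors": ReceptorConfig,
    "intracellular": IntracellularConfig,
    "cell": CellConfig,
    "mechanics": MechanicsConfig,
    "cycle": CycleConfig,
    "run": RunConfig,
}
_ATTR_FOR_SECTION = {name: (name if name != "field" else "field_") for name in _SECTION_KEYS}


def load_config(path: str | None = None, overrides: dict | None = None) -> Config:
    """Load a YAML configuration; unknown sections or keys are an error.

    An empty or missing file yields the full default configuration.
    """
    data: dict[str, Any] = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"configuration root must be a mapping, got {type(loaded).__name__}")
        data = loaded
    if overrides:
        for sec, kv in overrides.items():
            data.setdefault(sec, {}).update(kv)

    cfg = Config()
    for sec_name, kv in data.items():
        if sec_name not in _SECTION_KEYS:
            raise ValueError(f"unknown configuration section {sec_name!r}")
        if kv is None:
            continue
        if not isinstance(kv, dict):
            raise ValueError(f"section {sec_name!r} must be a mapping")
        section = getattr(cfg, _ATTR_FOR_SECTION[sec_name])
        valid = {f.name for f in dataclasses.fields(section)}
        for key, value in kv.items():
            if key not in valid:
                raise ValueError(f"unknown configuration key {sec_name}.{key!r}")
            setattr(section, key, value)
    return cfg.validate()


def scaled_tumour_config() -> Config:
    """Desk-scale tumour-growth configuration (two simulated days).

    Space, ligand supply, and the cell cycle are compressed together so
    that the growth-rate phenomenology of large, long-horizon tumours is
    observable in a two-day run on one CPU:

    * the domain radius is halved (120 → 60 µm);
    * the EGF introduction rate is set to half of the concentration-matched
      value for the reduced volume, emulating the per-cell ligand scarcity
      that competition inside a large tumour produces — this is the regime
      in which receptor count limits signalling;
    * the cell cycle is shortened to 12 h (G1 5.5 h) so the horizon spans
      three to four generations instead of two.

    Per-cell model parameters (molecule counts, rates, radii, the fate
    threshold) are unchanged.
    """
    cfg = Config()
    cfg.domain.r_domain = 60.0
    cfg.field_.introduction_rate = 1.375
    cfg.cycle.cycle_mean = 720.0
    cfg.cycle.cycle_jitter = 90.0
    cfg.cycle.g1_duration = 330.0
    return cfg.validate()


#: provenance tag for every default, keyed "section.key"
PROVENANCE: dict[str, str] = {
    "domain.r_domain": "paper",
    "domain.shell_thickness": "assumed",
    "field.d_egf": "assumed",
    "field.introduction_rate": "calibrated",   # ratio to degradation fixed by the stationary count 660
    "field.degradation_rate": "calibrated",
    "field.r_egf": "assumed",
    "field.rerelease_on_unbind": "assumed",
    "receptors.r_rec": "calibrated",
    "receptors.r_rec_outer": "calibrated",
    "receptors.k_off": "paper",                # mean receptor residence time 8 min
    "receptors.n_egfr": "paper",
    "intracellular.n_ras": "paper",
    "intracellular.n_raf": "paper",
    "intracellular.n_erk": "paper",
    "intracellular.n_tf": "paper",
    "intracellular.d_protein": "calibrated",
    "intracellular.r_bd": "calibrated",
    "intracellular.k_off_ras": "calibrated",
    "intracellular.k_off_raf": "calibrated",
    "intracellular.k_off_erk": "calibrated",
    "intracellular.k_off_tf": "calibrated",
    "cell.r_cell": "assumed",
    "cell.r_nucleus": "assumed",
    "mechanics.m": "assumed",
    "mechanics.mu": "assumed",
    "mechanics.K": "assumed",
    "mechanics.overdamped": "assumed",
    "cycle.cycle_mean": "paper",
    "cycle.cycle_jitter": "paper",
    "cycle.g1_duration": "assumed",
    "cycle.n_tf_star": "calibrated",
    "cycle.replenish_daughters": "assumed",
    "run.dt": "paper",
    "run.record_every": "assumed",
}
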