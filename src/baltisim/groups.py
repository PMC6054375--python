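"""Biological functional-group parameterisation.

Three structural kinds are modelled:

* ``producer`` -- single biomass pool growing on nutrients and light
  (small phytoplankton PS, diatoms PL, macroalgae MA with space
  limitation on suitable benthic habitat);
* ``pool`` -- single biomass pool consumers (zooplankton, mysids,
  benthic invertebrates), one clearance/intake/assimilation rate each;
* ``vertebrate`` -- age-structured groups (5 or 10 cohorts) with
  per-cohort numbers, individual weights, clearance and maximum intake
  per cohort, a hard juvenile->adult maturation cohort, a spawning
  ogive, Beverton-Holt recruitment scaled by environmental ramps, and
  forced quarterly distribution maps.

Diet is expressed through an availability matrix ``a[(predator, stage),
prey]`` in [0, 1].  Detrital food is addressed by the pseudo-prey codes
``DL`` (water-column labile detritus), ``DLsed``/``DRsed`` (sediment
detritus pools).

The shipped default catalog is a desk-scale stand-in for the calibrated
Baltic parameter tables: rates are order-of-magnitude plausible per
group and were balanced so the exemplar ecosystem holds a multi-decade
quasi-equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .model_domain import ValidationError

DETRITAL_PREY = ("DL", "DLsed", "DRsed")

JUVENILE = "juvenile"
ADULT = "adult"
STAGES = (JUVENILE, ADULT)

#: grams wet weight per mg N (inverse of 2% N by wet mass).
G_WW_PER_MG_N = 0.05
MG_N_PER_G_WW = 20.0


@dataclass(frozen=True)
class EnvRamp:
    """Piecewise-linear 0->1 ramp between lo and hi (recruitment scalar)."""

    lo: float
    hi: float

    def __call__(self, x: float) -> float:
        if self.hi <= self.lo:
            return 1.0 if x >= self.hi else 0.0
        return float(np.clip((x - self.lo) / (self.hi - self.lo), 0.0, 1.0))


@dataclass(frozen=True)
class ProducerParams:
    mu_max: float  # day-1
    K_N: float  # mg N m-3 half-saturation
    K_I: float  # W m-2 light half-saturation
    nh4_preference: float = 1.0
    mortality_lin: float = 0.05  # day-1, losses to unresolved grazers/lysis -> DL
    space_capacity_per_m2: Optional[float] = None  # tons ww per m2 suitable habitat (benthic only)

    def validate(self, code: str) -> None:
        if min(self.mu_max, self.K_N, self.K_I) <= 0:
            raise ValidationError(f"{code}: producer rates must be positive")


@dataclass(frozen=True)
class InvertebrateParams:
    clearance: float  # m3 (ton pred)-1 day-1
    max_intake: float  # day-1 per unit predator biomass
    assimilation: float
    mort_lin: float  # day-1
    O2_min: float = 0.0  # mg O2 m-3
    hypoxia_mort: float = 0.0  # day-1 extra when O2 < O2_min

    def validate(self, code: str) -> None:
        if not 0 < self.assimilation <= 1:
            raise ValidationError(f"{code}: assimilation must be in (0, 1]")
        if min(self.clearance, self.max_intake, self.mort_lin, self.O2_min, self.hypoxia_mort) < 0:
            raise ValidationError(f"{code}: rates must be >= 0")


@dataclass(frozen=True)
class VertebrateParams:
    n_cohorts: int  # 5 or 10
    maturation_cohort: int  # first adult cohort index
    spawn_ogive: tuple[float, ...]  # fraction contributing to spawning, per cohort
    clearance: tuple[float, ...]  # m3 ton-1 day-1 per cohort
    max_intake: tuple[float, ...]  # day-1 per cohort
    assimilation: float
    mort_lin: tuple[float, ...]  # yr-1 natural mortality per cohort
    F_adult: float  # yr-1
    F_juvenile: float  # yr-1
    BH_alpha: float  # recruits yr-1 asymptote
    BH_beta: float  # tons SSB at half-saturation
    init_weight_g: tuple[float, ...]  # reference individual wet weight per cohort
    recruit_weight_g: float
    env_T: Optional[EnvRamp] = None
    env_S: Optional[EnvRamp] = None
    env_O2: Optional[EnvRamp] = None
    O2_refuge_threshold: float = 1000.0  # mg O2 m-3
    gape_min: float = 1e-6  # prey:predator weight ratio window
    gape_max: float = 0.5
    reserve_frac: float = 0.25  # reference reserve share of individual weight
    growth_split_reserve: float = 0.5
    spawn_day: int = 120
    spawn_quarter: int = 1  # 0-based quarter whose adult map weights spawning habitat

    def validate(self, code: str) -> None:
        if self.n_cohorts not in (5, 10):
            raise ValidationError(f"{code}: n_cohorts must be 5 or 10")
        if not 0 < self.maturation_cohort < self.n_cohorts:
            raise ValidationError(f"{code}: maturation_cohort out of range")
        for name in ("spawn_ogive", "clearance", "max_intake", "mort_lin", "init_weight_g"):
            if len(getattr(self, name)) != self.n_cohorts:
                raise ValidationError(f"{code}: {name} must have {self.n_cohorts} entries")
        og = self.spawn_ogive
        if any(not 0 <= x <= 1 for x in og) or any(b < a for a, b in zip(og, og[1:])):
            raise ValidationError(f"{code}: spawn_ogive must be in [0,1], non-decreasing")
        if self.F_adult < 0 or self.F_juvenile < 0:
            raise ValidationError(f"{code}: F must be >= 0")
        if self.BH_beta <= 0:
            raise ValidationError(f"{code}: BH_beta must be > 0")
        if not self.gape_min < self.gape_max:
            raise ValidationError(f"{code}: gape_min must be < gape_max")
        if not 0 < self.assimilation <= 1:
            raise ValidationError(f"{code}: assimilation must be in (0, 1]")


@dataclass(frozen=True)
class FunctionalGroup:
    """One biological functional group with its parameters and placement."""

    code: str
    name: str
    kind: str  # producer | pool | vertebrate
    habitat: str  # pelagic | demersal | benthic
    params: ProducerParams | InvertebrateParams | VertebrateParams
    init_biomass: float  # tons ww, domain total target
    habitat_affinity: Mapping[str, float] = field(default_factory=dict)  # benthic placement
    nominal_prey_weight_g: float = 1.0  # size seen by gape-limited predators
    refuge: Mapping[str, float] = field(default_factory=dict)  # habitat -> protected fraction
    coastal_bias: float = 1.0  # initial-placement weighting of coastal boxes

    def validate(self) -> None:
        if self.kind not in ("producer", "pool", "vertebrate"):
            raise ValidationError(f"{self.code}: unknown kind {self.kind!r}")
        if self.habitat not in ("pelagic", "demersal", "benthic"):
            raise ValidationError(f"{self.code}: unknown habitat {self.habitat!r}")
        if self.init_biomass < 0:
            raise ValidationError(f"{self.code}: init_biomass must be >= 0")
        self.params.validate(self.code)

    @property
    def is_vertebrate(self) -> bool:
        return self.kind == "vertebrate"

    def stages(self) -> tuple[str, ...]:
        return STAGES if self.is_vertebrate else (ADULT,)


AvailabilityMatrix = dict[tuple[str, str], dict[str, float]]


def validate_availability(avail: AvailabilityMatrix, groups: Mapping[str, FunctionalGroup]) -> None:
    for (pred, stage), prey_map in avail.items():
        if pred not in groups:
            raise ValidationError(f"availability references unknown predator {pred!r}")
        if stage not in STAGES:
            raise ValidationError(f"availability has unknown stage {stage!r} for {pred}")
        for prey, a in prey_map.items():
            if prey not in groups and prey not in DETRITAL_PREY:
                raise ValidationError(f"availability references unknown prey {prey!r}")
            if not 0 <= a <= 1:
                raise ValidationError(f"availability[{pred},{stage}][{prey}] = {a} outside [0,1]")


# ---------------------------------------------------------------------------
# default catalog
# ---------------------------------------------------------------------------


def _ramp10(first_one: int) -> tuple[float, ...]:
    """Spawning ogive ramping linearly to 1 at cohort ``first_one``."""
    return tuple(min(1.0, a / first_one) for a in range(10))


def default_groups() -> dict[str, FunctionalGroup]:
    """The shipped exemplar ecosystem: 13 groups spanning producers to seals."""
    g: dict[str, FunctionalGroup] = {}

    g["PS"] = FunctionalGroup(
        "PS", "small phytoplankton", "producer", "pelagic",
        ProducerParams(mu_max=0.9, K_N=8.0, K_I=35.0, mortality_lin=0.06),
        init_biomass=1.68e5, nominal_prey_weight_g=1e-9, coastal_bias=3.0,
    )
    g["PL"] = FunctionalGroup(
        "PL", "large phytoplankton (diatoms)", "producer", "pelagic",
        ProducerParams(mu_max=1.4, K_N=20.0, K_I=25.0, mortality_lin=0.05),
        init_biomass=1.48e6, nominal_prey_weight_g=1e-8, coastal_bias=0.3,
    )
    g["MA"] = FunctionalGroup(
        "MA", "macroalgae", "producer", "benthic",
        ProducerParams(mu_max=0.15, K_N=3.0, K_I=20.0, mortality_lin=0.002,
                       space_capacity_per_m2=3.0e-4),
        init_biomass=2.84e5, habitat_affinity={"bedrock": 1.0},
        nominal_prey_weight_g=100.0,
    )

    g["ZM"] = FunctionalGroup(
        "ZM", "mesozooplankton", "pool", "pelagic",
        InvertebrateParams(clearance=2.9e5, max_intake=0.5, assimilation=0.35,
                           mort_lin=0.02, O2_min=1500.0, hypoxia_mort=0.1),
        init_biomass=5.7e4, nominal_prey_weight_g=5e-4,
    )
    g["MS"] = FunctionalGroup(
        "MS", "mysids", "pool", "pelagic",
        InvertebrateParams(clearance=7.0e5, max_intake=0.12, assimilation=0.3,
                           mort_lin=0.016, O2_min=1800.0, hypoxia_mort=0.15),
        init_biomass=1.54e5, nominal_prey_weight_g=0.05,
    )
    g["BF"] = FunctionalGroup(
        "BF", "benthic deposit feeders", "pool", "benthic",
        InvertebrateParams(clearance=2.2e3, max_intake=0.05, assimilation=0.25,
                           mort_lin=0.005, O2_min=2000.0, hypoxia_mort=0.2),
        init_biomass=2.63e5, habitat_affinity={"mud": 0.7, "sand": 0.3},
        nominal_prey_weight_g=1.0, refuge={"bedrock": 0.8, "mud": 0.7, "sand": 0.7},
    )
    g["PO"] = FunctionalGroup(
        "PO", "polychaetes", "pool", "benthic",
        InvertebrateParams(clearance=1.2e3, max_intake=0.05, assimilation=0.25,
                           mort_lin=0.004, O2_min=1800.0, hypoxia_mort=0.25),
        init_biomass=1.53e6, habitat_affinity={"mud": 0.8, "sand": 0.2},
        nominal_prey_weight_g=0.5, refuge={"bedrock": 0.8, "mud": 0.7, "sand": 0.7},
    )
    g["HF"] = FunctionalGroup(
        "HF", "hard-substrate filter feeders", "pool", "benthic",
        InvertebrateParams(clearance=2.0e4, max_intake=0.04, assimilation=0.25,
                           mort_lin=0.006, O2_min=1500.0, hypoxia_mort=0.15),
        init_biomass=5.79e5, habitat_affinity={"bedrock": 1.0, "man-made": 1.0},
        nominal_prey_weight_g=5.0, refuge={"bedrock": 0.9, "man-made": 0.9, "sand": 0.6, "mud": 0.6},
    )
    # parameterised identically to the polychaete deposit feeders: at
    # desk scale the two share the soft-sediment detritivore niche and
    # differ only in placement and the size seen by predators
    g["NE"] = FunctionalGroup(
        "NE", "Nephrops and large benthic crustaceans", "pool", "benthic",
        InvertebrateParams(clearance=1.2e3, max_intake=0.05, assimilation=0.25,
                           mort_lin=0.004, O2_min=1800.0, hypoxia_mort=0.25),
        init_biomass=4.5e4, habitat_affinity={"mud": 0.8, "sand": 0.2},
        nominal_prey_weight_g=20.0, refuge={"bedrock": 0.8, "mud": 0.7, "sand": 0.7},
    )

    # --- fish ------------------------------------------------------------
    sprat_w = (2.0, 6.0, 9.0, 11.0, 12.5, 13.5, 14.5, 15.0, 15.5, 16.0)
    g["FSR"] = FunctionalGroup(
        "FSR", "sprat", "vertebrate", "pelagic",
        VertebrateParams(
            n_cohorts=10, maturation_cohort=2, spawn_ogive=_ramp10(3),
            clearance=tuple(1.2e5 * (0.85 ** a) for a in range(10)),
            max_intake=(0.08, 0.05, 0.035, 0.03, 0.025, 0.022, 0.02, 0.018, 0.017, 0.016),
            assimilation=0.3,
            mort_lin=(0.6, 0.45, 0.35, 0.3, 0.3, 0.3, 0.3, 0.3, 0.3, 0.3),
            F_adult=0.07, F_juvenile=0.035,
            BH_alpha=5.0e10, BH_beta=3.0e4,
            init_weight_g=sprat_w, recruit_weight_g=2.0,
            env_T=EnvRamp(2.0, 5.0), env_S=None, env_O2=EnvRamp(1500.0, 3000.0),
            O2_refuge_threshold=1500.0, gape_min=1e-8, gape_max=0.05,
            spawn_day=150, spawn_quarter=1,
        ),
        init_biomass=1.77e5, nominal_prey_weight_g=10.0,
    )
    herring_w = (6.0, 15.0, 25.0, 35.0, 45.0, 54.0, 62.0, 68.0, 74.0, 80.0)
    g["FHR"] = FunctionalGroup(
        "FHR", "herring", "vertebrate", "pelagic",
        VertebrateParams(
            n_cohorts=10, maturation_cohort=2, spawn_ogive=_ramp10(3),
            clearance=tuple(1.0e5 * (0.85 ** a) for a in range(10)),
            max_intake=(0.07, 0.045, 0.034, 0.028, 0.024, 0.021, 0.019, 0.017, 0.016, 0.015),
            assimilation=0.3,
            mort_lin=(0.5, 0.35, 0.25, 0.2, 0.2, 0.2, 0.2, 0.2, 0.2, 0.2),
            F_adult=0.16, F_juvenile=0.08,
            BH_alpha=1.2e10, BH_beta=4.0e4,
            init_weight_g=herring_w, recruit_weight_g=6.0,
            env_T=EnvRamp(2.0, 5.0), env_S=None, env_O2=EnvRamp(1500.0, 3000.0),
            O2_refuge_threshold=1500.0, gape_min=1e-8, gape_max=0.05,
            spawn_day=140, spawn_quarter=1,
        ),
        init_biomass=3.16e5, nominal_prey_weight_g=40.0,
    )
    cod_w = (80.0, 400.0, 1000.0, 1900.0, 2900.0, 4000.0, 5100.0, 6200.0, 7200.0, 8000.0)
    g["FCD"] = FunctionalGroup(
        "FCD", "cod", "vertebrate", "demersal",
        VertebrateParams(
            n_cohorts=10, maturation_cohort=3, spawn_ogive=_ramp10(4),
            clearance=tuple(6.0e4 * (0.9 ** a) for a in range(10)),
            max_intake=(0.05, 0.032, 0.022, 0.016, 0.013, 0.011, 0.010, 0.009, 0.008, 0.0075),
            assimilation=0.3,
            mort_lin=(0.5, 0.3, 0.25, 0.2, 0.2, 0.2, 0.2, 0.2, 0.2, 0.2),
            F_adult=0.32, F_juvenile=0.16,
            BH_alpha=8.0e7, BH_beta=1.5e4,
            init_weight_g=cod_w, recruit_weight_g=80.0,
            # reproductive-volume anchors: O2 > 2 mL/L (2858 mg m-3) and S > 11
            env_T=None, env_S=EnvRamp(8.0, 11.0), env_O2=EnvRamp(2858.0, 5716.0),
            O2_refuge_threshold=2000.0, gape_min=1e-5, gape_max=0.25,
            spawn_day=170, spawn_quarter=1,
        ),
        init_biomass=7.9e4, nominal_prey_weight_g=1500.0,
    )
    seal_w = (25000.0, 45000.0, 60000.0, 70000.0, 78000.0,
              84000.0, 88000.0, 92000.0, 95000.0, 98000.0)
    g["SEA"] = FunctionalGroup(
        "SEA", "seals", "vertebrate", "pelagic",
        VertebrateParams(
            n_cohorts=10, maturation_cohort=4, spawn_ogive=_ramp10(5),
            clearance=tuple(2.0e4 * (0.95 ** a) for a in range(10)),
            max_intake=(0.012, 0.009, 0.007, 0.006, 0.005, 0.0045, 0.004, 0.0038, 0.0036, 0.0034),
            assimilation=0.2,
            mort_lin=(0.25, 0.12, 0.09, 0.07, 0.07, 0.07, 0.07, 0.07, 0.07, 0.09),
            F_adult=0.0, F_juvenile=0.0,
            BH_alpha=9.0e3, BH_beta=1.2e3,
            init_weight_g=seal_w, recruit_weight_g=25000.0,
            # temperature and salinity effects are switched off for mammals
            env_T=None, env_S=None, env_O2=None,
            O2_refuge_threshold=0.0, gape_min=1e-5, gape_max=0.6,
            spawn_day=60, spawn_quarter=0,
        ),
        init_biomass=6.9e3, nominal_prey_weight_g=70000.0,
    )

    for grp in g.values():
        grp.validate()
    return g


def default_availability() -> AvailabilityMatrix:
    """Shipped availability (diet accessibility) matrix.

    Pools and producers have no stage structure; their entries are keyed
    with the 'adult' stage.
    """
    a: AvailabilityMatrix = {
        ("ZM", ADULT): {"PS": 1.0, "PL": 0.7},
        ("MS", ADULT): {"DL": 1.0},
        ("BF", ADULT): {"DRsed": 1.0},
        ("PO", ADULT): {"DLsed": 1.0},
        ("HF", ADULT): {"PS": 0.3, "PL": 0.3, "DL": 0.6},
        ("NE", ADULT): {"DLsed": 1.0},
        ("FSR", JUVENILE): {"ZM": 0.9, "MS": 0.3},
        ("FSR", ADULT): {"ZM": 0.6, "MS": 0.3},
        ("FHR", JUVENILE): {"ZM": 0.9, "MS": 0.3},
        ("FHR", ADULT): {"ZM": 0.6, "MS": 0.3},
        ("FCD", JUVENILE): {"PO": 0.4, "BF": 0.35, "HF": 0.1, "NE": 0.4},
        ("FCD", ADULT): {"FSR": 0.9, "FHR": 0.15, "FCD": 0.02},
        ("SEA", JUVENILE): {"FHR": 0.5, "FSR": 0.5, "FCD": 0.1},
        ("SEA", ADULT): {"FHR": 0.5, "FSR": 0.4, "FCD": 0.2},
    }
    return a


# ---------------------------------------------------------------------------
# YAML round trip (group catalog + availability as one document)
# ---------------------------------------------------------------------------

_PARAM_CLASSES = {"producer": ProducerParams, "pool": InvertebrateParams,
                  "vertebrate": VertebrateParams}


def _params_to_dict(p) -> dict:
    out = {}
    for k, v in p.__dict__.items():
        if isinstance(v, EnvRamp):
            out[k] = {"lo": v.lo, "hi": v.hi}
        elif isinstance(v, tuple):
            out[k] = list(v)
        else:
            out[k] = v
    return out


def _params_from_dict(kind: str, d: dict):
    cls = _PARAM_CLASSES[kind]
    kwargs = {}
    for k, v in d.items():
        if k.startswith("env_") and isinstance(v, dict):
            kwargs[k] = EnvRamp(**v)
        elif isinstance(v, list):
            kwargs[k] = tuple(v)
        else:
            kwargs[k] = v
    return cls(**kwargs)


def save_catalog(groups: Mapping[str, FunctionalGroup], avail: AvailabilityMatrix,
                 path) -> None:
    doc = {
        "groups": {
            code: {
                "name": grp.name,
                "kind": grp.kind,
                "habitat": grp.habitat,
                "init_biomass": grp.init_biomass,
                "habitat_affinity": dict(grp.habitat_affinity),
                "nominal_prey_weight_g": grp.nominal_prey_weight_g,
                "refuge": dict(grp.refuge),
                "params": _params_to_dict(grp.params),
            }
            for code, grp in groups.items()
        },
        "availability": {
            f"{pred}:{stage}": dict(prey) for (pred, stage), prey in avail.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_catalog(path) -> tuple[dict[str, FunctionalGroup], AvailabilityMatrix]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    groups = {}
    for code, d in doc["groups"].items():
        grp = FunctionalGroup(
            code=code, name=d["name"], kind=d["kind"], habitat=d["habitat"],
            params=_params_from_dict(d["kind"], d["params"]),
            init_biomass=float(d["init_biomass"]),
            habitat_affinity=d.get("habitat_affinity", {}),
            nominal_prey_weight_g=float(d.get("nominal_prey_weight_g", 1.0)),
            refuge=d.get("refuge", {}),
        )
        grp.validate()
        groups[code] = grp
    avail: AvailabilityMatrix = {}
    for key, prey in doc.get("availability", {}).items():
        pred, stage = key.split(":")
        avail[(pred, stage)] = {k: float(v) for k, v in prey.items()}
    validate_availability(avail, groups)
    return groups, avail
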