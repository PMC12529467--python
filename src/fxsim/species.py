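"""Species parameterization: fire strategies, dispersal, and establishment envelopes.

Four wind-dispersed conifers of the Greater Yellowstone subalpine zone are
represented, with serotinous and non-serotinous lodgepole pine as separate
variants:

* subalpine fir   — fire avoider: no fire adaptations, short-distance disperser
* Engelmann spruce — fire avoider: temperature-sensitive establishment
* Douglas-fir     — fire resister: thick bark lets mature trees survive fire
* lodgepole pine  — serotinous variant is a fire embracer (canopy seed bank
  released by fire heat); the non-serotinous variant is killed by fire and
  relies on wind dispersal like the avoiders.

Numeric defaults (dispersal scales, thermal optima, fecundities) are
implementation choices exposed through :func:`default_species` and YAML
config; they encode the field-known orderings (fir disperses over the
shortest distances; spruce establishment is the most temperature- and
drought-sensitive; Douglas-fir prefers the warmest sites).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

AVOIDER = "avoider"
RESISTER = "resister"
EMBRACER = "embracer"

#: Species whose future seed sources are considered vulnerable (used for
#: operational Fx-zone delineation): the two avoiders plus Douglas-fir.
VULNERABLE_SPECIES = ("subalpine_fir", "engelmann_spruce", "douglas_fir")

#: The fir + spruce grouping used when summarizing avoider regeneration.
AVOIDER_SPECIES = ("subalpine_fir", "engelmann_spruce")


@dataclass(frozen=True)
class SpeciesParams:
    """Parameters governing one species' fire response, dispersal and regeneration.

    Attributes
    ----------
    strategy
        One of ``avoider`` / ``resister`` / ``embracer``.
    serotinous
        True only for the serotinous lodgepole variant; seed supply is an
        aerial canopy bank released in situ by fire rather than annual rain.
    maturity_age
        Stand age (yr) at which trees produce seed (and at which a serotinous
        canopy bank survives fire — younger stands lose it: immaturity risk).
    fecundity
        Seeds per mature tree per year.
    kernel_scale
        Mean dispersal distance (m) of the 2Dt kernel.
    masting_period
        Deterministic mast cycle length (yr); mast years multiply fecundity.
    establishment_T_opt, establishment_T_width
        Gaussian thermal envelope for establishment (°C, local summer temp).
    drought_sensitivity
        Exponential decay rate of establishment per unit positive
        moisture-deficit (aridity) index; unitless, >= 0.
    height_growth
        Cohort height increment (m/yr); cohorts graduate at 4 m.
    fire_survival_base, fire_survival_max
        Resister survival probability at stand age 0 and its asymptote in old
        stands (saturating bark-thickness proxy); zero for non-resisters.
    shade_establishment_factor
        Multiplier on establishment under intact canopy (1 in recent burns).
    """

    name: str
    strategy: str
    serotinous: bool
    maturity_age: float
    fecundity: float
    kernel_scale: float
    masting_period: int
    establishment_T_opt: float
    establishment_T_width: float
    drought_sensitivity: float
    height_growth: float
    fire_survival_base: float = 0.0
    fire_survival_max: float = 0.0
    shade_establishment_factor: float = 0.2
    mast_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if self.strategy not in (AVOIDER, RESISTER, EMBRACER):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.strategy != RESISTER and self.fire_survival_base != 0.0:
            raise ValueError("only resisters survive fire (fire_survival_base must be 0)")
        if self.serotinous and self.strategy != EMBRACER:
            raise ValueError("serotiny is an embracer trait")
        if self.kernel_scale <= 0 and not self.serotinous:
            raise ValueError("kernel_scale must be positive")
        if self.drought_sensitivity < 0:
            raise ValueError("drought_sensitivity must be >= 0")

    def mast_factor(self, year: int) -> float:
        """Deterministic masting multiplier for a calendar year."""
        if self.masting_period <= 1:
            return 1.0
        return self.mast_multiplier if year % self.masting_period == 0 else 1.0

    def fire_survival(self, stand_age: float) -> float:
        """Probability a mature tree survives fire, saturating with stand age.

        Older stands have thicker bark; non-resisters always return 0.
        """
        if self.strategy != RESISTER:
            return 0.0
        sat = 1.0 - float(2.0 ** (-stand_age / 80.0))  # half-saturation at 80 yr
        return self.fire_survival_base + (self.fire_survival_max - self.fire_survival_base) * sat


def default_species() -> dict[str, SpeciesParams]:
    """The default five-taxon parameter set, keyed by species name.

    Local summer temperature is the scenario series value lapsed to cell
    elevation (reference elevation 2300 m); thermal optima are on that scale.
    """
    return {
        sp.name: sp
        for sp in (
            SpeciesParams(
                name="subalpine_fir",
                strategy=AVOIDER,
                serotinous=False,
                maturity_age=35,
                fecundity=600,
                kernel_scale=30.0,
                masting_period=3,
                establishment_T_opt=11.0,
                establishment_T_width=3.5,
                drought_sensitivity=0.8,
                height_growth=0.22,
                shade_establishment_factor=0.45,
            ),
            SpeciesParams(
                name="engelmann_spruce",
                strategy=AVOIDER,
                serotinous=False,
                maturity_age=40,
                fecundity=800,
                kernel_scale=80.0,
                masting_period=4,
                establishment_T_opt=10.0,
                establishment_T_width=2.5,
                drought_sensitivity=1.3,
                height_growth=0.24,
                shade_establishment_factor=0.4,
            ),
            SpeciesParams(
                name="douglas_fir",
                strategy=RESISTER,
                serotinous=False,
                maturity_age=25,
                fecundity=900,
                kernel_scale=100.0,
                masting_period=5,
                establishment_T_opt=16.0,
                establishment_T_width=3.5,
                drought_sensitivity=0.5,
                height_growth=0.30,
                fire_survival_base=0.15,
                fire_survival_max=0.85,
                shade_establishment_factor=0.25,
            ),
            SpeciesParams(
                name="lodgepole_serotinous",
                strategy=EMBRACER,
                serotinous=True,
                maturity_age=20,
                fecundity=1200,
                kernel_scale=60.0,
                masting_period=1,
                establishment_T_opt=13.0,
                establishment_T_width=4.0,
                drought_sensitivity=0.45,
                height_growth=0.35,
                shade_establishment_factor=0.1,
            ),
            SpeciesParams(
                name="lodgepole_nonserotinous",
                strategy=AVOIDER,
                serotinous=False,
                maturity_age=15,
                fecundity=1000,
                kernel_scale=60.0,
                masting_period=2,
                establishment_T_opt=13.0,
                establishment_T_width=4.0,
                drought_sensitivity=0.45,
                height_growth=0.35,
                shade_establishment_factor=0.1,
            ),
        )
    }


def save_species_yaml(species: dict[str, SpeciesParams], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({name: asdict(sp) for name, sp in species.items()}, fh, sort_keys=False)


def load_species_yaml(path: str | Path) -> dict[str, SpeciesParams]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {name: SpeciesParams(**params) for name, params in raw.items()}
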