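"""Synthetic landscape, climate-scenario, and operational-input generators.

The simulator needs a subalpine forest landscape with the structure its
analyses assume: an elevation gradient with species zonation (Douglas-fir
low, lodgepole pine mid, spruce–fir high), a stockable (potentially
forested) mask, a stand-age mosaic that includes recent burns, and four
annual climate series (warm/hot x wet/dry) with prescribed end-of-century
warming and summer-precipitation deltas. Everything here is generated from
a seed; no external data are read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from fxsim.grid import GridSpec
from fxsim.species import EMBRACER, VULNERABLE_SPECIES, SpeciesParams

# Reference climatology shared by every scenario. Summer temperature is
# defined at the reference elevation and lapsed to cell elevation by the
# simulator; the aridity index standardizes against these fixed constants so
# that it is comparable ACROSS scenarios (a within-series z-score would
# erase the warming contrast the fire regime responds to).
BASE_SUMMER_TEMP = 13.0  # deg C at REF_ELEVATION
BASE_SUMMER_PRECIP = 12.0  # cm
REF_T_SD = 1.5  # deg C, interannual scale for standardization
REF_P_SD = 2.5  # cm
REF_ELEVATION = 2300.0  # m asl
LAPSE_RATE = 0.0065  # deg C per m elevation

CLIMATE_SCENARIOS = ("warm-wet", "hot-wet", "warm-dry", "hot-dry")

# End-of-century deltas (last-decade mean minus first-decade mean) targeted
# by each scenario: midpoints of the projected ranges (+4.1..4.2 and
# +6.6..6.8 deg C warming; +1.5..+3.3 cm wet / -2.4..-1.8 cm dry summers).
SCENARIO_DELTAS: dict[str, tuple[float, float]] = {
    "warm-wet": (4.15, 2.4),
    "hot-wet": (6.7, 2.4),
    "warm-dry": (4.15, -2.1),
    "hot-dry": (6.7, -2.1),
}


@dataclass
class CohortLayer:
    """Per-species regeneration cohorts as dense rasters.

    A cell's cohort is summarized by its seedling density (per ha), the age
    of the cohort (years since initiation), and its height (m). Cohorts are
    removed at 4 m height when they graduate to the mature tree layer.
    """

    density: np.ndarray
    age: np.ndarray
    height: np.ndarray

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "CohortLayer":
        return cls(
            density=np.zeros(shape, dtype=np.float32),
            age=np.zeros(shape, dtype=np.float32),
            height=np.zeros(shape, dtype=np.float32),
        )

    def copy(self) -> "CohortLayer":
        return CohortLayer(self.density.copy(), self.age.copy(), self.height.copy())


@dataclass
class LandscapeState:
    """Gridded forest state evolved by the simulator."""

    grid: GridSpec
    species: dict[str, SpeciesParams]
    stockable: np.ndarray  # uint8, 1 = potentially forested
    elevation: np.ndarray  # m asl
    mature_density: dict[str, np.ndarray]  # trees/ha per species
    canopy_seed_bank: dict[str, np.ndarray]  # seeds/ha, serotinous species only
    cohorts: dict[str, CohortLayer]
    stand_age: np.ndarray  # yr
    time_since_fire: np.ndarray  # yr
    year: int

    def copy(self) -> "LandscapeState":
        return LandscapeState(
            grid=self.grid,
            species=self.species,
            stockable=self.stockable.copy(),
            elevation=self.elevation.copy(),
            mature_density={k: v.copy() for k, v in self.mature_density.items()},
            canopy_seed_bank={k: v.copy() for k, v in self.canopy_seed_bank.items()},
            cohorts={k: v.copy() for k, v in self.cohorts.items()},
            stand_age=self.stand_age.copy(),
            time_since_fire=self.time_since_fire.copy(),
            year=self.year,
        )

    def total_mature_density(self) -> np.ndarray:
        out = np.zeros(self.grid.shape, dtype=np.float32)
        for arr in self.mature_density.values():
            out += arr
        return out

    def local_summer_temp(self, summer_temp: float) -> np.ndarray:
        """Scenario summer temperature lapsed to cell elevation."""
        return summer_temp - LAPSE_RATE * (self.elevation - REF_ELEVATION)

    def validate(self) -> None:
        ns = self.stockable == 0
        for name, dens in self.mature_density.items():
            if not np.all(np.isfinite(dens)) or np.any(dens < 0):
                raise ValueError(f"non-finite or negative mature density for {name}")
            if np.any(dens[ns] > 0):
                raise ValueError(f"mature {name} present on non-stockable cells")
        for name, layer in self.cohorts.items():
            if np.any(layer.height >= 4.0):
                raise ValueError(f"un-graduated cohort at >= 4 m for {name}")


@dataclass
class ClimateSeries:
    """Annual summer climate for one scenario.

    ``aridity_index`` is standardized temperature minus standardized
    precipitation, both against the fixed reference climatology, so positive
    values mean hotter/drier than the reference period and values are
    comparable across scenarios.
    """

    scenario: str
    years: np.ndarray
    summer_temp: np.ndarray
    summer_precip: np.ndarray
    aridity_index: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.years)
        if len(self.summer_temp) != n or len(self.summer_precip) != n:
            raise ValueError("climate series lengths do not match years")
        self.aridity_index = (self.summer_temp - BASE_SUMMER_TEMP) / REF_T_SD - (
            self.summer_precip - BASE_SUMMER_PRECIP
        ) / REF_P_SD

    def __len__(self) -> int:
        return len(self.years)

    def decadal_delta(self, variable: str = "summer_temp", decade: int = 10) -> float:
        """Mean of the last ``decade`` years minus mean of the first."""
        x = getattr(self, variable)
        return float(np.mean(x[-decade:]) - np.mean(x[:decade]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "scenario": self.scenario,
                "summer_temp": self.summer_temp,
                "summer_precip": self.summer_precip,
                "aridity_index": self.aridity_index,
            }
        )


@dataclass
class OperationalInputs:
    """Ancillary rasters for operational Fx-zone delineation."""

    vulnerable_density: np.ndarray  # trees/ha of avoider + resister species
    containment_likelihood: np.ndarray  # [0, 1]
    developed: np.ndarray  # uint8, 3 compact patches


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Zero-mean, unit-variance spatially correlated Gaussian field."""
    noise = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def generate_landscape(
    grid: GridSpec,
    species_set: dict[str, SpeciesParams],
    seed: int,
    *,
    stockable_target: float = 0.9,
    young_fraction: float = 0.10,
    recent_burn_horizon: int = 40,
    elev_range: tuple[float, float] = (1600.0, 2900.0),
    douglas_fir_max_elev: float = 2150.0,
    lodgepole_band: tuple[float, float] = (1700.0, 2650.0),
    spruce_fir_min_elev: float = 2350.0,
    base_density: float = 250.0,
    start_year: int = 2021,
) -> LandscapeState:
    """Generate the initial forest landscape.

    Elevation is a smooth north–south gradient plus correlated noise; species
    are zoned by hard elevation bands with overlapping ecotones (Douglas-fir
    below ``douglas_fir_max_elev``, lodgepole within ``lodgepole_band``,
    spruce–fir above ``spruce_fir_min_elev``). A ``young_fraction`` of
    stockable cells is flagged as burned within the last
    ``recent_burn_horizon`` years (these carry regenerating cohorts instead
    of mature trees and are excluded from Fx placement downstream).
    Deterministic given ``seed``.
    """
    if not species_set:
        raise ValueError("species_set must not be empty")
    required = {"subalpine_fir", "engelmann_spruce", "douglas_fir", "lodgepole_serotinous", "lodgepole_nonserotinous"}
    missing = required - set(species_set)
    if missing:
        raise ValueError(f"species_set missing required species: {sorted(missing)}")
    if not 0 <= young_fraction < 1:
        raise ValueError("young_fraction must be in [0, 1)")

    rng = np.random.default_rng(seed)
    shape = grid.shape
    nrows, ncols = shape

    # Elevation: linear gradient along rows (row 0 = high country) + noise.
    lo, hi = elev_range
    gradient = np.linspace(hi, lo, nrows)[:, None] * np.ones((1, ncols))
    elevation = gradient + 120.0 * _smooth_field(rng, shape, sigma=max(3.0, nrows / 30))
    elevation = np.clip(elevation, lo - 150.0, hi + 150.0)

    # Stockable mask: threshold a correlated field at the quantile giving the
    # target stockable fraction (unstockable = rock, water, alpine).
    stock_field = _smooth_field(rng, shape, sigma=max(3.0, nrows / 25))
    cutoff = np.quantile(stock_field, 1.0 - stockable_target)
    stockable = (stock_field >= cutoff).astype(np.uint8)

    # Stand ages: mature mosaic with a young recently-burned component.
    stand_age = rng.uniform(60, 300, size=shape).astype(np.float32)
    young = (rng.random(shape) < young_fraction) & (stockable == 1)
    young_age = rng.integers(0, recent_burn_horizon, size=shape).astype(np.float32)
    stand_age[young] = young_age[young]
    time_since_fire = stand_age.copy()

    # Species zonation weights: hard band limits, soft overlap inside.
    def _band_weight(lo_e: float | None, hi_e: float | None, soft: float = 150.0) -> np.ndarray:
        w = np.ones(shape)
        if lo_e is not None:
            w *= 1.0 / (1.0 + np.exp(-(elevation - lo_e) / soft))
            w[elevation < lo_e] = 0.0
        if hi_e is not None:
            w *= 1.0 / (1.0 + np.exp((elevation - hi_e + 2 * soft) / soft))
            w[elevation >= hi_e] = 0.0
        return w

    weights = {
        "douglas_fir": _band_weight(None, douglas_fir_max_elev),
        "lodgepole": _band_weight(*lodgepole_band),
        "spruce_fir": _band_weight(spruce_fir_min_elev, None),
    }
    serotiny_frac = 0.5 + 0.35 * np.tanh(_smooth_field(rng, shape, sigma=max(3.0, nrows / 20)))

    mature_mask = (stockable == 1) & ~young
    mature_density: dict[str, np.ndarray] = {}
    for name in species_set:
        if name == "douglas_fir":
            w = weights["douglas_fir"]
        elif name == "lodgepole_serotinous":
            w = weights["lodgepole"] * serotiny_frac
        elif name == "lodgepole_nonserotinous":
            w = weights["lodgepole"] * (1.0 - serotiny_frac)
        else:  # subalpine fir, Engelmann spruce share the high band
            w = weights["spruce_fir"] * (0.55 if name == "subalpine_fir" else 0.45)
        noise = np.exp(rng.normal(0.0, 0.3, size=shape))
        dens = (base_density * w * noise).astype(np.float32)
        dens[~mature_mask] = 0.0
        mature_density[name] = dens

    # Canopy seed bank for serotinous species: accumulates with stand age
    # past maturity, capped at 30 years of production.
    canopy_seed_bank: dict[str, np.ndarray] = {}
    for name, sp in species_set.items():
        if sp.serotinous:
            prod_years = np.clip(stand_age - sp.maturity_age, 0, 30)
            canopy_seed_bank[name] = (sp.fecundity * mature_density[name] * prod_years).astype(np.float32)

    # Young stands carry a regenerating cohort of the locally dominant species.
    cohorts = {name: CohortLayer.empty(shape) for name in species_set}
    if np.any(young):
        dom_weights = np.stack(
            [
                weights["douglas_fir"],
                weights["lodgepole"] * serotiny_frac,
                weights["lodgepole"] * (1 - serotiny_frac),
                weights["spruce_fir"] * 0.55,
                weights["spruce_fir"] * 0.45,
            ]
        )
        dom_names = [
            "douglas_fir",
            "lodgepole_serotinous",
            "lodgepole_nonserotinous",
            "subalpine_fir",
            "engelmann_spruce",
        ]
        dominant = np.argmax(dom_weights, axis=0)
        for i, name in enumerate(dom_names):
            sp = species_set[name]
            sel = young & (dominant == i) & (dom_weights[i] > 0)
            if not np.any(sel):
                continue
            layer = cohorts[name]
            max_age = max(int(3.9 / sp.height_growth) - 1, 1)
            age = np.minimum(stand_age, max_age)
            layer.density[sel] = 1200.0
            layer.age[sel] = age[sel]
            layer.height[sel] = np.minimum(age[sel] * sp.height_growth, 3.9)

    state = LandscapeState(
        grid=grid,
        species=dict(species_set),
        stockable=stockable,
        elevation=elevation.astype(np.float32),
        mature_density=mature_density,
        canopy_seed_bank=canopy_seed_bank,
        cohorts=cohorts,
        stand_age=stand_age,
        time_since_fire=time_since_fire,
        year=start_year,
    )
    state.validate()
    return state


def generate_climate(
    scenario: str,
    years: range = range(2021, 2101),
    seed: int = 0,
    *,
    ar1: float = 0.3,
    temp_sd: float = 0.7,
    precip_sd: float = 2.0,
    decade: int = 10,
) -> ClimateSeries:
    """Generate one scenario's annual summer climate series.

    Linear trend plus AR(1) interannual noise. The noise is adjusted so its
    first-decade and last-decade means are exactly zero, which pins the
    realized decadal delta (last-decade mean minus first-decade mean) to the
    scenario target regardless of seed. With ``temp_sd = precip_sd = 0`` the
    series is exactly linear in year.
    """
    if scenario not in SCENARIO_DELTAS:
        raise ValueError(f"unknown climate scenario {scenario!r}; expected one of {CLIMATE_SCENARIOS}")
    dT, dP = SCENARIO_DELTAS[scenario]
    yrs = np.asarray(list(years), dtype=float)
    n = len(yrs)
    if n < 2 * decade:
        raise ValueError(f"need at least {2 * decade} years, got {n}")
    rng = np.random.default_rng(seed)

    t0 = yrs[:decade].mean()
    t1 = yrs[-decade:].mean()
    span = t1 - t0

    def _series(base: float, delta: float, sd: float) -> np.ndarray:
        trend = base + delta * (yrs - t0) / span
        eps = np.zeros(n)
        if sd > 0:
            innov = rng.normal(0.0, sd * np.sqrt(1 - ar1**2), size=n)
            innov[0] = rng.normal(0.0, sd)
            for i in range(1, n):
                innov[i] += ar1 * innov[i - 1]
            eps = innov
        # Pin first- and last-decade noise means to zero (linear detrend
        # through the two decade means) so the decadal delta is exact.
        a = eps[:decade].mean()
        b = eps[-decade:].mean()
        eps = eps - (a + (b - a) * (yrs - t0) / span)
        return trend + eps

    temp = _series(BASE_SUMMER_TEMP, dT, temp_sd)
    precip = _series(BASE_SUMMER_PRECIP, dP, precip_sd)
    return ClimateSeries(scenario=scenario, years=yrs.astype(int), summer_temp=temp, summer_precip=precip)


def generate_operational_inputs(state: LandscapeState, seed: int) -> OperationalInputs:
    """Generate the ancillary rasters used to delineate operational Fx zones.

    ``vulnerable_density`` sums mature densities of subalpine fir, Engelmann
    spruce and Douglas-fir. ``containment_likelihood`` is a spatially
    autocorrelated [0, 1] field elevated along a synthetic road/river
    corridor (a stand-in for potential-control-location products).
    ``developed`` marks three compact disjoint patches designated for
    protection.
    """
    rng = np.random.default_rng(seed)
    shape = state.grid.shape
    nrows, ncols = shape

    vulnerable = np.zeros(shape, dtype=np.float32)
    for name in VULNERABLE_SPECIES:
        if name in state.mature_density:
            vulnerable += state.mature_density[name]

    # Base autocorrelated field mapped to [0, 1].
    base = _smooth_field(rng, shape, sigma=max(3.0, nrows / 20))
    base = (base - base.min()) / (base.max() - base.min() + 1e-12)
    # Synthetic corridor: sinusoidal polyline across the grid, boosting
    # containment within a smoothed buffer.
    rows = np.arange(nrows)
    center = ncols / 2 + (ncols / 4) * np.sin(2 * np.pi * rows / nrows + rng.uniform(0, 2 * np.pi))
    corridor = np.zeros(shape)
    cols = np.arange(ncols)[None, :]
    corridor[np.abs(cols - center[:, None]) < max(2, ncols // 50)] = 1.0
    corridor = ndimage.gaussian_filter(corridor, sigma=max(2.0, nrows / 40))
    if corridor.max() > 0:
        corridor = corridor / corridor.max()
    # Cubing the base field makes high containment scarce away from the
    # corridor, mirroring products where defensible locations are rare.
    containment = np.clip(0.35 * base**3 + 0.75 * corridor, 0.0, 1.0).astype(np.float32)

    # Three compact disjoint developed patches, one per horizontal third.
    developed = np.zeros(shape, dtype=np.uint8)
    radius = max(2, min(nrows, ncols) // 30)
    for k in range(3):
        r0 = int(rng.uniform(0.2, 0.8) * nrows)
        c0 = int((k + rng.uniform(0.3, 0.7)) * ncols / 3)
        rr, cc = np.ogrid[:nrows, :ncols]
        developed[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2] = 1

    return OperationalInputs(
        vulnerable_density=vulnerable,
        containment_likelihood=containment,
        developed=developed,
    )
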