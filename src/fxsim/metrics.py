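"""Response variables of the scenario comparison.

Computes mean annual area burned by period, postfire regeneration within
fire patches at a fixed lag, end-of-century landscape regeneration outside
Fx zones, operational-vs-reference difference maps with an ecological
threshold and signed-log transform, and Euclidean distance from difference
classes to the nearest Fx zone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from fxsim.grid import GridSpec
from fxsim.scenarios import FxScenario
from fxsim.simulator import SimOutput

EARLY_FIRE_YEARS = (2021, 2045)
LATE_FIRE_YEARS = (2071, 2095)
EARLY_REGEN_WINDOW = (2026, 2050)
LATE_REGEN_WINDOW = (2076, 2100)

CLASS_MORE = "more"
CLASS_LESS = "less"
CLASS_NONE = "none"
CLASS_ABSENT = "absent"
#: Integer legend for persisted class rasters.
CLASS_CODES = {CLASS_LESS: -1, CLASS_NONE: 0, CLASS_MORE: 1, CLASS_ABSENT: 9}


def area_burned_by_period(
    outputs: list[SimOutput],
    early: tuple[int, int] = EARLY_FIRE_YEARS,
    late: tuple[int, int] = LATE_FIRE_YEARS,
) -> pd.DataFrame:
    """Mean annual area burned per period, per replicate and per group.

    Returns one row per (scenario, climate, period) with the replicate mean,
    SD, SE (SD / sqrt(n)) and n. With a single replicate the SE is reported
    as 0 with ``se_degenerate = True``.
    """
    if not outputs:
        raise ValueError("empty output list")
    rows = []
    for out in outputs:
        years = out.years
        for period, (y0, y1) in (("early", early), ("late", late)):
            sel = (years >= y0) & (years <= y1)
            rows.append(
                {
                    "scenario": out.scenario,
                    "climate": out.climate,
                    "replicate": out.replicate,
                    "period": period,
                    "mean_ha_per_yr": float(out.area_burned[sel].mean()),
                }
            )
    per_rep = pd.DataFrame(rows)
    grouped = (
        per_rep.groupby(["scenario", "climate", "period"])["mean_ha_per_yr"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    grouped["se_degenerate"] = grouped["n"] < 2
    grouped["sd"] = grouped["sd"].fillna(0.0)
    grouped["se"] = np.where(grouped["n"] > 1, grouped["sd"] / np.sqrt(grouped["n"]), 0.0)
    return grouped


def postfire_regen_in_patches(
    output: SimOutput,
    lag: int = 5,
    window: tuple[int, int] = EARLY_REGEN_WINDOW,
    *,
    area_weighted: bool = True,
) -> pd.DataFrame:
    """Per-species mean regeneration density within fire patches at ``lag``
    years after each fire whose observation year falls in ``window``.

    A fire patch is the set of burned cells of one fire event. Regeneration
    is the density of cohorts no older than the lag (new postfire
    establishment, not pre-fire survivors). Fires too close to the end of
    the simulation for the lag are excluded and counted. Across fires the
    default is an area-weighted mean (pooling cells); ``area_weighted=False``
    averages fire means equally. Fires with no regeneration observation
    produce no rows (no fires is distinct from zero regeneration).
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    years = output.years
    last_year = int(years[-1])
    y0, y1 = window
    rows = []
    n_excluded = 0
    fire_cells: dict[int, tuple[int, np.ndarray]] = {}
    for _, fire in output.fires.iterrows():
        fire_year = int(fire["year"])
        obs_year = fire_year + lag
        if not (y0 <= obs_year <= y1):
            continue
        if obs_year > last_year:
            n_excluded += 1
            continue
        yi = int(np.flatnonzero(years == fire_year)[0])
        cells = output.fire_id_maps[yi] == int(fire["fire_id"])
        if cells.any():
            fire_cells[int(fire["fire_id"])] = (obs_year, cells)

    for sp in output.species_names:
        densities = []
        weights = []
        for fid, (obs_year, cells) in fire_cells.items():
            oi = int(np.flatnonzero(years == obs_year)[0])
            dens = output.cohort_density[sp][oi]
            age = output.cohort_age[sp][oi]
            young = np.where(age <= lag, dens, 0.0)
            densities.append(float(young[cells].mean()))
            weights.append(float(cells.sum()))
        if not densities:
            continue
        w = np.asarray(weights) if area_weighted else np.ones(len(weights))
        rows.append(
            {
                "scenario": output.scenario,
                "climate": output.climate,
                "replicate": output.replicate,
                "species": sp,
                "lag": lag,
                "window": f"{y0}-{y1}",
                "mean_density": float(np.average(densities, weights=w)),
                "n_fires": len(densities),
                "n_excluded": n_excluded,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "scenario", "climate", "replicate", "species", "lag", "window",
            "mean_density", "n_fires", "n_excluded",
        ],
    )


def regen_table(
    outputs: list[SimOutput],
    lag: int = 5,
    *,
    area_weighted: bool = True,
) -> pd.DataFrame:
    """Tidy table of in-patch postfire regeneration, early and late periods."""
    frames = []
    for out in outputs:
        for period, window in (("early", EARLY_REGEN_WINDOW), ("late", LATE_REGEN_WINDOW)):
            df = postfire_regen_in_patches(out, lag=lag, window=window, area_weighted=area_weighted)
            if not df.empty:
                df["period"] = period
                frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=[
                "scenario", "climate", "replicate", "species", "lag", "window",
                "mean_density", "n_fires", "n_excluded", "period",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def landscape_regen_final(output: SimOutput, fx: FxScenario) -> dict[str, np.ndarray]:
    """Final-year per-species regeneration with Fx cells masked out (NaN)."""
    masked = {}
    for sp, raster in output.final_regen.items():
        arr = raster.astype(np.float32).copy()
        arr[fx.mask == 1] = np.nan
        masked[sp] = arr
    return masked


@dataclass
class DifferenceMap:
    """Cellwise operational-minus-reference regeneration difference.

    ``classes`` partitions cells into more / less / none / absent using the
    ecological threshold (default 100 seedlings/ha); ``signed_log`` is
    sign(delta) * log10(|delta|) where |delta| exceeds the threshold and NaN
    elsewhere.
    """

    species: str
    delta: np.ndarray
    classes: np.ndarray  # object array of class labels
    signed_log: np.ndarray
    threshold: float

    def class_mask(self, label: str) -> np.ndarray:
        return self.classes == label

    def code_raster(self) -> np.ndarray:
        out = np.zeros(self.delta.shape, dtype=np.int8)
        for label, code in CLASS_CODES.items():
            out[self.classes == label] = code
        return out


def difference_map(
    op_runs: np.ndarray,
    ref_runs: np.ndarray,
    threshold: float = 100.0,
    species: str = "",
    presence_eps: float = 1e-9,
) -> DifferenceMap:
    """Difference in replicate-mean regeneration between two scenarios.

    ``op_runs`` and ``ref_runs`` are (n_replicates, nrows, ncols) stacks of
    final-year densities with equal replicate counts. Cells where the
    species is absent from both scenario means are classed ``absent``; cells
    within +/- ``threshold`` are ``none``; the rest are ``more`` / ``less``
    by the sign of the difference.
    """
    op_runs = np.asarray(op_runs, dtype=float)
    ref_runs = np.asarray(ref_runs, dtype=float)
    if op_runs.shape != ref_runs.shape:
        raise ValueError(f"replicate stacks differ in shape: {op_runs.shape} vs {ref_runs.shape}")
    mean_op = op_runs.mean(axis=0)
    mean_ref = ref_runs.mean(axis=0)
    delta = mean_op - mean_ref

    absent = (mean_op <= presence_eps) & (mean_ref <= presence_eps)
    small = np.abs(delta) <= threshold
    classes = np.full(delta.shape, CLASS_NONE, dtype=object)
    classes[~small & (delta > 0)] = CLASS_MORE
    classes[~small & (delta < 0)] = CLASS_LESS
    classes[absent] = CLASS_ABSENT

    signed_log = np.full(delta.shape, np.nan)
    big = ~small
    with np.errstate(divide="ignore"):
        signed_log[big] = np.sign(delta[big]) * np.log10(np.abs(delta[big]))
    return DifferenceMap(
        species=species, delta=delta, classes=classes, signed_log=signed_log, threshold=threshold
    )


def distance_to_fx(
    diff: DifferenceMap,
    fx: FxScenario,
    grid: GridSpec,
    *,
    zone_fraction: float = 0.75,
) -> dict:
    """Mean Euclidean distance (m) from each difference class to the nearest
    Fx cell, center to center, plus a zone-of-influence summary.

    The zone of influence is the distance below which ``zone_fraction`` of
    the ``more`` cells fall. Empty classes report NaN.
    """
    if fx.mask.sum() == 0:
        raise ValueError("Fx mask is empty; distances are undefined")
    dist = ndimage.distance_transform_edt(fx.mask == 0, sampling=grid.cell_size)
    result: dict = {"unit": "m"}
    for label in (CLASS_MORE, CLASS_LESS, CLASS_NONE):
        cells = diff.class_mask(label) & (fx.mask == 0)
        if cells.any():
            result[label] = float(dist[cells].mean())
        else:
            result[label] = float("nan")
            warnings.warn(f"difference class {label!r} is empty; distance reported as missing")
    more_cells = diff.class_mask(CLASS_MORE) & (fx.mask == 0)
    result["zone_of_influence"] = (
        float(np.quantile(dist[more_cells], zone_fraction)) if more_cells.any() else float("nan")
    )
    return result
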