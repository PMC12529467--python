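"""Experiment orchestration: factorial design, robustness set, operational comparison.

The factorial experiment crosses Fx amount (10 / 30 / 50 % of forested
area) and configuration (dispersed / clumped) plus a no-exclusion reference
— seven scenarios — with four climate scenarios and replicate fire
histories (20 replicates = 560 runs at full scale; a desk-scale preset uses
a 100 x 100 grid and 5 replicates = 140 runs). A robustness set varies the
NLM realization (10 NLMs x 2 configurations x 10 fire histories, hot-dry
climate only = 200 runs). The operational comparison runs the operational
Fx scenario against the reference and builds difference maps.

Seeds for every stream (landscape, NLM, fire, regeneration) derive
deterministically from one master seed via a stable counter hash, with fire
histories paired across scenarios within a replicate (variance reduction;
an ``independent_fires`` flag decouples them).
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from fxsim.grid import GridSpec
from fxsim.landscape import (
    CLIMATE_SCENARIOS,
    ClimateSeries,
    LandscapeState,
    generate_climate,
    generate_landscape,
    generate_operational_inputs,
)
from fxsim.metrics import (
    area_burned_by_period,
    difference_map,
    distance_to_fx,
    regen_table,
)
from fxsim.scenarios import FxScenario, delineate_operational, nlm_scenario, reference_scenario
from fxsim.simulator import RegimeParams, calibrate_regime, run_simulation
from fxsim.species import default_species
from fxsim.stats import (
    anova_summary_frame,
    regression_summary_frame,
    scenario_regression,
    two_way_anova,
)

logger = logging.getLogger("fxsim")

AMOUNTS = (0.1, 0.3, 0.5)
CONFIGURATIONS = ("dispersed", "clumped")


def derive_seed(master_seed: int, *parts) -> int:
    """Stable sub-seed from a master seed and a stream name tuple (< 2^31)."""
    key = f"{master_seed}:" + ":".join(str(p) for p in parts)
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


@dataclass
class RunManifest:
    """One simulation run: scenario provenance, climate, replicate, seeds."""

    run_id: str
    kind: str  # nlm | operational | reference
    amount: float
    configuration: str
    climate: str
    replicate: int
    seeds: dict[str, int]
    status: str = "pending"

    def to_row(self) -> dict:
        row = asdict(self)
        row.update({f"seed_{k}": v for k, v in row.pop("seeds").items()})
        return row


def build_factorial_manifest(
    master_seed: int,
    replicates: int = 20,
    *,
    amounts: tuple[float, ...] = AMOUNTS,
    configurations: tuple[str, ...] = CONFIGURATIONS,
    climates: tuple[str, ...] = CLIMATE_SCENARIOS,
    independent_fires: bool = False,
) -> list[RunManifest]:
    """Enumerate the factorial: (amounts x configurations + reference) x
    climates x replicates. One NLM per amount x configuration (fixed seed);
    fire seeds vary by replicate and are paired across scenarios by default.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    scenarios: list[tuple[str, float, str]] = [("reference", 0.0, "n/a")]
    scenarios += [("nlm", a, c) for a in amounts for c in configurations]
    runs = []
    for kind, amount, config in scenarios:
        scen_key = f"{kind}-{amount}-{config}"
        nlm_seed = derive_seed(master_seed, "nlm", scen_key)
        for climate in climates:
            for rep in range(replicates):
                fire_key = (scen_key, climate, rep) if independent_fires else (climate, rep)
                runs.append(
                    RunManifest(
                        run_id=f"{kind[:3]}_{int(amount * 100):02d}_{config[:4].replace('/', '')}_{climate}_r{rep:02d}",
                        kind=kind,
                        amount=amount,
                        configuration=config,
                        climate=climate,
                        replicate=rep,
                        seeds={
                            "landscape": derive_seed(master_seed, "landscape"),
                            "nlm": nlm_seed,
                            "fire": derive_seed(master_seed, "fire", *fire_key),
                            "regen": derive_seed(master_seed, "regen", scen_key, climate, rep),
                        },
                    )
                )
    _check_unique(runs)
    return runs


def build_robustness_manifest(
    master_seed: int,
    *,
    n_nlms: int = 10,
    n_fire_histories: int = 10,
    amount: float = 0.3,
    climate: str = "hot-dry",
    configurations: tuple[str, ...] = CONFIGURATIONS,
) -> list[RunManifest]:
    """NLM-robustness set: unique NLMs x configurations x fire histories in
    one climate (10 x 2 x 10 = 200 runs at the defaults)."""
    runs = []
    for config in configurations:
        for nlm_i in range(n_nlms):
            nlm_seed = derive_seed(master_seed, "nlm-rob", config, nlm_i)
            for rep in range(n_fire_histories):
                runs.append(
                    RunManifest(
                        run_id=f"rob_{config[:4]}_n{nlm_i:02d}_{climate}_r{rep:02d}",
                        kind="nlm",
                        amount=amount,
                        configuration=config,
                        climate=climate,
                        replicate=rep,
                        seeds={
                            "landscape": derive_seed(master_seed, "landscape"),
                            "nlm": nlm_seed,
                            "fire": derive_seed(master_seed, "fire", climate, rep),
                            "regen": derive_seed(master_seed, "regen-rob", config, nlm_i, rep),
                        },
                    )
                )
    _check_unique(runs)
    return runs


def _check_unique(runs: list[RunManifest]) -> None:
    ids = [r.run_id for r in runs]
    if len(set(ids)) != len(ids):
        raise ValueError("run ids are not unique")


def manifest_frame(runs: list[RunManifest]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in runs])


@dataclass
class ExperimentConfig:
    """Problem sizes and model settings for one experiment."""

    nrows: int = 100
    ncols: int = 100
    cell_size: float = 100.0
    years: tuple[int, int] = (2021, 2100)
    lag: int = 5
    fractal_dim: float = 0.9
    maturity_age: float = 60.0
    recent_burn_horizon: float = 40.0
    p_base: float = 0.55
    burn_frac_ref: float = 0.017
    peak_ratio: float = 3.4

    @classmethod
    def preset(cls, name: str) -> "ExperimentConfig":
        if name == "ci":
            return cls()
        if name == "full":
            return cls(nrows=200, ncols=200)
        raise ValueError(f"unknown preset {name!r}")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.nrows, self.ncols, self.cell_size)

    @property
    def year_range(self) -> range:
        return range(self.years[0], self.years[1] + 1)


def build_inputs(
    config: ExperimentConfig, master_seed: int
) -> tuple[LandscapeState, dict[str, ClimateSeries], RegimeParams]:
    """Landscape, the four climate series, and the calibrated fire regime."""
    species = default_species()
    state = generate_landscape(config.grid, species, derive_seed(master_seed, "landscape"))
    climates = {
        name: generate_climate(name, config.year_range, derive_seed(master_seed, "climate", name))
        for name in CLIMATE_SCENARIOS
    }
    stockable_ha = float(state.stockable.sum()) * config.grid.cell_area_ha
    ww = climates["warm-wet"].aridity_index
    hd = climates["hot-dry"].aridity_index
    regime = calibrate_regime(
        stockable_ha,
        aridity_ref=float(np.mean(ww)),
        aridity_peak=float(np.mean(hd[-25:])),
        burn_frac_ref=config.burn_frac_ref,
        peak_ratio=config.peak_ratio,
    )
    return state, climates, regime


def _resolve_scenario(
    run: RunManifest, state: LandscapeState, config: ExperimentConfig, cache: dict
) -> FxScenario:
    key = (run.kind, run.amount, run.configuration, run.seeds.get("nlm"))
    if key not in cache:
        if run.kind == "reference":
            cache[key] = reference_scenario(state.grid)
        elif run.kind == "nlm":
            cache[key] = nlm_scenario(
                state,
                run.amount,
                run.configuration,
                run.seeds["nlm"],
                fractal_dim=config.fractal_dim,
                maturity_age=config.maturity_age,
                recent_burn_horizon=config.recent_burn_horizon,
            )
        elif run.kind == "operational":
            inputs = generate_operational_inputs(state, run.seeds["nlm"])
            cache[key] = delineate_operational(inputs, state, maturity_age=config.maturity_age)
        else:
            raise ValueError(f"unknown scenario kind {run.kind!r}")
    return cache[key]


@dataclass
class ExperimentResult:
    """Aggregated outputs of one experiment."""

    manifest: pd.DataFrame
    area_burned: pd.DataFrame  # per-group summary
    area_burned_runs: pd.DataFrame  # per-run per-period means
    regen: pd.DataFrame  # tidy in-patch regeneration table
    anova: pd.DataFrame = field(default_factory=pd.DataFrame)
    regression: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_failed: int = 0
    exclusion_violations: int = 0  # burned cells inside Fx masks, all runs


def run_experiment(
    manifest: list[RunManifest],
    config: ExperimentConfig,
    master_seed: int,
    *,
    outdir: str | Path | None = None,
    lag: int | None = None,
    with_stats: bool = True,
) -> ExperimentResult:
    """Execute every run in the manifest and aggregate the responses.

    Per-run metric rows are written under ``outdir/runs`` when an output
    directory is given; reruns skip completed runs (resumable). Failed runs
    are logged, excluded from aggregation, and counted. An empty manifest
    yields an empty report with a warning.
    """
    lag = config.lag if lag is None else lag
    out_path = Path(outdir) if outdir is not None else None
    runs_dir = None
    if out_path is not None:
        runs_dir = out_path / "runs"
        runs_dir.mkdir(parents=True, exist_ok=True)

    if not manifest:
        logger.warning("empty manifest: nothing to run")
        empty = pd.DataFrame()
        return ExperimentResult(empty, empty, empty, empty)

    state, climates, regime = build_inputs(config, master_seed)
    scen_cache: dict = {}
    burn_rows: list[dict] = []
    regen_frames: list[pd.DataFrame] = []
    n_failed = 0
    violations = 0

    for run in manifest:
        cached = runs_dir / f"{run.run_id}.json" if runs_dir is not None else None
        if cached is not None and cached.exists():
            payload = json.loads(cached.read_text())
            if payload["seeds"] == run.seeds:
                burn_rows.extend(payload["burn_rows"])
                if payload["regen_rows"]:
                    regen_frames.append(pd.DataFrame(payload["regen_rows"]))
                violations += payload.get("violations", 0)
                run.status = "cached"
                continue
        try:
            fx = _resolve_scenario(run, state, config, scen_cache)
            label = fx.label if run.kind != "reference" else "reference"
            output = run_simulation(
                state,
                climates[run.climate],
                fx,
                regime,
                fire_seed=run.seeds["fire"],
                regen_seed=run.seeds["regen"],
                scenario_label=label,
                replicate=run.replicate,
                p_base=config.p_base,
            )
        except Exception:
            logger.exception("run %s failed", run.run_id)
            run.status = "failed"
            n_failed += 1
            continue
        run.status = "done"
        run_violations = int((output.fire_id_maps[:, fx.mask == 1] > 0).sum())
        violations += run_violations
        rows = _burn_rows(run, output)
        burn_rows.extend(rows)
        regen = regen_table([output], lag=lag)
        regen = _annotate(regen, run)
        if not regen.empty:
            regen_frames.append(regen)
        if cached is not None:
            cached.write_text(
                json.dumps(
                    {
                        "seeds": run.seeds,
                        "burn_rows": rows,
                        "regen_rows": regen.to_dict("records"),
                        "violations": run_violations,
                    }
                )
            )

    area_runs = pd.DataFrame(burn_rows)
    area_summary = pd.DataFrame()
    if not area_runs.empty:
        grouped = (
            area_runs.groupby(["scenario", "climate", "period"])["mean_ha_per_yr"]
            .agg(mean="mean", sd="std", n="count")
            .reset_index()
        )
        grouped["sd"] = grouped["sd"].fillna(0.0)
        grouped["se"] = np.where(grouped["n"] > 1, grouped["sd"] / np.sqrt(grouped["n"]), 0.0)
        area_summary = grouped

    regen_df = (
        pd.concat(regen_frames, ignore_index=True) if regen_frames else pd.DataFrame()
    )
    anova_df = pd.DataFrame()
    regression_df = pd.DataFrame()
    if with_stats and not regen_df.empty:
        anova_df, regression_df = run_stats(regen_df)

    result = ExperimentResult(
        manifest=manifest_frame(manifest),
        area_burned=area_summary,
        area_burned_runs=area_runs,
        regen=regen_df,
        anova=anova_df,
        regression=regression_df,
        n_failed=n_failed,
        exclusion_violations=violations,
    )
    if out_path is not None:
        write_report(result, out_path)
    return result


def _burn_rows(run: RunManifest, output) -> list[dict]:
    summary = area_burned_by_period([output])
    rows = []
    for _, row in summary.iterrows():
        rows.append(
            {
                "run_id": run.run_id,
                "scenario": row["scenario"],
                "amount": run.amount,
                "configuration": run.configuration,
                "climate": row["climate"],
                "replicate": run.replicate,
                "period": row["period"],
                "mean_ha_per_yr": row["mean"],
            }
        )
    return rows


def _annotate(regen: pd.DataFrame, run: RunManifest) -> pd.DataFrame:
    if regen.empty:
        return regen
    regen = regen.copy()
    regen["run_id"] = run.run_id
    regen["amount"] = run.amount
    regen["configuration"] = run.configuration
    return regen


def run_stats(regen_df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ANOVA (per species x period, Fx runs only, climates pooled) and
    per-climate regressions (reference included) from a tidy regen table."""
    anova_results = {}
    regression_results = {}
    for (species, period), grp in regen_df.groupby(["species", "period"]):
        fx_only = grp[grp["amount"] > 0]
        if (
            fx_only["amount"].nunique() >= 2
            and fx_only["configuration"].nunique() >= 2
            and len(fx_only) >= 8
        ):
            try:
                anova_results[f"{species}|{period}"] = two_way_anova(
                    fx_only, response_label=f"{species}|{period}"
                )
            except Exception:
                logger.exception("ANOVA failed for %s %s", species, period)
        for climate, cgrp in grp.groupby("climate"):
            if len(cgrp) >= 4 and cgrp["amount"].nunique() >= 2:
                key = f"{species}|{climate}|{period}"
                try:
                    regression_results[key] = scenario_regression(cgrp, response_label=key)
                except Exception:
                    logger.exception("regression failed for %s", key)
    return anova_summary_frame(anova_results), regression_summary_frame(regression_results)


def write_report(result: ExperimentResult, outdir: str | Path, *, plots: bool = False) -> None:
    """Persist the experiment report as CSVs (and optional PNG figures)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.manifest.to_csv(out / "manifest.csv", index=False)
    result.area_burned_runs.to_csv(out / "area_burned_runs.csv", index=False)
    result.area_burned.to_csv(out / "area_burned_summary.csv", index=False)
    result.regen.to_csv(out / "regen.csv", index=False)
    result.anova.to_csv(out / "anova.csv", index=False)
    result.regression.to_csv(out / "regression.csv", index=False)
    if result.n_failed:
        (out / "failures.txt").write_text(f"failed runs: {result.n_failed}\n")
    if plots and not result.area_burned.empty:
        _plot_report(result, out)


def _plot_report(result: ExperimentResult, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4))
    for ax, period in zip(axes, ("early", "late")):
        sub = result.area_burned[result.area_burned["period"] == period]
        piv = sub.pivot_table(index="scenario", columns="climate", values="mean")
        piv.plot.bar(ax=ax, yerr=None)
        ax.set_ylabel("area burned (ha/yr)")
        ax.set_title(f"{period} century")
    fig.tight_layout()
    fig.savefig(out / "area_burned.png", dpi=120)
    plt.close(fig)

    if not result.regen.empty:
        fig, ax = plt.subplots(figsize=(9, 4))
        summary = (
            result.regen.groupby(["species", "scenario", "period"])["mean_density"]
            .agg(["mean", "sem"])
            .reset_index()
        )
        for i, (species, grp) in enumerate(summary.groupby("species")):
            late = grp[grp["period"] == "late"]
            ax.errorbar(
                [f"{species[:8]}\n{s}" for s in late["scenario"]],
                late["mean"],
                yerr=2 * late["sem"].fillna(0.0),
                fmt="o",
            )
        ax.set_ylabel("seedlings/ha (late)")
        ax.tick_params(axis="x", rotation=90, labelsize=6)
        fig.tight_layout()
        fig.savefig(out / "regen_late.png", dpi=120)
        plt.close(fig)


@dataclass
class OperationalComparison:
    """Operational-vs-reference outputs for one climate scenario."""

    climate: str
    fx: FxScenario
    diff_maps: dict[str, object]  # species -> DifferenceMap
    distances: dict[str, dict]  # species -> class distance summary (m)
    regen: pd.DataFrame


def run_operational_comparison(
    config: ExperimentConfig,
    master_seed: int,
    *,
    climate: str = "hot-dry",
    replicates: int = 5,
    species_subset: tuple[str, ...] = ("subalpine_fir", "engelmann_spruce", "douglas_fir"),
) -> OperationalComparison:
    """Run operational and reference scenarios and compare end-of-century
    regeneration cell by cell (difference maps, distance to Fx)."""
    state, climates, regime = build_inputs(config, master_seed)
    inputs = generate_operational_inputs(state, derive_seed(master_seed, "operational"))
    fx_op = delineate_operational(inputs, state, maturity_age=config.maturity_age)
    fx_ref = reference_scenario(state.grid)

    stacks: dict[str, dict[str, list[np.ndarray]]] = {
        "operational": {sp: [] for sp in species_subset},
        "reference": {sp: [] for sp in species_subset},
    }
    regen_frames = []
    for label, fx in (("operational", fx_op), ("reference", fx_ref)):
        for rep in range(replicates):
            output = run_simulation(
                state,
                climates[climate],
                fx,
                regime,
                fire_seed=derive_seed(master_seed, "fire", climate, rep),
                regen_seed=derive_seed(master_seed, "regen-op", label, rep),
                scenario_label=label,
                replicate=rep,
                p_base=config.p_base,
            )
            for sp in species_subset:
                stacks[label][sp].append(output.final_regen[sp])
            regen = regen_table([output], lag=config.lag)
            if not regen.empty:
                regen_frames.append(regen)

    diff_maps = {}
    distances = {}
    for sp in species_subset:
        dm = difference_map(
            np.stack(stacks["operational"][sp]),
            np.stack(stacks["reference"][sp]),
            species=sp,
        )
        diff_maps[sp] = dm
        if fx_op.mask.sum():
            distances[sp] = distance_to_fx(dm, fx_op, config.grid)
    return OperationalComparison(
        climate=climate,
        fx=fx_op,
        diff_maps=diff_maps,
        distances=distances,
        regen=pd.concat(regen_frames, ignore_index=True) if regen_frames else pd.DataFrame(),
    )
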