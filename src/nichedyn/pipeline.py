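"""End-to-end orchestration: simulate -> ordinate -> dynamics -> drivers ->
sdm -> report, with every artifact stamped with the config hash and seed."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import drivers as drv
from . import dynamics as dyn
from . import ordination as ordn
from . import sdm as sdmmod
from . import simulate as sim
from .core import (
    AnalysisConfig,
    ClimateGrid,
    ContractError,
    RangeSet,
    filter_min_presences,
    read_climate_grid,
    read_presence_table,
    resolve_range_overlap,
    write_climate_grid,
    write_presence_table,
)

logger = logging.getLogger("nichedyn")

STAGES = ("simulate", "ordinate", "dynamics", "drivers", "sdm", "report")

__all__ = ["STAGES", "compare_niches", "run_pipeline"]


def compare_niches(
    native_grid: ClimateGrid,
    alien_grid: ClimateGrid,
    native_range: RangeSet,
    alien_range: RangeSet,
    config: AnalysisConfig | None = None,
) -> tuple[dyn.NicheComparison, dict]:
    """Full niche comparison for one species x realm.

    Calibrates the two-axis climate ordination on the pooled cells of both
    regions, kernel-smooths native and alien occupancy on a shared grid,
    restricts to analog climates, and returns the E/S/U record together with
    the intermediate objects (ordination, grids, mask, novelty report).
    """
    config = config or AnalysisConfig()
    pooled = np.vstack([native_grid.climate, alien_grid.climate])
    ordination = ordn.fit_scaled_pca(pooled, n_axes=2)
    ok_var = ordn.variance_check(ordination, 0.75)

    s_np = ordn.project_scores(ordination, native_grid.climate_for(native_range.cell_ids))
    s_ap = ordn.project_scores(ordination, alien_grid.climate_for(alien_range.cell_ids))
    s_nb = ordn.project_scores(ordination, native_grid.climate)
    s_ab = ordn.project_scores(ordination, alien_grid.climate)

    bf = ordn.DEFAULT_BANDWIDTH_FACTOR
    h1 = bf * max(ordn.silverman_bandwidth(s_np[:, 0]), ordn.silverman_bandwidth(s_ap[:, 0]))
    h2 = bf * max(ordn.silverman_bandwidth(s_np[:, 1]), ordn.silverman_bandwidth(s_ap[:, 1]))
    allsc = np.vstack([s_np, s_ap, s_nb, s_ab])
    extent = (
        allsc[:, 0].min() - h1, allsc[:, 0].max() + h1,
        allsc[:, 1].min() - h2, allsc[:, 1].max() + h2,
    )
    g_native = ordn.estimate_occupancy_grid(
        s_np, s_nb, config.grid_resolution, extent, config.occupancy_correction
    )
    g_alien = ordn.estimate_occupancy_grid(
        s_ap, s_ab, config.grid_resolution, extent, config.occupancy_correction
    )
    mask = ordn.compute_analog_mask(g_native, g_alien, config.analog_quantile)
    E, S, U = dyn.niche_dynamic_indices(
        g_native, g_alien, mask, config.occupancy_quantile
    )
    novelty = ordn.novelty_summary(alien_grid.climate, native_grid.climate)
    comparison = dyn.NicheComparison(
        species_id=alien_range.species_id,
        realm_id=alien_range.realm_id,
        expansion=E, stability=S, unfilling=U,
        percent_novel=novelty.percent_novel,
        variance_check=ok_var,
        exceeds_5pct=novelty.exceeds_5pct,
        n_native=native_range.n,
        n_alien=alien_range.n,
    )
    detail = {
        "ordination": ordination,
        "native_grid": g_native,
        "alien_grid": g_alien,
        "analog_mask": mask,
        "novelty": novelty,
    }
    return comparison, detail


def _default_scenarios():
    """The three canonical scenarios: niche conservatism, geometric
    unfilling, and optimum-shift expansion."""
    return {
        "conserved": dict(delta=(0.0, 0.0), mask_fn=None),
        "unfilled": dict(delta=(0.0, 0.0), mask_fn=sim.half_mass_mask()),
        "expanded": dict(delta=(2.0, 0.0), mask_fn=None),
    }


def run_pipeline(
    config: AnalysisConfig,
    out_dir: str | Path,
    stages: tuple[str, ...] = STAGES,
    n_presences: int = 400,
    n_cells: int = 10000,
    driver_variables: list[str] | None = None,
    driver_n: int = 337,
) -> dict:
    """Run the requested stages on the bundled synthetic world.

    Each stage writes CSV outputs under ``out_dir`` and appends to the JSON
    run manifest (stamped with the config hash and seed).  Stages read the
    CSVs written by earlier stages, so a stage can be re-run in isolation.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ContractError(f"unknown stage(s): {sorted(unknown)}; valid: {STAGES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = (json.loads(manifest_path.read_text())
                if manifest_path.exists() else {})
    manifest["config"] = config.to_dict()
    manifest["config_hash"] = config.hash()
    manifest["seed"] = config.seed
    results: dict = {"manifest": manifest}

    scenario_specs = _default_scenarios()

    def stamp(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        df["config_hash"] = config.hash()
        df["seed"] = config.seed
        return df

    if "simulate" in stages:
        truth = {}
        for i, (name, spec) in enumerate(scenario_specs.items()):
            sc = sim.make_scenario(
                n_native=n_presences, n_alien=n_presences, n_cells=n_cells,
                seed=config.seed + i, species_id=name, **spec,
            )
            write_climate_grid(sc.native_grid, out / f"{name}_native_climate.csv")
            write_climate_grid(sc.alien_grid, out / f"{name}_alien_climate.csv")
            write_presence_table(
                [sc.native_range, sc.alien_range], out / f"{name}_presences.csv"
            )
            truth[name] = {
                "true_expansion": sc.true_expansion,
                "true_stability": sc.true_stability,
                "true_unfilling": sc.true_unfilling,
            }
        (out / "truth.json").write_text(json.dumps(
            {"config_hash": config.hash(), "seed": config.seed, "truth": truth},
            indent=2,
        ))
        manifest["simulate"] = {"scenarios": sorted(scenario_specs)}
        results["truth"] = truth

    if "ordinate" in stages or "dynamics" in stages:
        rows = []
        for name in scenario_specs:
            ng = read_climate_grid(out / f"{name}_native_climate.csv", "native_region")
            ag = read_climate_grid(out / f"{name}_alien_climate.csv", "alien_region")
            ranges = read_presence_table(
                out / f"{name}_presences.csv", {"native": ng, "alien": ag}
            )
            nat = next(r for r in ranges if r.role == "native")
            ali = next(r for r in ranges if r.role == "alien")
            if nat.cell_ids & ali.cell_ids:  # two-region worlds never overlap
                nat = resolve_range_overlap(nat, ali)
            kept, _ = filter_min_presences([nat, ali], config.min_presences)
            if len(kept) < 2:
                logger.warning("%s: dropped by the minimum-presence filter", name)
                continue
            comparison, _detail = compare_niches(ng, ag, nat, ali, config)
            flags = dyn.binarize_metrics(comparison, config.binary_threshold)
            rows.append({
                "scenario": name,
                "species_id": comparison.species_id,
                "realm_id": comparison.realm_id,
                "expansion": comparison.expansion,
                "stability": comparison.stability,
                "unfilling": comparison.unfilling,
                "percent_novel": comparison.percent_novel,
                "exceeds_5pct": comparison.exceeds_5pct,
                "variance_check": comparison.variance_check,
                **{f"flag_{k}": v for k, v in flags.items()},
            })
        comp_df = stamp(pd.DataFrame(rows))
        comp_df.to_csv(out / "niche_comparisons.csv", index=False)
        manifest["dynamics"] = {"n_comparisons": len(comp_df)}
        results["comparisons"] = comp_df

    if "drivers" in stages:
        table = sim.generate_driver_table(seed=config.seed)
        table.to_csv(out / "driver_table.csv", index=False)
        variables = driver_variables or drv.DRIVER_NAMES
        out_tables = {}
        for response, family in (("expansion", "binomial"), ("unfilling", "beta")):
            design = drv.prepare_design(table, response)[variables]
            retained, vif_table = drv.vif_screen(design)
            if response == "expansion":
                y = table["expansion"].to_numpy(dtype=float)
                factors = {"realm": pd.Categorical(table["realm"]).codes.astype(np.intp)}
            else:
                y = drv.shrink_to_open_interval(
                    np.sqrt(table["unfilling"].to_numpy(dtype=float))
                )
                factors = {
                    "realm": pd.Categorical(table["realm"]).codes.astype(np.intp),
                    "order": pd.Categorical(table["order"]).codes.astype(np.intp),
                }
            cs, avg, _gm = drv.all_subsets_inference(
                design[retained], y, family, factors,
                delta_cutoff=config.delta_aicc_cutoff,
            )
            stamp(avg.table).to_csv(out / f"averaged_{response}.csv", index=False)
            rank = cs.table.copy()
            rank["variables"] = rank["variables"].map(lambda v: "+".join(v) or "1")
            stamp(rank).to_csv(out / f"candidates_{response}.csv", index=False)
            vif_table.to_csv(out / f"vif_{response}.csv", index=False)
            out_tables[response] = (cs, avg)
        manifest["drivers"] = {
            "n_candidates": {r: out_tables[r][0].n_candidates for r in out_tables}
        }
        results["drivers"] = out_tables

    if "sdm" in stages:
        rows = []
        comp_df = pd.read_csv(out / "niche_comparisons.csv")
        for name in scenario_specs:
            ng = read_climate_grid(out / f"{name}_native_climate.csv", "native_region")
            ag = read_climate_grid(out / f"{name}_alien_climate.csv", "alien_region")
            ranges = read_presence_table(
                out / f"{name}_presences.csv", {"native": ng, "alien": ag}
            )
            nat = next(r for r in ranges if r.role == "native")
            ali = next(r for r in ranges if r.role == "alien")
            nat_rows = ng.rows_for(nat.sorted_cells())
            ali_rows = ag.rows_for(ali.sorted_cells())
            nat_mask = np.zeros(ng.n_cells, dtype=bool)
            nat_mask[nat_rows] = True
            ali_mask = np.zeros(ag.n_cells, dtype=bool)
            ali_mask[ali_rows] = True
            pooled = np.vstack([ng.climate, ag.climate])
            try:
                ens = sdmmod.fit_native_ensemble(
                    ng.climate[nat_mask], ng.climate[~nat_mask], pooled,
                    species_id=name, n_axes=config.sdm_axes,
                    n_pa_sets=config.sdm_pa_sets,
                    n_replicates=config.sdm_replicates,
                    n_trees=config.sdm_trees,
                    calibration_fraction=config.sdm_calibration_fraction,
                    auc_cutoff=config.sdm_auc_cutoff,
                    seed=config.seed,
                )
                ev = sdmmod.evaluate_transfer(
                    ens, ag.climate[ali_mask], ag.climate[~ali_mask],
                    np.vstack([ng.climate[~nat_mask], ag.climate[~ali_mask]]),
                    realm_id=ali.realm_id, seed=config.seed,
                )
            except (ContractError, sdmmod.UntransferableError) as exc:
                logger.warning("%s: transfer evaluation skipped (%s)", name, exc)
                continue
            comp = comp_df[comp_df["scenario"] == name].iloc[0]
            rows.append({
                "scenario": name,
                "auc": ev.auc, "max_tss": ev.max_tss, "cbi": ev.cbi,
                "sensitivity": ev.sensitivity, "specificity": ev.specificity,
                "tier": ev.tier,
                "expansion": comp["expansion"], "unfilling": comp["unfilling"],
            })
        ev_df = stamp(pd.DataFrame(rows))
        ev_df.to_csv(out / "transfer_evaluations.csv", index=False)
        manifest["sdm"] = {"n_evaluations": len(ev_df)}
        results["transfer"] = ev_df

    if "report" in stages:
        comp_df = pd.read_csv(out / "niche_comparisons.csv")
        comparisons = [
            dyn.NicheComparison(
                species_id=r.species_id, realm_id=r.realm_id,
                expansion=r.expansion, stability=r.stability,
                unfilling=r.unfilling,
            )
            for r in comp_df.itertuples()
        ]
        summary = stamp(dyn.summarize_by_realm(comparisons, config.binary_threshold))
        summary.to_csv(out / "realm_summary.csv", index=False)
        manifest["report"] = {"n_realms": len(summary) - 1}
        results["summary"] = summary

    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return results
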