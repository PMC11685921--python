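"""End-to-end pipeline driver.

Stages: simulate -> assign -> drift -> community -> assembly -> stats.
(Source assignment runs before drift because drift target zones come from
the genetic assignments.)  Each stage consumes only declared upstream
outputs under the run directory, every random draw flows from a per-stage
seed registry derived from the run seed, and the final report compares
recovered quantities against the scenario truth.
"""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .assembly import partition_processes
from .community import (
    STATUS_NON_RAFT,
    STATUS_RAFT,
    alpha_diversity,
    bray_curtis,
    classify_and_partition,
    core_taxa,
    dysbiosis_score,
    rarefy,
    weighted_rrna_trait,
)
from .drift import advect_backward, seed_particles, summarize_raft, match_drifter_window
from .envfields import static_point_stats, write_field_csv
from .hostassign import (
    TIER_UNASSIGNED,
    assign_source,
    assignment_to_zone,
    build_support_tree,
)
from .stats import (
    build_site_pairs,
    fit_gdm,
    fit_smooth_glm,
    gdm_importance,
    tost_paired,
    welch_t,
    wilcoxon_z,
)
from .synthdata import (
    ScenarioConfig,
    gen_drifter_tracks,
    gen_environment,
    gen_host_populations,
    gen_microbiomes,
)

STAGES = ("simulate", "assign", "drift", "community", "assembly", "stats")

DEFAULT_CONFIG = {
    "scenario": {},
    "assign": {"n_boot": 60, "support_threshold": 80.0, "buffer_km": 15.0},
    "drift": {
        "n_rafts": 6,
        "n_particles": 20,
        "dt_hours": 2.0,
        "max_days": 15.0,
        "radius_km": 1.0,
        "offshore_deg": 0.6,
    },
    "community": {"rarefy_depth": 4000, "core_stop_fraction": 0.03},
    "assembly": {"n_null": 25, "min_bin": 20},
    "stats": {"n_perm": 25, "tost_bound": 0.25},
}

REQUIRED_BLOCKS = set(DEFAULT_CONFIG)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _merge_config(config: dict | None) -> dict:
    config = config or {}
    unknown = set(config) - REQUIRED_BLOCKS
    if unknown:
        raise ValueError(f"unknown config blocks: {sorted(unknown)}")
    merged = {}
    for block, defaults in DEFAULT_CONFIG.items():
        merged[block] = {**defaults, **config.get(block, {})}
    return merged


def validate_config(config: dict | None) -> dict:
    merged = _merge_config(config)
    cfg = ScenarioConfig(**merged["scenario"])
    merged["scenario_obj"] = cfg
    return merged


def run_pipeline(config: dict | None, out_dir, seed: int = 0) -> dict:
    """Run every stage and write a machine-readable recovery report.

    Returns the report dict; identical (config, seed) produce identical
    reports.
    """
    conf = validate_config(config)
    cfg: ScenarioConfig = conf["scenario_obj"]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {stage: seed + 1000 * i for i, stage in enumerate(STAGES)}
    report: dict = {"seed": seed, "seeds": seeds, "stages": {}}
    t0 = time.time()

    # ---------------- simulate ----------------
    stage_dir = out / "simulate"
    stage_dir.mkdir(exist_ok=True)
    try:
        fields = gen_environment(cfg, seed=seeds["simulate"])
        genotypes, truth_hosts, pop_coords, coastline = gen_host_populations(
            cfg, seed=seeds["simulate"] + 1
        )
        drifters = gen_drifter_tracks(cfg, fields, n=8, seed=seeds["simulate"] + 2)
        write_field_csv(fields["sst"], stage_dir / "sst.csv")
        dio.write_genotypes_tsv(genotypes, stage_dir / "genotypes.tsv")
        dio.write_coords_tsv(genotypes.coords, stage_dir / "coords.tsv")
        dio.write_trajectories_csv(drifters, stage_dir / "drifters.csv")
        dio.write_json(truth_hosts, stage_dir / "truth_hosts.json")
        report["stages"]["simulate"] = {
            "n_individuals": genotypes.n_individuals,
            "n_snps": genotypes.n_loci,
            "n_drifters": len(drifters),
        }
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("simulate", exc) from exc

    # ---------------- assign ----------------
    stage_dir = out / "assign"
    stage_dir.mkdir(exist_ok=True)
    try:
        ac = conf["assign"]
        tree = build_support_tree(
            genotypes, n_boot=int(ac["n_boot"]), seed=seeds["assign"]
        )
        dio.write_tree_newick(tree, stage_dir / "support_tree.nwk")
        assignments = {}
        zones = {}
        correct = 0
        n_assigned = 0
        for query, truth in truth_hosts.items():
            a = assign_source(
                tree, query, genotypes.coords,
                support_threshold=float(ac["support_threshold"]),
            )
            assignments[query] = a
            if a.tier != TIER_UNASSIGNED:
                n_assigned += 1
                zone = assignment_to_zone(a, coastline, buffer_km=float(ac["buffer_km"]))
                zones[query] = zone
                dio.target_zone_to_geojson(zone, stage_dir / f"zone_{query}.geojson")
                if zone.contains(truth["lat"], truth["lon"]):
                    correct += 1
        report["stages"]["assign"] = {
            "n_queries": len(truth_hosts),
            "n_assigned": n_assigned,
            "zone_accuracy": correct / n_assigned if n_assigned else float("nan"),
            "tiers": {q: a.tier for q, a in assignments.items()},
        }
    except Exception as exc:
        raise PipelineError("assign", exc) from exc

    # ---------------- drift ----------------
    stage_dir = out / "drift"
    stage_dir.mkdir(exist_ok=True)
    try:
        dc = conf["drift"]
        domain = (cfg.lat_min, cfg.lat_max, cfg.lon_min, cfg.lon_max)
        raft_ids = [q for q in zones][: int(dc["n_rafts"])]
        summaries = {}
        tallies = {}
        cov_rows = {}
        for r, raft_id in enumerate(raft_ids):
            zone = zones[raft_id]
            site_lat = float(np.mean(zone.lats))
            site_lon = float(np.mean(zone.lons)) + float(dc["offshore_deg"])
            collection_time = cfg.n_days - 2.0
            particles = seed_particles(
                site_lat,
                site_lon,
                collection_time,
                n=int(dc["n_particles"]),
                radius_km=float(dc["radius_km"]),
                seed=seeds["drift"] + r,
            )
            trajectories = [
                advect_backward(
                    p,
                    (fields["cur_u"], fields["cur_v"]),
                    (fields["wind_u"], fields["wind_v"]),
                    zone,
                    domain,
                    dt_hours=float(dc["dt_hours"]),
                    max_days=min(float(dc["max_days"]), collection_time - 1.0),
                )
                for p in particles
            ]
            dio.write_trajectories_csv(trajectories, stage_dir / f"traj_{raft_id}.csv")
            summary = summarize_raft(trajectories, fields["sst"])
            fallback = summarize_raft(trajectories, fields["sst"], reached_only=False)
            summaries[raft_id] = summary
            tallies[raft_id] = {
                s: sum(tr.status == s for tr in trajectories)
                for s in ("reached_target", "left_domain", "timed_out")
            }
            cov_rows[raft_id] = {
                "raft_time": summary.median_raft_time
                if np.isfinite(summary.median_raft_time)
                else float(dc["max_days"]) / 2.0,
                "sst": summary.representative_sst
                if np.isfinite(summary.representative_sst)
                else fallback.representative_sst,
                "sigma_sst": summary.representative_sigma_sst
                if np.isfinite(summary.representative_sigma_sst)
                else fallback.representative_sigma_sst,
            }
        raft_cov = pd.DataFrame.from_dict(cov_rows, orient="index")
        raft_cov.to_csv(stage_dir / "raft_covariates.csv", index_label="raft")
        report["stages"]["drift"] = {
            "fraction_reached": {r: s.fraction_reached for r, s in summaries.items()},
            "median_raft_time": {r: s.median_raft_time for r, s in summaries.items()},
            "termination_tallies": tallies,
        }
    except Exception as exc:
        raise PipelineError("drift", exc) from exc

    # ---------------- community ----------------
    stage_dir = out / "community"
    stage_dir.mkdir(exist_ok=True)
    try:
        cc = conf["community"]
        table, asv_tree, traits, truth_mb = gen_microbiomes(
            cfg, raft_cov, seed=seeds["community"]
        )
        table = rarefy(table, depth=int(cc["rarefy_depth"]), seed=seeds["community"] + 1)
        dio.write_community_tsv(
            table,
            stage_dir / "counts.tsv",
            stage_dir / "metadata.tsv",
            stage_dir / "taxonomy.tsv",
        )
        dio.write_tree_newick(asv_tree, stage_dir / "asv_tree.nwk")
        dio.write_trait_tsv(traits, stage_dir / "traits.tsv")
        dio.write_json(truth_mb, stage_dir / "truth_microbiome.json")

        alpha = alpha_diversity(table)
        alpha.to_csv(stage_dir / "alpha.csv")
        bc = bray_curtis(table)
        core = core_taxa(
            table.by_status(STATUS_NON_RAFT),
            stop_fraction=float(cc["core_stop_fraction"]),
        )
        core.to_csv(stage_dir / "core.csv", index_label="taxon")
        _, fracs = classify_and_partition(table, core.index)
        fracs.to_csv(stage_dir / "class_fractions.csv", index_label="sample")
        dys = dysbiosis_score(bc, table.metadata["status"])
        dys.to_csv(stage_dir / "dysbiosis.csv", index_label="sample")
        trait_vals = weighted_rrna_trait(table, traits)
        trait_vals.to_csv(stage_dir / "rrna_trait.csv", index_label="sample")

        true_core = set(truth_mb["core_taxa"])
        got_core = set(core.index)
        jacc = len(true_core & got_core) / len(true_core | got_core)
        report["stages"]["community"] = {
            "n_samples": len(table.samples),
            "core_size": len(got_core),
            "core_jaccard_vs_truth": jacc,
            "min_core_occupancy": float(core["occupancy"].min()),
        }
    except Exception as exc:
        raise PipelineError("community", exc) from exc

    # ---------------- assembly ----------------
    stage_dir = out / "assembly"
    stage_dir.mkdir(exist_ok=True)
    try:
        asc = conf["assembly"]
        fractions = partition_processes(
            table,
            asv_tree,
            n_null=int(asc["n_null"]),
            min_bin=int(asc["min_bin"]),
            seed=seeds["assembly"],
        )
        fractions.to_csv(stage_dir / "process_fractions.csv", index_label="group")
        report["stages"]["assembly"] = {
            g: {p: float(v) for p, v in row.items()}
            for g, row in fractions.iterrows()
        }
    except Exception as exc:
        raise PipelineError("assembly", exc) from exc

    # ---------------- stats ----------------
    stage_dir = out / "stats"
    stage_dir.mkdir(exist_ok=True)
    try:
        sc = conf["stats"]
        raft_meta = table.metadata[table.metadata["status"] == STATUS_RAFT]
        raft_ids2 = list(raft_meta.index)
        raft_bc = bray_curtis(table.select(raft_ids2))
        sample_data = raft_meta[["raft_time", "sst", "sigma_sst"]]
        pairs = build_site_pairs(sample_data, raft_bc.data)
        gdm = fit_gdm(pairs)
        importance, pvals = gdm_importance(
            pairs=pairs, fit=gdm, n_perm=int(sc["n_perm"]), seed=seeds["stats"]
        )
        pd.DataFrame({"importance": importance, "p": pvals}).to_csv(
            stage_dir / "gdm_importance.csv", index_label="predictor"
        )
        for pred in pairs.predictors:
            gdm.spline_curve(pred).to_csv(stage_dir / f"gdm_spline_{pred}.csv", index=False)

        glm_data = alpha.join(table.metadata)
        glm_data = glm_data[np.isfinite(glm_data["sigma_sst"])]
        fit_rich = fit_smooth_glm(
            glm_data, "richness", ["sigma_sst"], ["status"], family="negative_binomial"
        )
        grid = np.linspace(
            glm_data["sigma_sst"].min(), glm_data["sigma_sst"].max(), 80
        )
        curve = fit_rich.predict_term("sigma_sst", grid)
        pd.DataFrame({"sigma_sst": grid, "effect": curve}).to_csv(
            stage_dir / "richness_smooth.csv", index=False
        )

        # drifter-window sigma vs modelled static-point sigma (paired)
        drift_sig, model_sig = [], []
        for tr in drifters:
            try:
                w = match_drifter_window(tr, fields["sst"])
                s = static_point_stats(
                    fields["sst"], tr.lats[-1], tr.lons[-1], tr.times[-1]
                )
            except Exception:
                continue
            drift_sig.append(w.sigma_sst)
            model_sig.append(s.sigma_sst)
        tost = (
            tost_paired(drift_sig, model_sig, bound_d=float(sc["tost_bound"]))
            if len(drift_sig) >= 3
            else None
        )

        z, wp = wilcoxon_z(
            dys[raft_meta.index].to_numpy(),
            dys[table.metadata.index[table.metadata["status"] == STATUS_NON_RAFT]].to_numpy(),
        )
        tt, tdf, tp = welch_t(
            trait_vals[raft_meta.index].dropna().to_numpy(),
            trait_vals[
                table.metadata.index[table.metadata["status"] == STATUS_NON_RAFT]
            ].dropna().to_numpy(),
        )
        report["stages"]["stats"] = {
            "gdm_deviance_explained": gdm.deviance_explained,
            "gdm_importance": importance.to_dict(),
            "hump_peak_estimate": float(grid[np.argmax(curve)]),
            "hump_peak_truth": cfg.ish_peak,
            "tost_p": tost.p if tost else None,
            "dysbiosis_wilcoxon_z": z,
            "dysbiosis_wilcoxon_p": wp,
            "trait_welch_t": tt,
            "trait_welch_p": tp,
        }
    except Exception as exc:
        raise PipelineError("stats", exc) from exc

    dio.write_json(report, out / "report.json")  # deterministic content only
    report = dict(report, runtime_seconds=round(time.time() - t0, 1))
    return report
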