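"""End-to-end orchestration of the landscape-genetics analysis.

``run(config)`` executes the stages in order — synthetic data, ensemble
SDM, range shift, connectivity, diversity statistics plus persistence
projection, Mantel tests, climate-covariate admixture with projection
and turnover, and the genetic-landscape GAM — writing every artifact
into a run directory with a manifest (config echo, per-stage seeds,
durations). One global seed is split into independent per-stage seeds
with ``numpy.random.SeedSequence`` spawn keys, so any stage is
reproducible in isolation.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import admixture, connectivity, landscape, mantel, popgen, sdm
from .raster import average_gcm_stacks  # re-exported convenience  # noqa: F401
from .synthetic import (
    SyntheticScenario,
    generate_climate_stack,
    generate_occurrences,
    generate_populations_and_genotypes,
)

__all__ = ["PipelineConfig", "run", "stage_seed"]

_STAGES = (
    "data", "sdm", "rangeshift", "connectivity", "popgen", "mantel",
    "admixture", "landscape",
)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(global_seed, spawn_key=(_STAGES.index(stage),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Everything one synthetic end-to-end run needs.

    Unknown keys in ``from_dict`` are rejected so configuration typos
    fail before any stage runs.
    """

    seed: int = 0
    out_dir: str = "landgen_run"
    scenario: dict = field(default_factory=dict)  # SyntheticScenario overrides
    n_occurrences: int = 200
    occurrence_beta: list | None = None           # logistic truth; default built
    rarefy_km: float = 5.0
    prune_r_max: float = 0.75
    pa_ratio: float = 1.0
    ensemble: dict = field(default_factory=dict)  # EnsembleConfig overrides
    min_n: int = 5
    mantel_permutations: int = 999
    admix_k_values: tuple[int, ...] = (1, 2, 3, 4)
    admix_sweeps: int = 2000
    admix_burn_in: int = 200
    admix_covariates: int = 3
    idw_power: float = 2.0
    idw_neighbors: int = 12
    gam_df: int = 10
    gam_max_cells: int = 2000
    stages: tuple[str, ...] = _STAGES

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def validate(self) -> None:
        for s in self.stages:
            if s not in _STAGES:
                raise ValueError(f"unknown stage {s!r}")
        if self.pa_ratio <= 0 or self.n_occurrences < 10:
            raise ValueError("invalid sampling configuration")


def run(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns a results dict and writes
    artifacts + ``manifest.json`` under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest: dict = {"seed": config.seed, "stages": {}, "stage_seeds": {}}

    def record(stage: str, t0: float, **info) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3), **info}

    # ---- data ------------------------------------------------------------
    t0 = time.time()
    sc_kwargs = dict(config.scenario)
    sc_kwargs.setdefault("seed", stage_seed(config.seed, "data"))
    scenario = SyntheticScenario(**sc_kwargs)
    current_stack, future_stack = generate_climate_stack(scenario)
    beta = config.occurrence_beta
    if beta is None:
        # restricted-range species under strong control of the first two
        # climate axes (negative intercept keeps prevalence moderate)
        beta = [-2.0] + [0.0] * current_stack.n_layers
        beta[1], beta[2] = 3.0, -2.0
    beta = np.asarray(beta, dtype=float)
    occ, true_suit = generate_occurrences(
        current_stack, beta, config.n_occurrences,
        seed=stage_seed(config.seed, "data") + 1,
    )
    pops, gt, haps, Q_true = generate_populations_and_genotypes(
        scenario, current_stack
    )
    pops.to_csv(out / "populations.csv")
    occ.to_csv(out / "occurrences.csv")
    gt.to_genalex_csv(out / "genotypes.csv")
    haps.to_fasta(out / "haplotypes.fasta")
    results["data"] = {
        "scenario": scenario, "current_stack": current_stack,
        "future_stack": future_stack, "occurrences": occ,
        "true_suitability": true_suit, "pops": pops, "genotypes": gt,
        "haplotypes": haps, "Q_true": Q_true,
    }
    record("data", t0, n_occurrences=len(occ), n_pops=len(pops))

    # ---- SDM -------------------------------------------------------------
    if "sdm" in config.stages:
        t0 = time.time()
        seed = stage_seed(config.seed, "sdm")
        pruned, kept = sdm.prune_correlated_variables(
            current_stack, config.prune_r_max
        )
        rare = sdm.rarefy_occurrences(occ, config.rarefy_km)
        if len(rare) < 10:
            rare = occ  # tiny synthetic grids can over-rarefy
        n_pa = max(int(round(config.pa_ratio * len(rare))), 10)
        pas = sdm.sample_pseudo_absences(pruned, rare, n_pa, seed=seed)
        ens_cfg = sdm.EnsembleConfig(seed=seed, **config.ensemble)
        models, evals = sdm.fit_ensemble(rare, pas, pruned, ens_cfg)
        suit_cur = sdm.ensemble_predict(models, evals, pruned, "current")
        future_pruned = future_stack.subset(kept)
        suit_fut = sdm.ensemble_predict(models, evals, future_pruned, "future")
        lpt = sdm.lpt_threshold(suit_cur, rare)
        bin_cur = sdm.binarize(suit_cur, lpt)
        bin_fut = sdm.binarize(suit_fut, lpt)
        results["sdm"] = {
            "kept_layers": kept, "rarefied": rare, "pseudo_absences": pas,
            "models": models, "evaluations": evals, "suit_current": bin_cur,
            "suit_future": bin_fut, "lpt": lpt,
        }
        ev = [asdict(e) for e in evals]
        (out / "evaluations.json").write_text(json.dumps(ev, indent=1))
        record("sdm", t0, lpt=lpt,
               n_retained=int(sum(e.retained for e in evals)))

    # ---- range shift -----------------------------------------------------
    if "rangeshift" in config.stages and "sdm" in results:
        t0 = time.time()
        shift = sdm.range_shift(results["sdm"]["suit_current"],
                                results["sdm"]["suit_future"])
        results["rangeshift"] = shift
        (out / "range_shift.json").write_text(json.dumps({
            "area_km2": shift.area_km2,
            "current_area_km2": shift.current_area_km2,
            "future_area_km2": shift.future_area_km2,
            "percent_change": shift.percent_change,
        }, indent=1))
        record("rangeshift", t0, percent_change=shift.percent_change)

    # ---- connectivity ----------------------------------------------------
    if "connectivity" in config.stages and "sdm" in results:
        t0 = time.time()
        friction = connectivity.friction_from_suitability(
            results["sdm"]["suit_current"]
        )
        R = connectivity.resistance_matrix(pops, friction)
        links = connectivity.shared_haplotype_links(haps)
        net_all = connectivity.build_network(pops, friction, links, "all-pairs")
        net_shared = connectivity.build_network(
            pops, friction, links, "shared-haplotype"
        )
        results["connectivity"] = {
            "friction": friction, "resistance": R, "links": links,
            "network_all": net_all, "network_shared": net_shared,
        }
        mantel.write_distance_csv(out / "resistance.csv", R, pops.ids)
        net_all.edge_dataframe().to_csv(out / "network_all_pairs.csv", index=False)
        net_shared.edge_dataframe().to_csv(out / "network_shared.csv", index=False)
        record("connectivity", t0, n_shared_links=len(links))

    # ---- popgen ----------------------------------------------------------
    if "popgen" in config.stages:
        t0 = time.time()
        table = popgen.diversity_table(gt, haps)
        table_f = popgen.filter_min_n(table, config.min_n)
        F, labels = popgen.pairwise_fst(gt)
        lin = popgen.linearize_fst(F)
        proj = None
        if "sdm" in results:
            proj = popgen.project_future_diversity(
                gt, haps, pops, results["sdm"]["suit_future"],
                results["sdm"]["lpt"],
            )
            proj.table.to_csv(out / "diversity_projected.csv", index=False)
        results["popgen"] = {
            "table": table, "table_filtered": table_f, "fst": F,
            "fst_labels": labels, "fst_linearized": lin, "projection": proj,
        }
        table.to_csv(out / "diversity.csv", index=False)
        mantel.write_distance_csv(out / "fst_linearized.csv", lin, labels)
        record("popgen", t0, n_pops_reported=len(table_f))

    # ---- Mantel ----------------------------------------------------------
    if "mantel" in config.stages and "connectivity" in results and "popgen" in results:
        t0 = time.time()
        seed = stage_seed(config.seed, "mantel")
        G = results["popgen"]["fst_linearized"]
        R = results["connectivity"]["resistance"]
        E, _ = mantel.geographic_distance_matrix(pops)
        r_gr, p_gr = mantel.mantel(G, R, config.mantel_permutations, seed)
        r_ge, p_ge = mantel.mantel(G, E, config.mantel_permutations, seed + 1)
        r_part, p_part = mantel.partial_mantel(
            G, R, E, config.mantel_permutations, seed + 2
        )
        results["mantel"] = {
            "resistance": {"r": r_gr, "p": p_gr},
            "euclidean": {"r": r_ge, "p": p_ge},
            "partial_resistance_given_euclidean": {"r": r_part, "p": p_part},
        }
        (out / "mantel.json").write_text(json.dumps(results["mantel"], indent=1))
        record("mantel", t0, r_resistance=r_gr)

    # ---- admixture -------------------------------------------------------
    if "admixture" in config.stages:
        t0 = time.time()
        seed = stage_seed(config.seed, "admixture")
        cov, cov_names = admixture.select_covariates(
            current_stack, pops, config.admix_covariates
        )
        ind_pop = np.array([pops.ids.index(p) for p in gt.populations])
        cov_ind = cov[ind_pop]
        coords_ind = pops.coords()[ind_pop]
        loci = admixture.encode_genotypes(gt)
        fits = [
            admixture.fit(
                loci, coords_ind, cov_ind, K_max=k,
                sweeps=config.admix_sweeps, burn_in=config.admix_burn_in,
                seed=seed + k, covariate_names=cov_names,
            )
            for k in config.admix_k_values
        ]
        best, dic_table = admixture.select_runs(fits)
        fut_cov = future_stack.subset(cov_names).values_at_points(
            coords_ind[:, 0], coords_ind[:, 1]
        )
        Q_proj = admixture.project(best, fut_cov, coords_ind)
        Q_reg = admixture.regression_ancestry(best, cov_ind, coords_ind)
        report = admixture.turnover(Q_reg, Q_proj)
        results["admixture"] = {
            "fits": fits, "best": best, "dic_table": dic_table,
            "covariates": cov_names, "Q_projected": Q_proj,
            "turnover": report,
        }
        dic_table.to_csv(out / "dic_table.csv", index=False)
        np.savetxt(out / "Q_matrix.csv", best.Q, delimiter=",")
        (out / "turnover.json").write_text(json.dumps({
            "overall_r": report.overall_r,
            "per_cluster_r": report.per_cluster_r.tolist(),
            "lost_clusters": report.lost_clusters,
            "threshold": report.threshold,
        }, indent=1))
        record("admixture", t0, best_K=best.K, dic=best.dic)

    # ---- genetic landscape ----------------------------------------------
    if "landscape" in config.stages and "popgen" in results and "sdm" in results:
        t0 = time.time()
        seed = stage_seed(config.seed, "landscape")
        lin = results["popgen"]["fst_linearized"]
        samples = landscape.midpoint_distances(pops, lin)
        grid = current_stack.grid
        surface = landscape.idw_interpolate(
            samples, grid, power=config.idw_power,
            k_neighbors=config.idw_neighbors,
        )
        change = landscape.suitability_change(
            results["sdm"]["suit_current"], results["sdm"]["suit_future"]
        )
        reg = landscape.stability_gam(
            surface, change, grid, df=config.gam_df,
            max_cells=config.gam_max_cells, seed=seed,
            threshold=results["sdm"]["lpt"],
        )
        results["landscape"] = {"samples": samples, "surface": surface,
                                "change": change, "regression": reg}
        (out / "gam.json").write_text(json.dumps({
            "r2": reg.r2, "p_value": reg.p_value, "n": reg.n,
            "threshold": reg.threshold,
            "sign_convention": reg.sign_convention,
        }, indent=1))
        record("landscape", t0, r2=reg.r2)

    for stage in _STAGES:
        manifest["stage_seeds"][stage] = stage_seed(config.seed, stage)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    results["manifest"] = manifest
    return results
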