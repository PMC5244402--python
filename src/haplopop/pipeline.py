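"""One-shot orchestration of every analysis stage with reproducible seeding.

``run_all`` executes the stages in the order mating types -> diversity ->
linkage -> AMOVA / pairwise F_ST -> DAPC -> spatial (IBD, SAShA, GRA),
writes each stage's CSV outputs plus a consolidated ``report.json`` and a
``run.log``.  A single global seed is turned into per-stage substreams by
hashing the stage name, so re-running a stage in isolation reproduces its
in-pipeline result regardless of execution order, and identical config +
seed gives a byte-identical report.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import io
from .amova import amova, pairwise_fst
from .core import GenotypeDataset, MatTable, SitesTable, allele_frequencies
from .dapc import dapc, one_hot_impute
from .diversity import diversity_table
from .linkage import linkage_table
from .mating import heterothallism_check, mat_ratio_tests
from .simulate import SimulationConfig, simulate
from .spatial import (distance_pair_kde, edwards_distance, geo_distance_matrix,
                      mantel_ibd, sasha_gra)

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Inputs plus per-stage parameters for a full pipeline run."""

    output_dir: str = "haplopop_out"
    seed: int = 0
    genotypes_path: Optional[str] = None
    sites_path: Optional[str] = None
    mat_path: Optional[str] = None
    simulate: Optional[SimulationConfig] = None
    g_population: Optional[int] = None
    g_region: Optional[int] = None
    n_perm_linkage: int = 999
    n_perm_amova: int = 20000
    n_perm_fst: int = 999
    n_perm_mantel: int = 999
    n_perm_sasha: int = 1000
    n_boot_gra: int = 1000
    k_max: int = 8
    n_pca: Optional[int] = None
    kde_grid: int = 100

    def validate(self) -> None:
        if self.simulate is None and self.genotypes_path is None:
            raise ValueError("need either input paths or a simulate block")
        if self.simulate is None and self.sites_path is None:
            raise ValueError("sites table required for spatial stages")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream below 2**31."""
    return (seed * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


def _round_floats(obj):
    if isinstance(obj, float):
        return float(f"{obj:.10g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_all(config: RunConfig) -> Dict:
    """Execute every stage; stage failures are recorded and do not stop
    independent stages.  Returns the report dict (also written as JSON)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger = logging.getLogger("haplopop.run")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)

    report: Dict = {"schema_version": REPORT_SCHEMA_VERSION, "seed": config.seed,
                    "stages": {}, "errors": {}}

    def run_stage(name, fn):
        t0 = time.time()
        try:
            result = fn()
            report["stages"][name] = result
            logger.info("stage %s ok (%.2fs)", name, time.time() - t0)
        except Exception as exc:  # record and continue
            report["errors"][name] = f"{type(exc).__name__}: {exc}"
            logger.error("stage %s failed: %s", name, exc)

    # ---- inputs -----------------------------------------------------
    if config.simulate is not None:
        data, sites, mat, truth = simulate(config.simulate)
        io.write_genotypes(data, out / "genotypes.csv")
        io.write_sites(sites, out / "sites.csv")
        io.write_mat(mat, out / "mat.csv")
        truth.to_json(out / "truth.json")
        report["input"] = {"source": "simulated", "seed": config.simulate.seed}
    else:
        sites = io.read_sites(config.sites_path)
        data = io.read_genotypes(config.genotypes_path, sites=sites)
        mat = io.read_mat(config.mat_path) if config.mat_path else None
        report["input"] = {"source": str(config.genotypes_path)}
    report["input"].update({"n_samples": data.n_samples, "n_loci": data.n_loci,
                            "n_populations": len(data.populations),
                            "n_regions": len(data.regions)})

    # ---- mating types ----------------------------------------------
    if mat is not None:
        def _mat():
            tests = mat_ratio_tests(mat, data)
            tests.to_csv(out / "mat_tests.csv", index=False)
            het = heterothallism_check(mat)
            overall = tests[tests["population"] == "overall"].iloc[0]
            return {"overall_n1": int(overall["n1"]), "overall_n2": int(overall["n2"]),
                    "overall_chi2": float(overall["chi2"]),
                    "overall_p_chi2": float(overall["p_chi2"]),
                    "amplification_success": het.success_fraction,
                    "heterothallism_violations": len(het.violations)}
        run_stage("mat", _mat)

    # ---- diversity ---------------------------------------------------
    def _diversity():
        table = diversity_table(data, config.g_population, config.g_region)
        table.to_csv(out / "diversity.csv", index=False)
        pops = table[table["level"] == "population"]
        regs = table[table["level"] == "region"]
        return {"uh_mean_over_pops": float(pops["uh_mean"].mean()),
                "g_population": int(pops["g"].iloc[0]),
                "g_region": int(regs["g"].iloc[0]),
                "AR_by_region": dict(zip(regs["stratum"], regs["AR_mean"].astype(float))),
                "PAR_by_region": dict(zip(regs["stratum"], regs["PAR_mean"].astype(float))),
                "AR_mean_over_pops": float(pops["AR_mean"].mean())}
    run_stage("diversity", _diversity)

    # ---- linkage -----------------------------------------------------
    def _linkage():
        table = linkage_table(data, n_perm=config.n_perm_linkage,
                              seed=stage_seed(config.seed, "linkage"))
        table.to_csv(out / "linkage.csv", index=False)
        return {"n_mlg_total": int(table["n_MLG"].sum()),
                "rbar_d_by_pop": dict(zip(table["population"],
                                          [None if pd.isna(v) else float(v)
                                           for v in table["rBarD"]])),
                "n_perm": config.n_perm_linkage}
    run_stage("linkage", _linkage)

    # ---- AMOVA / F_ST ------------------------------------------------
    def _amova():
        res = amova(data, n_perm=config.n_perm_amova,
                    seed=stage_seed(config.seed, "amova"))
        res.table.to_csv(out / "amova.csv", index=False)
        return {"df": [int(v) for v in res.table["df"]],
                "SS": [float(v) for v in res.table["SS"]],
                "sigma2": [float(v) for v in res.table["sigma2"]],
                "pct": [float(v) for v in res.table["pct"]],
                "phi": {k: (None if not np.isfinite(v) else float(v))
                        for k, v in res.phi.items()},
                "p": res.p, "n_perm": res.n_perm}
    run_stage("amova", _amova)

    def _fst():
        res = pairwise_fst(data, n_perm=config.n_perm_fst,
                           seed=stage_seed(config.seed, "fst"))
        res.fst.to_csv(out / "fst_matrix.csv")
        res.pvalues.to_csv(out / "fst_pvalues.csv")
        vals = res.fst.values[np.triu_indices(len(res.fst), k=1)]
        vals = vals[np.isfinite(vals)]
        return {"max_fst": float(vals.max()), "mean_fst": float(vals.mean()),
                "n_perm": res.n_perm}
    run_stage("fst", _fst)

    # ---- DAPC --------------------------------------------------------
    def _dapc():
        X = one_hot_impute(data)
        res = dapc(X, k_max=config.k_max, n_pca=config.n_pca,
                   seed=stage_seed(config.seed, "dapc"), data=data)
        pd.DataFrame({"K": list(res.bic_by_k), "BIC": list(res.bic_by_k.values())}
                     ).to_csv(out / "dapc_bic.csv", index=False)
        if res.memberships is not None:
            pd.DataFrame(res.memberships, index=data.sample_ids,
                         columns=[f"cluster_{i + 1}" for i in
                                  range(res.memberships.shape[1])]
                         ).to_csv(out / "dapc_memberships.csv")
            pd.DataFrame(res.discriminant_coords, index=data.sample_ids
                         ).to_csv(out / "dapc_coords.csv")
        if res.cluster_by_population is not None:
            res.cluster_by_population.to_csv(out / "cluster_by_population.csv")
        return {"k_opt": int(res.k_opt), "n_pca": int(res.n_pca_retained),
                "bic_by_k": {str(k): float(v) for k, v in res.bic_by_k.items()},
                "min_membership_max": (None if res.memberships is None else
                                       float(res.memberships.max(axis=1).min()))}
    run_stage("dapc", _dapc)

    # ---- spatial -----------------------------------------------------
    def _ibd():
        freqs = allele_frequencies(data)
        gen = edwards_distance(freqs)
        geo = geo_distance_matrix(sites, data.populations)
        pairs = []
        pops = data.populations
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                pairs.append({"pop1": pops[i], "pop2": pops[j],
                              "gen_dist": gen.iloc[i, j], "geo_km": geo.iloc[i, j]})
        pd.DataFrame(pairs).to_csv(out / "ibd.csv", index=False)
        res = mantel_ibd(gen, geo, n_perm=config.n_perm_mantel,
                         seed=stage_seed(config.seed, "mantel"))
        (out / "mantel.txt").write_text(
            f"mantel_r\t{res.r:.6f}\np\t{res.p_perm}\nn_perm\t{res.n_perm}\n")
        kde = distance_pair_kde(gen, geo, grid=config.kde_grid)
        grid_df = pd.DataFrame(kde.density,
                               index=pd.Index(kde.y, name="genetic"),
                               columns=pd.Index(kde.x, name="geo_km"))
        grid_df.to_csv(out / "kde_grid.csv")
        return {"mantel_r": float(res.r), "mantel_p": res.p_perm,
                "n_perm": res.n_perm,
                "kde_bandwidths": [kde.bandwidth_x, kde.bandwidth_y]}
    run_stage("ibd", _ibd)

    def _sasha_gra():
        overall, gra = sasha_gra(data, sites, n_perm=config.n_perm_sasha,
                                 n_boot=config.n_boot_gra,
                                 seed=stage_seed(config.seed, "sasha"))
        gra.table.to_csv(out / "gra.csv", index=False)
        rows = [{"subset": "all", "observed_mean_km": overall.observed_mean_km,
                 "expected_mean_km": overall.expected_mean_km,
                 "p": overall.p_perm}]
        result = {"observed_mean_km": overall.observed_mean_km,
                  "expected_mean_km": overall.expected_mean_km,
                  "p": overall.p_perm, "n_perm": overall.n_perm,
                  "n_alleles": gra.n_alleles, "n_restricted": gra.n_restricted,
                  "pct_restricted": gra.pct_restricted, "n_boot": gra.n_boot}
        if gra.restricted_sasha is not None:
            rs = gra.restricted_sasha
            rows.append({"subset": "restricted",
                         "observed_mean_km": rs.observed_mean_km,
                         "expected_mean_km": rs.expected_mean_km, "p": rs.p_perm})
            result["restricted_observed_mean_km"] = rs.observed_mean_km
            result["restricted_expected_mean_km"] = rs.expected_mean_km
            result["restricted_p"] = rs.p_perm
        pd.DataFrame(rows).to_csv(out / "sasha_summary.csv", index=False)
        return result
    run_stage("sasha", _sasha_gra)

    report = _round_floats(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    handler.close()
    logger.removeHandler(handler)
    return report
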