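"""End-to-end orchestration: simulate/load -> code -> filter -> 84 REML
triples -> combine -> bend -> BLUP -> parity aggregation -> DHL.

Every stage writes its outputs under the configured directory and is
skipped on re-run when its outputs already exist, so a run can be resumed
and individual cached triple runs can be invalidated by deleting their
files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .aggregation import aggregate, parity_incidence, whole_life_incidence
from .covariance import CovarianceSet
from .datasets import TRAITS
from .dhl import DHLConfig, compute_dhl, ebv_correlations, mean_survival_rates
from .mixed_model import ModelSpec, build_mme, solve_blup
from .multirun import (
    RunResult, assemble_G0, assemble_P0, bend, combine_runs, enumerate_triples,
)
from .reml import SpectralWorkspace, reml_estimate
from .simulate import SimulationConfig, simulate_dataset
from .survival import apply_filters, code_survival

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    output_dir: str
    simulation: SimulationConfig | None = None
    records_paths: tuple[str, str, str] | None = None  # cows, lactations, tests
    pedigree_path: str | None = None
    min_hy: int = 5
    reml_method: str = "auto"
    reml_tol: float = 1e-8
    reml_max_iter: int = 200
    reml_ll_tol: float = 1e-6
    bending_floor: float = 1e-5
    incidence: str = "parity"  # or "whole_life"
    min_daughters: int = 50
    min_reliability: float = 0.90
    seed: int = 1


def _stage_done(*paths: Path) -> bool:
    return all(p.exists() for p in paths)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages, reusing cached outputs; returns the run report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "seed": config.seed}

    # ---- data: simulate or load -------------------------------------------
    ped_path = out / "pedigree.csv"
    paths = {k: out / f"{k}.csv" for k in ("cows", "lactations", "tests")}
    if config.simulation is not None:
        if not _stage_done(ped_path, *paths.values()):
            ds = simulate_dataset(config.simulation)
            hio.write_pedigree(ds.pedigree, ped_path)
            if ds.records is None:  # gaussian mode: table is the data
                hio.write_survival_table(ds.table, out / "survival.csv")
                for p in paths.values():
                    p.write_text("")  # placeholders: no raw records in gaussian mode
            else:
                hio.write_records(ds.records, paths["cows"], paths["lactations"], paths["tests"])
            report["stages"]["simulate"] = {"cached": False, "n_animals": ds.pedigree.n}
        else:
            report["stages"]["simulate"] = {"cached": True}
        pedigree = hio.read_pedigree(ped_path)
    else:
        if config.records_paths is None or config.pedigree_path is None:
            raise ValueError("either simulation or records/pedigree paths are required")
        pedigree = hio.read_pedigree(config.pedigree_path)
        paths = dict(zip(("cows", "lactations", "tests"), map(Path, config.records_paths)))

    # ---- survival coding ---------------------------------------------------
    surv_path = out / "survival.csv"
    if not _stage_done(surv_path):
        records = hio.read_records(paths["cows"], paths["lactations"], paths["tests"])
        table = code_survival(records)
        hio.write_survival_table(table, surv_path)
        report["stages"]["code"] = {"cached": False, "n_cows": len(table)}
    else:
        report["stages"]["code"] = {"cached": True}
    table = hio.read_survival_table(surv_path)
    n_censored = int(table.data["censored"].sum())
    report["records"] = {
        "n_total": len(table),
        "n_censored": n_censored,
        "n_uncensored": len(table) - n_censored,
    }

    # ---- filters -----------------------------------------------------------
    filt_path = out / "filtered.csv"
    filt_report_path = out / "filter_report.json"
    if not _stage_done(filt_path, filt_report_path):
        filtered, freport = apply_filters(table, pedigree, min_hy=config.min_hy)
        hio.write_survival_table(filtered, filt_path)
        filt_report_path.write_text(json.dumps(asdict(freport), indent=1))
        report["stages"]["filter"] = {"cached": False}
    else:
        report["stages"]["filter"] = {"cached": True}
    filtered = hio.read_survival_table(filt_path)
    report["filter"] = json.loads(filt_report_path.read_text())

    # ---- three-trait REML runs --------------------------------------------
    runs_dir = out / "runs"
    runs_dir.mkdir(exist_ok=True)
    triples = enumerate_triples(len(TRAITS))
    complete = not filtered.data[list(TRAITS)].isna().any().any()
    workspace = None
    if complete:
        workspace = SpectralWorkspace(pedigree, filtered.data, TRAITS)
    runs: list[RunResult] = []
    n_recomputed = 0
    for triple in triples:
        names = tuple(TRAITS[k] for k in triple)
        fpath = runs_dir / ("run_" + "_".join(str(k) for k in triple) + ".csv")
        flag_path = Path(str(fpath) + ".flag")
        if fpath.exists() and flag_path.exists():
            df = pd.read_csv(fpath, index_col=0)
            t = len(names)
            G = df.iloc[:t].to_numpy()
            R = df.iloc[t: 2 * t].to_numpy()
            converged = flag_path.read_text().strip() == "1"
            runs.append(RunResult(names, CovarianceSet(G=G, R=R, traits=names), converged))
            continue
        cov, rep = reml_estimate(
            filtered, pedigree, names, method=config.reml_method,
            tol=config.reml_tol, max_iter=config.reml_max_iter,
            ll_tol=config.reml_ll_tol, workspace=workspace,
        )
        n_recomputed += 1
        stacked = pd.DataFrame(
            np.vstack([cov.G, cov.R]),
            index=[f"G_{t}" for t in names] + [f"R_{t}" for t in names],
            columns=list(names),
        )
        stacked.to_csv(fpath)
        Path(str(fpath) + ".flag").write_text("1" if rep.converged else "0")
        runs.append(RunResult(names, cov, rep.converged))
    n_conv = sum(r.converged for r in runs)
    report["stages"]["reml"] = {
        "n_triples": len(triples), "n_converged": n_conv, "n_recomputed": n_recomputed,
    }

    # ---- combine, assemble, bend ------------------------------------------
    combine_files = [out / f for f in ("combined_traits.csv", "combined_pairs.csv",
                                       "g0.csv", "p0.csv", "g_bent.csv",
                                       "r_bent.csv", "bend_report.json")]
    if not _stage_done(*combine_files):
        est = combine_runs(runs, TRAITS)
        est.traits.to_csv(out / "combined_traits.csv")
        est.pairs.to_csv(out / "combined_pairs.csv")
        G0 = assemble_G0(est)
        P0 = assemble_P0(est)
        bend_G = bend(G0, floor=config.bending_floor)
        R0 = P0 - bend_G.G_bent
        bend_R = bend(R0, floor=config.bending_floor)
        hio.write_matrix(G0, out / "g0.csv", TRAITS)
        hio.write_matrix(P0, out / "p0.csv", TRAITS)
        hio.write_matrix(bend_G.G_bent, out / "g_bent.csv", TRAITS)
        hio.write_matrix(bend_R.G_bent, out / "r_bent.csv", TRAITS)
        (out / "bend_report.json").write_text(json.dumps({
            "n_floored": bend_G.n_floored,
            "max_change": bend_G.max_change,
            "min_eigenvalue_before": float(np.min(bend_G.eigenvalues)),
        }, indent=1))
    G0 = hio.read_matrix(out / "g0.csv").to_numpy()
    P0 = hio.read_matrix(out / "p0.csv").to_numpy()
    G_bent = hio.read_matrix(out / "g_bent.csv").to_numpy()
    R_bent = hio.read_matrix(out / "r_bent.csv").to_numpy()
    report["stages"]["bend"] = json.loads((out / "bend_report.json").read_text())

    # ---- BLUP --------------------------------------------------------------
    ebv_path = out / "ebv.csv"
    rel_path = out / "reliability.csv"
    sires = pedigree.data.loc[pedigree.data["animal"].isin(
        set(pedigree.data["sire"]) - {0}
    ), "animal"]
    daughters = pedigree.data["sire"].value_counts()
    if not _stage_done(ebv_path, rel_path):
        cov9 = CovarianceSet(G=G_bent, R=R_bent, traits=TRAITS)
        spec = ModelSpec(traits=TRAITS)
        system = build_mme(table, pedigree, spec, cov9)
        sol = solve_blup(system, pev_animals=list(sires), pedigree=pedigree)
        sol.ebv.to_csv(ebv_path)
        sol.reliability.to_csv(rel_path)
        report["stages"]["blup"] = {"cached": False, "residual_norm": sol.residual_norm}
    else:
        report["stages"]["blup"] = {"cached": True}
    ebv = pd.read_csv(ebv_path, index_col=0)
    reliability = pd.read_csv(rel_path, index_col=0)

    # ---- parity aggregation ------------------------------------------------
    W = parity_incidence() if config.incidence == "parity" else whole_life_incidence()
    agg = aggregate(G0, P0, W)
    labels = ["parity1", "parity2", "parity3"] if config.incidence == "parity" else ["all"]
    if not _stage_done(out / "parity_summary.csv"):
        agg.summary(labels).to_csv(out / "parity_summary.csv")
    report["aggregation"] = {
        "heritability": [float(h) for h in agg.heritability],
        "genetic_correlations": np.round(agg.genetic_correlations, 4).tolist(),
    }

    # ---- DHL ---------------------------------------------------------------
    M = filtered.trait_matrix()
    binary = bool(np.isin(M[~np.isnan(M)], (0.0, 1.0)).all())
    if binary:
        mu = mean_survival_rates(filtered)
    elif config.simulation is not None:
        # continuous (liability) phenotypes carry no survival rates; use the
        # configured stage culling rates of the generating process
        mu = 1.0 - np.asarray(config.simulation.culling_rates, dtype=float)
    else:
        raise ValueError("DHL needs binary survival codes or a simulation config")
    dhl_cfg = DHLConfig(mean_survival=mu)
    sire_ebv = ebv.loc[ebv.index.isin(sires)]
    result = compute_dhl(sire_ebv, dhl_cfg)
    dhl_df = pd.DataFrame({"dhl_days": result.dhl})
    if not _stage_done(out / "dhl.csv"):
        dhl_df.to_csv(out / "dhl.csv")
    report["dhl"] = {
        "n_sires": len(dhl_df),
        "mean_days": float(result.dhl.mean()),
        "baseline_mu": [float(m) for m in mu],
    }

    # stage-EBV vs DHL correlations among well-proven sires
    corr_tab = sire_ebv.copy()
    corr_tab["DHL"] = result.dhl
    try:
        corr = ebv_correlations(
            corr_tab,
            n_daughters=daughters,
            reliability=reliability.mean(axis=1),
            min_daughters=config.min_daughters,
            min_reliability=config.min_reliability,
        )
        if not _stage_done(out / "ebv_correlations.csv"):
            corr.to_csv(out / "ebv_correlations.csv")
        report["dhl"]["corr_with_stages"] = np.round(
            corr.loc["DHL", list(TRAITS)], 3
        ).tolist()
    except ValueError as exc:
        report["dhl"]["corr_with_stages"] = f"skipped: {exc}"

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=1, default=str))
    return report
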