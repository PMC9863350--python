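"""End-to-end orchestration: spatial screening -> MET factor-analytic fits
-> selection scores -> economic index -> OCS mating plan -> genetic trends.

The pipeline consumes a pedigree CSV and a stacked plot CSV (columns
site, cycle, range, row, genotype, then one column per trait), or an
in-memory simulated archive, and writes per-stage CSV/JSON artifacts plus
a manifest recording the seed and per-stage runtimes.  Reruns with the
same inputs and seed reproduce every numeric output.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from breedgain import economic, met, ocs, scores, spatial, trends
from breedgain.pedigree import (
    RelationshipMatrix,
    build_additive_matrix,
    inbreeding_coefficients,
    load_pedigree,
)

log = logging.getLogger("breedgain.pipeline")

__all__ = ["PipelineConfig", "run_pipeline"]

REQUIRED_PLOT_COLUMNS = ["site", "cycle", "range", "row", "genotype"]


@dataclass
class PipelineConfig:
    pedigree_path: str | Path | None = None
    plots_path: str | Path | None = None
    weights_path: str | Path | None = None
    out_dir: str | Path = "breedgain_out"
    traits: list[str] = field(default_factory=lambda: ["GY"])
    seed: int = 0
    years_per_cycle: float = 2.0
    max_k: int = 2
    run_spatial_screen: bool = True
    run_ocs: bool = True
    ocs_matings: int = 20
    ocs_target_degrees: float = 45.0
    ocs_generations: int = 300
    ocs_population: int = 60


def _load_plots(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_PLOT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"plot table missing column(s): {missing}")
    return frame


def run_pipeline(
    config: PipelineConfig,
    plots: pd.DataFrame | None = None,
    pedigree_records=None,
) -> Path:
    """Run every stage in order and write artifacts to the output directory.

    Either file paths in the config or in-memory inputs may be supplied.
    A stage failure aborts with the stage name; partial outputs persist.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    stage_t0 = time.perf_counter()

    def done(stage: str):
        nonlocal stage_t0
        manifest["stages"][stage] = round(time.perf_counter() - stage_t0, 3)
        log.info("stage %s finished in %.2fs", stage, manifest["stages"][stage])
        stage_t0 = time.perf_counter()

    try:
        if plots is None:
            plots = _load_plots(config.plots_path)
        if pedigree_records is None:
            pedigree_records = load_pedigree(config.pedigree_path)
        rm = build_additive_matrix(pedigree_records)
        inbreeding_coefficients(rm).to_csv(out / "inbreeding.csv")
        done("kinship")

        if config.run_spatial_screen:
            terms = {}
            for site, sub in plots.groupby("site"):
                lay = spatial.TrialLayout.from_frame(sub)
                for trait in config.traits:
                    y = sub[trait].to_numpy(float)
                    if np.isfinite(y).sum() < 20:
                        continue
                    try:
                        fit = spatial.select_spatial_model(lay, y)
                        terms[f"{site}:{trait}"] = fit.terms
                    except (RuntimeError, np.linalg.LinAlgError, ValueError) as exc:
                        log.warning("spatial screen failed at %s/%s: %s", site, trait, exc)
            (out / "spatial_terms.json").write_text(json.dumps(terms, indent=1))
            done("spatial")

        score_frames = {}
        sel_tables = []
        site_mean_rows = []
        for trait in config.traits:
            data = met.METDataset.from_plots(plots, rm, value_col=trait)
            fit, table = met.select_optimum_model(data, max_k=config.max_k)
            table.insert(0, "trait", trait)
            sel_tables.append(table)
            if fit.k >= 1:
                fit = met.rotate_loadings(fit)
                sc = scores.selection_scores(fit)
                env = met.env_genetic_correlations(fit)
                env.to_csv(out / f"genetic_correlations_{trait}.csv")
            else:
                sc = pd.DataFrame({"PBV": met.pbv_across_env(fit)})
                sc["OP"] = np.nan
                sc["RMSD"] = 0.0
            score_frames[trait] = sc
            for site, mean in zip(fit.sites, fit.site_means):
                cyc = plots.loc[plots["site"] == site, "cycle"].iloc[0]
                site_mean_rows.append(
                    {"trait": trait, "site": site, "cycle": cyc, "site_mean": mean}
                )
        pd.concat(sel_tables, ignore_index=True).to_csv(out / "model_selection.csv",
                                                        index=False)
        all_scores = pd.concat(score_frames, axis=1)
        all_scores.to_csv(out / "selection_scores.csv")
        done("met")

        weights = (
            economic.EconomicWeights.from_file(config.weights_path)
            if config.weights_path
            else economic.EconomicWeights()
        )
        # price only the traits that were analysed
        weights.percent_weights = {
            t: w for t, w in weights.percent_weights.items() if t in config.traits
        }
        pbv = pd.DataFrame({t: score_frames[t]["PBV"] for t in config.traits})
        rmsd = score_frames["GY"]["RMSD"] if "GY" in score_frames else None
        idx_table = economic.index_table(pbv.dropna(), weights, rmsd=rmsd)
        idx_table.to_csv(out / "economic_index.csv")
        done("index")

        if config.run_ocs:
            last_cycle = int(plots["cycle"].max())
            cand_ids = sorted(
                set(plots.loc[plots["cycle"] == last_cycle, "genotype"])
                & set(idx_table.index)
            )
            sub = rm.submatrix(cand_ids)
            cand = ocs.CandidateSet(
                ids=cand_ids,
                index=idx_table.loc[cand_ids, "index_incl_rmsd"].to_numpy(),
                A=sub.a,
            )
            plan = ocs.optimize_matings(
                cand,
                ocs.OCSConfig(
                    n_matings=config.ocs_matings,
                    target_degrees=config.ocs_target_degrees,
                    population_size=config.ocs_population,
                    generations=config.ocs_generations,
                    seed=config.seed,
                ),
            )
            pd.DataFrame(plan.pairs, columns=["female", "male"]).to_csv(
                out / "mating_plan.csv", index=False
            )
            (out / "ocs_summary.json").write_text(json.dumps(plan.summary(), indent=1))
            done("ocs")

        cycle_of = plots.groupby("genotype")["cycle"].max()
        trend_rows = []
        for trait in config.traits:
            sc = score_frames[trait].dropna(subset=["PBV"])
            recs = pd.DataFrame(
                {"cycle": cycle_of.reindex(sc.index), "value": sc["PBV"]}
            ).dropna()
            if recs["cycle"].nunique() < 2:
                continue
            tr = trends.regress_over_cycles(
                recs, years_per_cycle=config.years_per_cycle
            )
            trend_rows.append(
                {
                    "trait": trait,
                    "method": "PBV",
                    "slope_per_cycle": tr.slope,
                    "slope_se": tr.slope_se,
                    "annual_gain": tr.annual_gain,
                    "p_value": tr.p_value,
                }
            )
            smr = pd.DataFrame(
                [r for r in site_mean_rows if r["trait"] == trait]
            )
            if smr["cycle"].nunique() >= 2:
                env_tr = trends.environmental_trend(smr)
                trend_rows.append(
                    {
                        "trait": trait,
                        "method": "site_mean",
                        "slope_per_cycle": env_tr.slope,
                        "slope_se": env_tr.slope_se,
                        "annual_gain": env_tr.annual_gain,
                        "p_value": env_tr.p_value,
                    }
                )
        pd.DataFrame(trend_rows).to_csv(out / "trends.csv", index=False)
        done("trends")
    except Exception as exc:
        manifest["failed_stage"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
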