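"""End-to-end run: simulate -> screen -> partition -> MERF -> contributions -> power."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import OUTCOME_COLUMNS, RunConfig
from .evaluate import (aggregate_importance, build_feature_matrix,
                       compute_directions, run_seeds)
from .io import write_tables
from .lmm import fit_global_lmm, screen_features, screen_to_frame
from .outcomes import diagnose_depression, diagnose_ptsd
from .pathways import contribution_tables
from .power import spearman_power
from .simulate import SimulationConfig, SyntheticCohort, simulate_cohort

__all__ = ["run_all", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _diagnosis_groups(cohort_data: pd.DataFrame, panel: pd.DataFrame, outcome: str,
                      week: int, ptsd_cut: int, dep_cut: float) -> pd.Series:
    """Map sample id -> diagnosis group label at the chosen week."""
    at_week = panel[panel["week"] == week].set_index("subject_id")
    if outcome == "ptsd":
        labels = at_week["pcl5_raw"].map(
            lambda v: f"PTSD raw score > {ptsd_cut}" if diagnose_ptsd(v, ptsd_cut)
            else f"PTSD raw score <= {ptsd_cut}"
        )
    elif outcome == "depression":
        labels = at_week["promis_t"].map(
            lambda v: f"Depression t-score >= {dep_cut:g}" if diagnose_depression(v, dep_cut)
            else f"Depression t-score < {dep_cut:g}"
        )
    else:
        raise ValueError(f"no diagnosis grouping defined for outcome {outcome!r}")
    by_sample = pd.Series(
        labels.reindex(cohort_data.index).to_numpy(),
        index=pd.Index(cohort_data["sample_id"].to_numpy(), name="sample_id"),
    )
    return by_sample


def run_all(config: RunConfig, cohort: SyntheticCohort | None = None) -> dict:
    """Execute every stage and write CSV outputs plus a summary JSON.

    ``cohort`` may be a pre-built data bundle; by default a synthetic
    cohort is generated from ``config.simulation``. Returns the summary
    dict (also written to ``out_dir/summary.json``).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "gutapns_version": __version__,
        "config_hash": config.content_hash(),
        "config": config.to_dict(),
        "outcomes": {},
    }

    stage = "simulate"
    try:
        if cohort is None:
            sim_cfg = SimulationConfig(**config.simulation)
            cohort = simulate_cohort(sim_cfg)
        write_tables(
            {
                "species_abundance": cohort.species,
                "pathway_abundance": cohort.pathways,
                "cohort": cohort.cohort,
                "outcome_panel": cohort.outcomes,
            },
            out_dir,
        )
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    features = build_feature_matrix(cohort.species, cohort.cohort)

    for outcome in config.outcomes:
        col = OUTCOME_COLUMNS[outcome]
        osum: dict = {}

        stage = f"screen[{outcome}]"
        try:
            screen = screen_features(cohort.outcomes, cohort.species, cohort.cohort,
                                     col, fdr_level=config.fdr_level)
            screen_df = screen_to_frame(screen)
            screen_df.to_csv(out_dir / f"screen_{outcome}.csv", index=False)
            selected = [r.feature for r in screen if r.selected]
            osum["n_selected"] = len(selected)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

        stage = f"variance_partition[{outcome}]"
        try:
            if selected:
                glm = fit_global_lmm(cohort.outcomes, cohort.species, cohort.cohort,
                                     col, selected)
                vp = glm.variance_partition()
                vp.to_frame().to_csv(out_dir / f"variance_partition_{outcome}.csv")
                osum["microbiome_share"] = vp.microbiome_share
            else:
                osum["microbiome_share"] = None
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

        stage = f"merf[{outcome}]"
        try:
            runs = run_seeds(cohort.outcomes, features, col,
                             seeds=config.seeds, **config.merf)
            metrics = pd.DataFrame(
                [{"seed": r.seed, "rmse_test": r.rmse_test,
                  "corr_test": r.corr_test, "error": r.error} for r in runs]
            )
            metrics.to_csv(out_dir / f"merf_metrics_{outcome}.csv", index=False)
            directions = compute_directions(cohort.outcomes, features, col)
            imp = aggregate_importance(runs, directions=directions)
            imp.to_csv(out_dir / f"importance_{outcome}.csv")
            ok = metrics["error"].isna()
            osum["mean_rmse_test"] = float(metrics.loc[ok, "rmse_test"].mean())
            osum["mean_corr_test"] = float(metrics.loc[ok, "corr_test"].mean())
            osum["top_feature"] = imp.index[0] if len(imp) else None
            # heatmap-ready long table: feature x outcome direction
            directions.rename("rho").reset_index().assign(outcome=outcome).to_csv(
                out_dir / f"direction_{outcome}.csv", index=False
            )
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

        if outcome in ("ptsd", "depression"):
            stage = f"contrib[{outcome}]"
            try:
                groups = _diagnosis_groups(cohort.cohort.data, cohort.outcomes,
                                           outcome, config.group_week,
                                           config.ptsd_cut, config.depression_cut)
                pids = [k.split(":", 1)[0] for k in cohort.pathways.pathway_keys]
                contrib = contribution_tables(cohort.pathways, groups,
                                              pathway_ids=pids,
                                              rank=config.contribution_rank)
                contrib.to_csv(out_dir / f"contribution_{outcome}.csv", index=False)
                osum["n_contribution_rows"] = int(len(contrib))
            except Exception as exc:
                raise PipelineError(stage, exc) from exc

        summary["outcomes"][outcome] = osum

    stage = "power"
    try:
        summary["power"] = spearman_power(rho=config.power_rho, n=config.power_n,
                                          alpha=config.power_alpha)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %s", out_dir / "summary.json")
    return summary
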