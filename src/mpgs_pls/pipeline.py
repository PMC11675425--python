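"""End-to-end analysis runs: whole sample, MDD-only, BD-only.

One run reads the score panel and phenotype table, filters to the requested
diagnostic subgroup, autoscales within that subgroup, picks the number of
PLS components by 7-fold cross-validation, fits the NIPALS model, ranks the
scores by VIP, tabulates category contributions, evaluates the first latent
variable as a classifier (in-sample and cross-validated AUC), compares
demographics between outcome groups, and writes every artifact to the
output directory.  The diagnosis covariate enters the predictor block only
in the whole-sample run; it is never part of the VIP ranking.

Scores are ranked by importance only — no per-score hypothesis tests and no
multiple-testing correction are performed; the single selection device is
the VIP > 1 rule.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import cohort_table, comparison_frame
from .datatypes import AnalysisError, PhenotypeTable, ScorePanel, align
from .evaluation import roc_first_latent, roc_from_scores
from .io import read_panel
from .pls import Design, PLSModel, autoscale, fit_model, fit_nipals, prepare
from .selection import CVResult, cross_validate, cv_report
from .vip import (
    category_summary_frame,
    compute_vip,
    rank_and_select,
    summarize_categories,
)

SUBGROUPS = ("all", "MDD", "BD")
TOP_K = 20


@dataclass
class RunConfig:
    scores_path: str | Path | None = None
    meta_path: str | Path | None = None
    phenotypes_path: str | Path | None = None
    subgroup: str = "all"
    n_folds: int = 7
    max_components: int = 5
    vip_threshold: float = 1.0
    seed: int = 0
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.subgroup not in SUBGROUPS:
            raise AnalysisError(f"subgroup must be one of {SUBGROUPS}")

    @property
    def include_diagnosis_covariate(self) -> bool:
        # the covariate is meaningful only when both diagnoses are present
        return self.subgroup == "all"


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def subset_subgroup(
    panel: ScorePanel, phenotypes: PhenotypeTable, subgroup: str
) -> tuple[ScorePanel, PhenotypeTable]:
    """Restrict both tables to one diagnostic group (no-op for 'all')."""
    phenotypes = align(panel, phenotypes)
    if subgroup == "all":
        return panel, phenotypes
    keep = phenotypes.diagnosis == subgroup
    if not keep.any():
        raise AnalysisError(f"subgroup {subgroup!r} is empty")
    ids = phenotypes.sample_ids[keep]
    sub_panel = ScorePanel(panel.scores.loc[ids], panel.meta.copy())
    return sub_panel, PhenotypeTable(phenotypes.table.loc[ids])


def cv_latent_scores(
    design: Design, n_components: int, cv: CVResult
) -> np.ndarray:
    """First-latent-variable scores for each subject from the fold that held
    it out, using fold-internally scaled refits."""
    X, y = design.X_raw, design.y_raw
    out = np.empty(len(y))
    for k in range(cv.n_folds):
        test = cv.fold_assignments == k
        train = ~test
        sd = X[train].std(axis=0, ddof=1)
        keep = sd > 0.0
        Xtr, xc, xs = autoscale(X[train][:, keep])
        ytr = (y[train] - y[train].mean()) / y[train].std(ddof=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_nipals(Xtr, ytr, n_components)
        Xte = (X[test][:, keep] - xc) / xs
        W, P = fit["W"], fit["P"]
        R = W @ np.linalg.inv(P.T @ W)
        out[test] = (Xte @ R)[:, 0]
    return out


def run_analysis(
    config: RunConfig,
    panel: ScorePanel | None = None,
    phenotypes: PhenotypeTable | None = None,
) -> dict:
    """Execute one full analysis; returns the run report (also written to
    ``config.out_dir`` when set, together with all artifact files)."""
    checksums = {}
    if panel is None or phenotypes is None:
        if not (config.scores_path and config.meta_path and config.phenotypes_path):
            raise AnalysisError("either in-memory inputs or all three paths required")
        panel, phenotypes = read_panel(
            config.scores_path, config.meta_path, config.phenotypes_path
        )
        checksums = {
            "scores": _sha256(config.scores_path),
            "score_meta": _sha256(config.meta_path),
            "phenotypes": _sha256(config.phenotypes_path),
        }

    panel, phenotypes = subset_subgroup(panel, phenotypes, config.subgroup)
    design = prepare(
        panel, phenotypes, include_diagnosis_covariate=config.include_diagnosis_covariate
    )

    cv = cross_validate(
        design.X_raw,
        design.y_raw,
        max_components=config.max_components,
        n_folds=config.n_folds,
        stratified=True,
        seed=config.seed,
    )
    model = fit_model(design, cv.selected_components)

    vip_table = compute_vip(model, panel.meta)
    ranked = rank_and_select(vip_table, threshold=config.vip_threshold)
    categories = summarize_categories(ranked, panel)

    roc_in = roc_first_latent(model, design.X_raw, design.y_raw)
    t1_cv = cv_latent_scores(design, cv.selected_components, cv)
    roc_cv = roc_from_scores(t1_cv, design.y_raw)

    demo_results, demo_skipped = cohort_table(phenotypes)

    # the per-model scalar "coefficient" is ambiguous in common reporting:
    # expose both the first-component y-loading (autoscaled) and the slope
    # of the 0/1 outcome on t1 in original units
    q1 = float(model.y_loadings[0])
    report = {
        "config": {
            "subgroup": config.subgroup,
            "n_folds": config.n_folds,
            "max_components": config.max_components,
            "vip_threshold": config.vip_threshold,
            "seed": config.seed,
            "include_diagnosis_covariate": config.include_diagnosis_covariate,
        },
        "provenance": {
            "package_version": __version__,
            "input_checksums": checksums,
        },
        "n_samples": design.n_samples,
        "n_cases": int(design.y_raw.sum()),
        "n_predictors": design.n_predictors,
        "n_ranked_predictors": int((~design.is_covariate).sum()),
        "dropped_constant_columns": design.dropped_columns,
        "cross_validation": cv_report(cv),
        "selected_components": cv.selected_components,
        "r2x": model.r2x.tolist(),
        "r2y": model.r2y.tolist(),
        "r2y_cumulative": float(model.r2y.sum()),
        "q2_selected": float(cv.q2[cv.selected_components - 1]),
        "coefficient_q1_autoscaled": q1,
        "coefficient_slope_original": q1 * model.y_scale,
        "nipals_iterations": model.n_iterations,
        "n_selected_vip": int(ranked["selected"].sum()),
        "top_contributors": ranked.head(TOP_K).to_dict(orient="records"),
        "category_summary": category_summary_frame(categories).to_dict(
            orient="records"
        ),
        "auc_in_sample": roc_in.auc,
        "auc_cv": roc_cv.auc,
        "cohort_comparisons": comparison_frame(demo_results).to_dict(orient="records"),
        "cohort_variables_skipped_constant": demo_skipped,
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ranked.to_csv(out / "vip_ranking.tsv", sep="\t", index=False)
        category_summary_frame(categories).to_csv(
            out / "category_summary.tsv", sep="\t", index=False
        )
        roc_in.points_frame().to_csv(out / "roc_points.tsv", sep="\t", index=False)
        comparison_frame(demo_results).to_csv(
            out / "cohort_table.tsv", sep="\t", index=False
        )
        model.to_json(out / "model.json")
        (out / "metrics.json").write_text(
            json.dumps(
                {
                    "auc_in_sample": roc_in.auc,
                    "auc_cv": roc_cv.auc,
                    "r2y_cumulative": float(model.r2y.sum()),
                    "q2_selected": float(cv.q2[cv.selected_components - 1]),
                    "n_selected_vip": int(ranked["selected"].sum()),
                },
                indent=1,
            )
        )
        (out / "run_report.json").write_text(json.dumps(report, indent=1))
    return report


def read_inputs(
    scores_path: str | Path, meta_path: str | Path, phenotypes_path: str | Path
) -> tuple[ScorePanel, PhenotypeTable]:
    """Read and validate the three panel files (see :mod:`mpgs_pls.io`)."""
    return read_panel(scores_path, meta_path, phenotypes_path)
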