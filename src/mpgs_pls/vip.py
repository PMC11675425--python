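"""Variable importance in projection (VIP) ranking and category tables.

For a fitted model with components a = 1..A, explained-y sums of squares
SSY_a = q_a^2 * t_a't_a, and weights w_a, the VIP of predictor j is

    VIP_j = sqrt( p * sum_a SSY_a (w_aj / ||w_a||)^2 / sum_a SSY_a )

— the y-variance-weighted form, under which the mean of VIP^2 over ranked
predictors is exactly 1, making "VIP > 1" (strict) the natural cut for an
above-average contribution.  With a single component every common VIP
variant coincides and the ranking equals the |w| ranking.

The diagnosis covariate, when present, is part of the fit but excluded from
the ranking: ``p`` counts ranked predictors only and the weights are
renormalised within them, so the normalisation identity holds for the
reported table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MetadataError, ScorePanel
from .pls import PLSModel

VIP_THRESHOLD = 1.0


def compute_vip(model: PLSModel, meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-predictor VIP table (one row per non-covariate predictor).

    Columns: ``score_id, phenotype, category, weight, vip`` — ``weight`` is
    the first-component predictive weight, whose sign gives the direction of
    association.  ``meta`` (indexed by score id, columns phenotype/category)
    fills the label columns when given.
    """
    if model.n_components < 1:
        raise ValueError("model has no components")
    ranked = ~model.is_covariate
    p = int(ranked.sum())
    if p == 0:
        raise ValueError("no non-covariate predictors to rank")
    W = model.weights[ranked, :]  # p x A, renormalised below
    T, q = model.x_scores, model.y_loadings
    ssy = q**2 * np.einsum("ia,ia->a", T, T)  # per-component explained y-SS
    wnorm2 = np.sum(W**2, axis=0)
    vip2 = p * (W**2 / wnorm2) @ ssy / ssy.sum()
    vip = np.sqrt(vip2)

    ids = [c for c, r in zip(model.column_ids, ranked) if r]
    table = pd.DataFrame(
        {
            "score_id": ids,
            "weight": model.weights[ranked, 0],
            "vip": vip,
        }
    )
    if meta is not None:
        missing = [i for i in ids if i not in meta.index]
        if missing:
            raise MetadataError(f"scores without metadata: {missing[:5]}")
        table["phenotype"] = meta.loc[ids, "phenotype"].to_numpy()
        table["category"] = meta.loc[ids, "category"].to_numpy()
        table = table[["score_id", "phenotype", "category", "weight", "vip"]]
    return table


def rank_and_select(
    vip_table: pd.DataFrame, threshold: float = VIP_THRESHOLD
) -> pd.DataFrame:
    """Sort by VIP (descending), assign ranks, flag VIP > threshold (strict).

    Ties are broken by |weight| descending, then score id lexicographically,
    so the ordering is fully deterministic.
    """
    t = vip_table.copy()
    t["_absw"] = t["weight"].abs()
    t = t.sort_values(
        ["vip", "_absw", "score_id"], ascending=[False, False, True], kind="stable"
    ).drop(columns="_absw")
    t["rank"] = np.arange(1, len(t) + 1)
    t["selected"] = t["vip"] > threshold
    t["direction"] = np.where(t["weight"] > 0, "positive", "negative")
    return t.reset_index(drop=True)


@dataclass
class CategorySummary:
    category: str
    n_total_in_panel: int
    n_selected: int
    n_positive: int  # selected with positive weight: predicts PPD presence
    n_negative: int
    percent_included: float  # 100 * n_selected / n_total_in_panel


def summarize_categories(
    ranked: pd.DataFrame, panel: ScorePanel | pd.DataFrame
) -> list[CategorySummary]:
    """Per-category totals and selected counts split by weight sign.

    Positive weight means the score predicts presence of the outcome (PPD),
    negative weight its absence.  Totals come from the panel metadata so
    that scores dropped during preparation still count toward the
    denominator.
    """
    meta = panel.meta if isinstance(panel, ScorePanel) else panel
    if "category" not in ranked.columns:
        raise MetadataError("ranked table lacks a category column")
    unknown = set(ranked["category"]) - set(meta["category"])
    if unknown:
        raise MetadataError(f"unknown category labels: {sorted(unknown)}")
    totals = meta["category"].value_counts()
    out: list[CategorySummary] = []
    for category in totals.index:
        rows = ranked[ranked["category"] == category]
        sel = rows[rows["selected"]]
        n_pos = int((sel["weight"] > 0).sum())
        n_neg = int((sel["weight"] <= 0).sum())
        n_total = int(totals[category])
        out.append(
            CategorySummary(
                category=category,
                n_total_in_panel=n_total,
                n_selected=len(sel),
                n_positive=n_pos,
                n_negative=n_neg,
                percent_included=100.0 * len(sel) / n_total,
            )
        )
    return out


def category_summary_frame(summaries: list[CategorySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "category": [s.category for s in summaries],
            "n_total_in_panel": [s.n_total_in_panel for s in summaries],
            "n_selected": [s.n_selected for s in summaries],
            "n_positive": [s.n_positive for s in summaries],
            "n_negative": [s.n_negative for s in summaries],
            "percent_included": [s.percent_included for s in summaries],
        }
    )
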