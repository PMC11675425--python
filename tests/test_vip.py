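"""VIP scores: normalization identity, closed forms, ranking and categories."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import mpgs_pls as m
from mpgs_pls.datatypes import MetadataError
from mpgs_pls.vip import category_summary_frame, compute_vip, rank_and_select

from conftest import random_design


def _fit(panel, pheno, A=2, covariate=False):
    d = m.prepare(panel, pheno, include_diagnosis_covariate=covariate)
    return m.fit_model(d, A)


def test_mean_squared_vip_is_one(small_panel):
    panel, pheno = small_panel
    for A in (1, 2, 3):
        vip = compute_vip(_fit(panel, pheno, A))["vip"].to_numpy()
        assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-10)


def test_mean_squared_vip_is_one_with_covariate_excluded(paper_shaped):
    _, panel, pheno, _ = paper_shaped
    model = _fit(panel, pheno, A=1, covariate=True)
    table = compute_vip(model, panel.meta)
    assert len(table) == 341  # the diagnosis covariate is not ranked
    assert "diagnosis_BD" not in set(table["score_id"])
    assert np.mean(table["vip"] ** 2) == pytest.approx(1.0, abs=1e-10)


def test_single_component_closed_form(small_panel):
    """A = 1: VIP_j = sqrt(p) |w_j| / ||w|| — direct loop-free oracle."""
    panel, pheno = small_panel
    model = _fit(panel, pheno, A=1)
    vip = compute_vip(model)["vip"].to_numpy()
    w = model.weights[:, 0]
    oracle = np.sqrt(len(w)) * np.abs(w) / np.linalg.norm(w)
    np.testing.assert_allclose(vip, oracle, atol=1e-10)


def test_uniform_weights_give_unit_vip():
    """Equal |w| across predictors means every VIP is exactly 1."""
    n, p = 24, 6
    rng = np.random.default_rng(0)
    f = rng.standard_normal(n)
    X = np.column_stack([f + 1e-3 * rng.standard_normal(n) for _ in range(p)])
    sample_ids = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    score_ids = pd.Index([f"SC{j}" for j in range(p)], name="score_id")
    # identical columns up to tiny noise -> nearly equal weights; build the
    # exact case instead by symmetrizing the weights on a fitted model
    panel = m.ScorePanel(
        pd.DataFrame(X, index=sample_ids, columns=score_ids),
        pd.DataFrame({"phenotype": score_ids, "category": ["psychiatric"] * p},
                     index=score_ids),
    )
    y = (f > 0).astype(int)
    pheno = m.PhenotypeTable(
        pd.DataFrame({"ppd": y, "diagnosis": ["MDD"] * n}, index=sample_ids)
    )
    model = _fit(panel, pheno, A=1)
    model.weights = np.full_like(model.weights, 1 / np.sqrt(p))
    vip = compute_vip(model)["vip"].to_numpy()
    np.testing.assert_allclose(vip, 1.0, atol=1e-12)


def test_vip_invariant_to_component_sign_flip(small_panel):
    panel, pheno = small_panel
    model = _fit(panel, pheno, A=2)
    vip1 = compute_vip(model)["vip"].to_numpy()
    model.weights[:, 0] *= -1
    model.x_scores[:, 0] *= -1
    model.y_loadings[0] *= -1
    vip2 = compute_vip(model)["vip"].to_numpy()
    np.testing.assert_allclose(vip1, vip2, atol=1e-12)


def test_single_component_ranking_equals_weight_ranking(small_panel):
    panel, pheno = small_panel
    model = _fit(panel, pheno, A=1)
    ranked = rank_and_select(compute_vip(model))
    by_weight = ranked.reindex(
        ranked["weight"].abs().sort_values(ascending=False).index
    )["score_id"]
    assert list(ranked["score_id"]) == list(by_weight)


def test_ranks_are_permutation_and_threshold_is_strict():
    table = pd.DataFrame(
        {
            "score_id": ["a", "b", "c", "d"],
            "weight": [0.5, -0.4, 0.3, 0.2],
            "vip": [1.5, 1.0, 1.0, 0.2],
        }
    )
    ranked = rank_and_select(table)
    assert sorted(ranked["rank"]) == [1, 2, 3, 4]
    # vip exactly 1.0 is NOT selected ("greater than 1" is strict)
    assert list(ranked["selected"]) == [True, False, False, False]
    # tie at vip=1.0 broken by |weight| descending
    tied = ranked[ranked["vip"] == 1.0]
    assert list(tied["score_id"]) == ["b", "c"]


def test_all_below_threshold_selects_nothing():
    table = pd.DataFrame(
        {"score_id": ["a", "b"], "weight": [0.1, -0.2], "vip": [0.9, 0.8]}
    )
    ranked = rank_and_select(table)
    assert ranked["selected"].sum() == 0
    assert list(ranked["rank"]) == [1, 2]


def test_category_summary_matches_hand_tally():
    """12-score toy table tallied by hand."""
    meta = pd.DataFrame(
        {
            "phenotype": [f"p{i}" for i in range(12)],
            "category": ["psychiatric"] * 4 + ["immune_inflammation"] * 5
            + ["sleep_circadian"] * 3,
        },
        index=pd.Index([f"SC{i:02d}" for i in range(12)], name="score_id"),
    )
    table = pd.DataFrame(
        {
            "score_id": meta.index,
            "phenotype": meta["phenotype"].to_numpy(),
            "category": meta["category"].to_numpy(),
            "weight": [0.3, -0.2, 0.1, 0.05, -0.4, 0.35, 0.2, -0.1, 0.02,
                       -0.5, 0.45, 0.01],
            "vip": [2.0, 1.5, 0.8, 0.2, 1.9, 1.7, 1.2, 0.9, 0.1, 2.2, 1.1, 0.3],
        }
    )
    ranked = rank_and_select(table)
    summary = {s.category: s for s in m.summarize_categories(ranked, meta)}
    # psychiatric: SC00 (w+), SC01 (w-) selected of 4
    assert (summary["psychiatric"].n_selected,
            summary["psychiatric"].n_positive,
            summary["psychiatric"].n_negative) == (2, 1, 1)
    assert summary["psychiatric"].percent_included == pytest.approx(50.0)
    # immune: SC04 (-), SC05 (+), SC06 (+) of 5
    assert (summary["immune_inflammation"].n_selected,
            summary["immune_inflammation"].n_positive,
            summary["immune_inflammation"].n_negative) == (3, 2, 1)
    assert summary["immune_inflammation"].percent_included == pytest.approx(60.0)
    # sleep: SC09 (-), SC10 (+) of 3
    assert (summary["sleep_circadian"].n_selected,
            summary["sleep_circadian"].n_positive,
            summary["sleep_circadian"].n_negative) == (2, 1, 1)
    for s in summary.values():
        assert s.n_selected == s.n_positive + s.n_negative


def test_zero_selected_gives_zero_counts():
    meta = pd.DataFrame(
        {"phenotype": ["p1", "p2"], "category": ["psychiatric", "psychiatric"]},
        index=pd.Index(["SC1", "SC2"], name="score_id"),
    )
    table = pd.DataFrame(
        {"score_id": ["SC1", "SC2"], "phenotype": ["p1", "p2"],
         "category": ["psychiatric"] * 2, "weight": [0.1, 0.2],
         "vip": [0.5, 0.6]}
    )
    summaries = m.summarize_categories(rank_and_select(table), meta)
    assert summaries[0].n_selected == 0
    assert summaries[0].percent_included == 0.0


def test_unknown_category_rejected():
    meta = pd.DataFrame(
        {"phenotype": ["p1"], "category": ["psychiatric"]},
        index=pd.Index(["SC1"], name="score_id"),
    )
    table = pd.DataFrame(
        {"score_id": ["SC1"], "phenotype": ["p1"], "category": ["mystery"],
         "weight": [0.1], "vip": [1.5], "selected": [True]}
    )
    with pytest.raises(MetadataError):
        m.summarize_categories(table, meta)


@given(st.integers(0, 10_000))
def test_vip_normalization_property(seed):
    """Normalization holds for arbitrary random problems and A."""
    rng = np.random.default_rng(seed)
    panel, pheno = random_design(rng, n=15, p=6)
    model = _fit(panel, pheno, A=int(rng.integers(1, 4)))
    vip = compute_vip(model)["vip"].to_numpy()
    assert np.sum(vip**2) == pytest.approx(len(vip), abs=1e-8)


def test_causal_scores_outrank_null_scores(paper_shaped):
    _, panel, pheno, truth = paper_shaped
    model = _fit(panel, pheno, A=1)
    ranked = rank_and_select(compute_vip(model, panel.meta))
    ranks = ranked.set_index("score_id")["rank"]
    causal = list(truth.causal_score_ids)
    null = [s for s in ranks.index if s not in set(causal)]
    assert ranks[causal].mean() < ranks[null].mean()


def test_category_summary_frame_columns():
    meta = pd.DataFrame(
        {"phenotype": ["p1"], "category": ["psychiatric"]},
        index=pd.Index(["SC1"], name="score_id"),
    )
    table = pd.DataFrame(
        {"score_id": ["SC1"], "phenotype": ["p1"], "category": ["psychiatric"],
         "weight": [0.4], "vip": [1.4]}
    )
    frame = category_summary_frame(
        m.summarize_categories(rank_and_select(table), meta)
    )
    assert list(frame.columns) == [
        "category", "n_total_in_panel", "n_selected", "n_positive",
        "n_negative", "percent_included",
    ]
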