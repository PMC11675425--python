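"""Core data containers shared across the analysis stages.

A :class:`ScorePanel` holds the samples x scores predictor block (one
pre-computed polygenic score per column) together with per-score metadata
(phenotype label and trait category).  A :class:`PhenotypeTable` holds the
per-subject binary outcome (history of peripartum depression), the mood
disorder diagnosis label, and any demographic columns used for cohort
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default trait categories of the score panel.  The category column is
#: free-form; these four names are the canonical grouping used throughout.
CATEGORIES = (
    "psychiatric",
    "hormone_pregnancy",
    "immune_inflammation",
    "sleep_circadian",
)

DIAGNOSES = ("MDD", "BD")


class MetadataError(ValueError):
    """Score/phenotype metadata is inconsistent with the score matrix."""


class AnalysisError(ValueError):
    """The inputs cannot support the requested analysis (e.g. one-class y)."""


@dataclass
class ScorePanel:
    """Samples x scores matrix with per-score phenotype/category labels.

    Parameters
    ----------
    scores
        DataFrame indexed by sample id, one numeric column per score id.
    meta
        DataFrame indexed by score id with columns ``phenotype`` and
        ``category``, aligned to ``scores.columns``.
    """

    scores: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.scores.columns.duplicated().any():
            raise MetadataError("duplicate score ids in score matrix")
        if self.scores.index.duplicated().any():
            raise MetadataError("duplicate sample ids in score matrix")
        missing = set(self.scores.columns) - set(self.meta.index)
        extra = set(self.meta.index) - set(self.scores.columns)
        if missing or extra:
            raise MetadataError(
                f"score metadata mismatch: {len(missing)} scores without "
                f"metadata, {len(extra)} metadata rows without scores"
            )
        for col in ("phenotype", "category"):
            if col not in self.meta.columns:
                raise MetadataError(f"score metadata lacks required column {col!r}")
        # keep metadata in matrix column order
        self.meta = self.meta.loc[self.scores.columns]
        if not all(np.issubdtype(dt, np.number) for dt in self.scores.dtypes):
            raise MetadataError("score matrix contains non-numeric columns")

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]

    @property
    def n_scores(self) -> int:
        return self.scores.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.scores.index

    @property
    def score_ids(self) -> pd.Index:
        return self.scores.columns

    def category_counts(self) -> pd.Series:
        return self.meta["category"].value_counts()


@dataclass
class PhenotypeTable:
    """Per-subject outcome, diagnosis and optional demographics.

    ``table`` is indexed by sample id and must contain an integer ``ppd``
    column (1 = history of peripartum depression) and a ``diagnosis`` column
    with labels MDD/BD.  Additional columns are treated as demographics.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise MetadataError("duplicate sample ids in phenotype table")
        for col in ("ppd", "diagnosis"):
            if col not in self.table.columns:
                raise MetadataError(f"phenotype table lacks required column {col!r}")
        vals = set(pd.unique(self.table["ppd"]))
        if not vals <= {0, 1}:
            raise MetadataError(f"outcome column must be coded 0/1, got {sorted(vals)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def outcome(self) -> np.ndarray:
        return self.table["ppd"].to_numpy(dtype=float)

    @property
    def diagnosis(self) -> pd.Series:
        return self.table["diagnosis"]

    @property
    def demographics(self) -> pd.DataFrame:
        return self.table.drop(columns=["ppd", "diagnosis"])

    def subset(self, sample_ids) -> "PhenotypeTable":
        return PhenotypeTable(self.table.loc[sample_ids])


def align(panel: ScorePanel, phenotypes: PhenotypeTable) -> PhenotypeTable:
    """Return the phenotype table reindexed to the panel's sample order.

    Raises :class:`MetadataError` if the two id sets differ.
    """
    if set(panel.sample_ids) != set(phenotypes.sample_ids):
        only_panel = set(panel.sample_ids) - set(phenotypes.sample_ids)
        only_pheno = set(phenotypes.sample_ids) - set(panel.sample_ids)
        raise MetadataError(
            f"sample id mismatch: {len(only_panel)} ids only in scores, "
            f"{len(only_pheno)} only in phenotypes"
        )
    return PhenotypeTable(phenotypes.table.loc[panel.sample_ids])
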