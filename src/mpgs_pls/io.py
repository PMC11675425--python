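"""Reading and writing the tab-separated panel/phenotype file dialect.

Three files describe a study:

* ``scores.tsv`` — header ``sample_id`` plus one column per score id; one
  numeric row per subject.
* ``score_meta.tsv`` — columns ``score_id, phenotype, category``.
* ``phenotypes.tsv`` — columns ``sample_id, ppd, diagnosis`` plus optional
  demographic columns.

All files are UTF-8 with ``.`` decimal separators.  Readers realign the
phenotype table to the score matrix by sample id and reject inconsistent
inputs with a located error.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datatypes import MetadataError, PhenotypeTable, ScorePanel, align


class InputFormatError(ValueError):
    """A panel input file is malformed."""


def read_scores(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
    except ValueError as exc:
        raise InputFormatError(f"{path}: malformed header ({exc})") from exc
    bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if bad:
        raise InputFormatError(
            f"{path}: non-numeric score columns {bad[:5]}"
            + ("..." if len(bad) > 5 else "")
        )
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()
        raise InputFormatError(f"{path}: missing values in rows {rows[:5]}")
    return df


def read_score_meta(path: str | Path) -> pd.DataFrame:
    try:
        meta = pd.read_csv(path, sep="\t", index_col="score_id")
    except ValueError as exc:
        raise InputFormatError(f"{path}: malformed header ({exc})") from exc
    for col in ("phenotype", "category"):
        if col not in meta.columns:
            raise InputFormatError(f"{path}: missing column {col!r}")
    return meta


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    try:
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
    except ValueError as exc:
        raise InputFormatError(f"{path}: malformed header ({exc})") from exc
    return PhenotypeTable(df)


def read_panel(
    scores_path: str | Path,
    meta_path: str | Path,
    phenotypes_path: str | Path,
) -> tuple[ScorePanel, PhenotypeTable]:
    """Read and cross-validate the three input files.

    The phenotype table is reordered to the score matrix's sample order, so
    downstream code can rely on positional alignment.
    """
    scores = read_scores(scores_path)
    meta = read_score_meta(meta_path)
    phenotypes = read_phenotypes(phenotypes_path)
    try:
        panel = ScorePanel(scores, meta)
        phenotypes = align(panel, phenotypes)
    except MetadataError as exc:
        raise MetadataError(
            f"{scores_path} / {meta_path} / {phenotypes_path}: {exc}"
        ) from exc
    return panel, phenotypes


def write_panel(
    panel: ScorePanel, phenotypes: PhenotypeTable, directory: str | Path
) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "scores": directory / "scores.tsv",
        "score_meta": directory / "score_meta.tsv",
        "phenotypes": directory / "phenotypes.tsv",
    }
    panel.scores.to_csv(paths["scores"], sep="\t")
    panel.meta.to_csv(paths["score_meta"], sep="\t")
    phenotypes.table.to_csv(paths["phenotypes"], sep="\t")
    return paths
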