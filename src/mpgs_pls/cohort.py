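"""Case/control cohort comparison statistics.

Continuous variables are compared with the pooled-variance (Student) two
sample t-test plus Cohen's d; categorical variables with the uncorrected
Pearson chi-square plus Cramer's V.  Both tests can be computed either from
raw per-subject columns or from published summary statistics (group mean,
SD, n, or a contingency table), and the two paths agree exactly when the
summaries are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AnalysisError, PhenotypeTable


@dataclass(frozen=True)
class SummaryStat:
    """Mean/SD/n summary of one group for a continuous variable."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise AnalysisError(f"group {self.label!r}: need n >= 2")
        if self.sd < 0:
            raise AnalysisError(f"group {self.label!r}: negative SD")


@dataclass
class ComparisonResult:
    variable: str
    statistic_type: str  # "t" or "chi2"
    statistic: float
    effect_size: float
    effect_size_name: str  # "cohens_d" or "cramers_v"
    df: float
    p_value: float


def t_test_from_summary(
    g1: SummaryStat, g2: SummaryStat, variable: str = ""
) -> ComparisonResult:
    """Pooled-variance Student t-test and Cohen's d from group summaries."""
    sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / (g1.n + g2.n - 2)
    if sp2 == 0.0:
        raise AnalysisError(f"{variable or 'variable'}: zero pooled variance")
    t, p = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=True
    )
    d = (g1.mean - g2.mean) / np.sqrt(sp2)
    return ComparisonResult(
        variable=variable,
        statistic_type="t",
        statistic=float(t),
        effect_size=float(d),
        effect_size_name="cohens_d",
        df=g1.n + g2.n - 2,
        p_value=float(p),
    )


def chi2_test(table, variable: str = "") -> ComparisonResult:
    """Uncorrected Pearson chi-square and Cramer's V on a 2 x k count table."""
    table = np.asarray(table, dtype=float)
    if table.min() < 0:
        raise AnalysisError(f"{variable or 'variable'}: negative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise AnalysisError(f"{variable or 'variable'}: zero margin in count table")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    n = table.sum()
    k = min(table.shape) - 1
    v = np.sqrt(chi2 / (n * k)) if k > 0 else 0.0
    return ComparisonResult(
        variable=variable,
        statistic_type="chi2",
        statistic=float(chi2),
        effect_size=float(v),
        effect_size_name="cramers_v",
        df=float(df),
        p_value=float(p),
    )


def t_test_from_raw(
    values: np.ndarray, group: np.ndarray, variable: str = ""
) -> ComparisonResult:
    """Raw-data path: summarise each group then delegate to the summary path,
    so the two routes agree by construction."""
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise AnalysisError(f"{variable}: need exactly two groups, got {labels.size}")
    # cases (group == max label, e.g. ppd == 1) listed first
    g1v = values[group == labels[-1]]
    g2v = values[group == labels[0]]
    g1 = SummaryStat(str(labels[-1]), len(g1v), float(g1v.mean()), float(g1v.std(ddof=1)))
    g2 = SummaryStat(str(labels[0]), len(g2v), float(g2v.mean()), float(g2v.std(ddof=1)))
    return t_test_from_summary(g1, g2, variable=variable)


def chi2_test_from_raw(
    values: np.ndarray, group: np.ndarray, variable: str = ""
) -> ComparisonResult:
    crosstab = pd.crosstab(pd.Series(group), pd.Series(values))
    return chi2_test(crosstab.to_numpy(), variable=variable)


def cohort_table(
    phenotypes: PhenotypeTable,
    variables: list[str] | None = None,
    group_column: str = "ppd",
) -> tuple[list[ComparisonResult], list[str]]:
    """Compare each demographic variable between outcome groups.

    Numeric columns get the t-test path, non-numeric (or few-valued integer)
    columns the chi-square path.  Constant variables are excluded and
    returned in the second element rather than reported.
    """
    df = phenotypes.table
    group = df[group_column].to_numpy()
    if variables is None:
        variables = [c for c in df.columns if c not in (group_column, "diagnosis")]
    results: list[ComparisonResult] = []
    skipped: list[str] = []
    for var in variables:
        if var not in df.columns:
            raise AnalysisError(f"variable {var!r} not in phenotype table")
        col = df[var]
        if col.nunique(dropna=True) < 2:
            skipped.append(var)
            continue
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 5:
            results.append(t_test_from_raw(col.to_numpy(), group, variable=var))
        else:
            results.append(chi2_test_from_raw(col.to_numpy(), group, variable=var))
    return results, skipped


def comparison_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variable": [r.variable for r in results],
            "statistic_type": [r.statistic_type for r in results],
            "statistic": [r.statistic for r in results],
            "effect_size": [r.effect_size for r in results],
            "effect_size_name": [r.effect_size_name for r in results],
            "df": [r.df for r in results],
            "p_value": [r.p_value for r in results],
        }
    )
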