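"""Synthetic multi-polygenic-score panels with planted case/control signal.

Real PRS panels are strongly multicollinear: the same trait is often scored
by several near-duplicate published scoring files (e.g. multiple "Monocyte
count" scores), and scores within a trait correlate heavily while scores for
unrelated traits are closer to independent.  The generator reproduces that
structure at the score level:

* scores are organised in phenotype *blocks*; within a block, columns share a
  latent factor so that their pairwise correlation is approximately a chosen
  rho (``x = sqrt(rho) * factor + sqrt(1 - rho) * noise``, all standard
  normal, which guarantees a positive semi-definite correlation structure);
* a sparse set of phenotype blocks carries a planted linear effect on a
  continuous liability ``L = X beta + e``;
* case status is assigned by rank-thresholding the liability so that the
  case/control margins are exact by construction, mirroring a fixed
  case/control study design rather than a Bernoulli draw;
* each subject gets an MDD or BD diagnosis label with fixed margins,
  independent of the outcome unless a signal entry is restricted to one
  diagnostic group.

No genotypes, allele dosages or linkage disequilibrium are simulated; the
panel is generated directly at the score level.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CATEGORIES, PhenotypeTable, ScorePanel
from . import io as _io


class ConfigurationError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class BlockSpec:
    """One phenotype block: ``size`` near-duplicate scores at correlation rho."""

    phenotype: str
    category: str
    size: int
    rho: float

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ConfigurationError(f"block {self.phenotype!r}: size must be >= 1")
        if not (0.0 <= self.rho < 1.0):
            raise ConfigurationError(
                f"block {self.phenotype!r}: rho must be in [0, 1), got {self.rho}"
            )


@dataclass(frozen=True)
class SignalSpec:
    """Planted effect for one phenotype block.

    ``beta`` is the per-score effect on the liability scale (all scores in
    the block share it).  If ``group`` is ``"MDD"`` or ``"BD"`` the effect
    applies only to subjects with that diagnosis, allowing diagnosis-specific
    genetic architecture to be simulated; by default the effect is global.
    """

    phenotype: str
    beta: float
    group: str | None = None


# Default case/control and diagnosis margins of the emulated study design:
# 178 parous women with mood disorders, 62 with a PPD history, 72 MDD / 106 BD.
DEFAULT_N_CASES = 62
DEFAULT_N_CONTROLS = 116
DEFAULT_CATEGORY_SIZES = {
    "psychiatric": 67,
    "hormone_pregnancy": 89,
    "immune_inflammation": 131,
    "sleep_circadian": 54,
}
DEFAULT_MDD_FRACTION = 72 / 178

# Block-size multiplicities cycled within each category: most traits have
# 1-4 near-duplicate scores from different source publications.
_BLOCK_SIZE_CYCLE = (3, 2, 4, 1, 3, 2, 1)
DEFAULT_RHO = 0.9


def default_blocks(
    category_sizes: dict[str, int] | None = None, rho: float = DEFAULT_RHO
) -> list[BlockSpec]:
    """Partition each category into phenotype blocks of cycled sizes."""
    sizes = dict(category_sizes or DEFAULT_CATEGORY_SIZES)
    blocks: list[BlockSpec] = []
    for category, total in sizes.items():
        remaining = total
        i = 0
        while remaining > 0:
            size = min(_BLOCK_SIZE_CYCLE[i % len(_BLOCK_SIZE_CYCLE)], remaining)
            blocks.append(
                BlockSpec(
                    phenotype=f"{category}_trait{i + 1:02d}",
                    category=category,
                    size=size,
                    rho=rho,
                )
            )
            remaining -= size
            i += 1
    return blocks


def default_signal(
    blocks: list[BlockSpec], n_causal: int = 20, beta: float = 0.5
) -> list[SignalSpec]:
    """Pick phenotype blocks totalling exactly ``n_causal`` scores.

    Blocks are taken round-robin across categories so the planted signal is
    spread over all four trait domains.  Sleep/circadian effects are planted
    with a negative sign (genetic morningness protective), the rest positive.
    """
    by_cat: dict[str, list[BlockSpec]] = {}
    for b in blocks:
        by_cat.setdefault(b.category, []).append(b)
    chosen: list[BlockSpec] = []
    total = 0
    idx = 0
    while total < n_causal:
        progressed = False
        for cat in by_cat:
            queue = by_cat[cat]
            if idx < len(queue) and total < n_causal:
                b = queue[idx]
                if total + b.size <= n_causal:
                    chosen.append(b)
                    total += b.size
                    progressed = True
        idx += 1
        if not progressed and total < n_causal:
            # fill the remainder with any block of exactly the missing size
            need = n_causal - total
            for b in blocks:
                if b not in chosen and b.size == need:
                    chosen.append(b)
                    total += b.size
                    break
            else:
                raise ConfigurationError(
                    f"cannot assemble exactly {n_causal} causal scores from blocks"
                )
    return [
        SignalSpec(
            phenotype=b.phenotype,
            beta=-beta if b.category == "sleep_circadian" else beta,
        )
        for b in chosen
    ]


@dataclass
class SimConfig:
    """Full description of one simulated study.

    ``noise_sd`` is the standard deviation of the non-genetic component of
    the liability.  Under the default planted signal (20 causal scores,
    |beta| = 0.5, rho = 0.9 blocks) the genetic component has variance ~14.7,
    so the default ``noise_sd = 2.0`` makes the liability ~79% genetic —
    a strong but not deterministic signal, consistent with a panel selected
    for traits plausibly related to the outcome.
    """

    n_cases: int = DEFAULT_N_CASES
    n_controls: int = DEFAULT_N_CONTROLS
    category_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_SIZES)
    )
    block_spec: list[BlockSpec] | None = None
    signal_spec: list[SignalSpec] | None = None
    noise_sd: float = 2.0
    cross_category_loading: float = 0.0
    mdd_fraction: float = DEFAULT_MDD_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ConfigurationError("need at least one case and one control")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if not (0.0 <= self.cross_category_loading < 1.0):
            raise ConfigurationError("cross_category_loading must be in [0, 1)")
        if self.block_spec is None:
            self.block_spec = default_blocks(self.category_sizes)
        if self.signal_spec is None:
            self.signal_spec = default_signal(self.block_spec)
        per_cat: dict[str, int] = {c: 0 for c in self.category_sizes}
        for b in self.block_spec:
            if b.category not in per_cat:
                raise ConfigurationError(f"block category {b.category!r} not declared")
            per_cat[b.category] += b.size
        if per_cat != self.category_sizes:
            raise ConfigurationError(
                f"block sizes per category {per_cat} do not match "
                f"category_sizes {self.category_sizes}"
            )
        known = {b.phenotype for b in self.block_spec}
        for s in self.signal_spec:
            if s.phenotype not in known:
                raise ConfigurationError(
                    f"signal phenotype {s.phenotype!r} has no block"
                )
            if s.group is not None and s.group not in ("MDD", "BD"):
                raise ConfigurationError(f"signal group must be MDD/BD, got {s.group!r}")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def n_scores(self) -> int:
        return sum(self.category_sizes.values())


@dataclass
class GroundTruth:
    """What was planted: per-score effects and the realised liability."""

    true_effect_vector: pd.Series  # indexed by score id, liability-scale beta
    latent_liability: pd.Series  # indexed by sample id
    outcome_rule: str

    @property
    def causal_score_ids(self) -> pd.Index:
        return self.true_effect_vector.index[self.true_effect_vector != 0.0]


def generate_panel(
    config: SimConfig,
) -> tuple[ScorePanel, PhenotypeTable, GroundTruth]:
    """Draw one synthetic score panel, phenotype table and ground truth.

    Reproducible: the same configuration (including ``seed``) yields
    bitwise-identical output.
    """
    if config.n_scores == 0:
        raise ConfigurationError("panel must contain at least one score")
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    gamma = config.cross_category_loading

    sample_ids = [f"subj{i + 1:03d}" for i in range(n)]

    global_factor = rng.standard_normal(n) if gamma > 0 else None
    columns: list[np.ndarray] = []
    score_ids: list[str] = []
    phenotypes: list[str] = []
    categories: list[str] = []
    beta_by_score: dict[str, float] = {}
    group_by_score: dict[str, str | None] = {}
    signal = {s.phenotype: s for s in config.signal_spec}

    k = 0
    for block in config.block_spec:
        factor = rng.standard_normal(n)
        for _ in range(block.size):
            idio = rng.standard_normal(n)
            x = np.sqrt(block.rho) * factor + np.sqrt(1.0 - block.rho) * idio
            if global_factor is not None:
                x = np.sqrt(gamma) * global_factor + np.sqrt(1.0 - gamma) * x
            k += 1
            sid = f"SC{k:04d}"
            columns.append(x)
            score_ids.append(sid)
            phenotypes.append(block.phenotype)
            categories.append(block.category)
            s = signal.get(block.phenotype)
            beta_by_score[sid] = s.beta if s is not None else 0.0
            group_by_score[sid] = s.group if s is not None else None

    X = np.column_stack(columns)
    scores = pd.DataFrame(X, index=pd.Index(sample_ids, name="sample_id"),
                          columns=pd.Index(score_ids, name="score_id"))
    meta = pd.DataFrame(
        {"phenotype": phenotypes, "category": categories},
        index=pd.Index(score_ids, name="score_id"),
    )

    # diagnosis labels: fixed margins, random assignment, drawn before the
    # outcome so diagnosis-restricted effects can enter the liability
    n_mdd = int(round(config.mdd_fraction * n))
    diagnosis = np.array(["MDD"] * n_mdd + ["BD"] * (n - n_mdd))
    diagnosis = diagnosis[rng.permutation(n)]

    beta = np.array([beta_by_score[s] for s in score_ids])
    liability = np.zeros(n)
    for j, sid in enumerate(score_ids):
        if beta[j] == 0.0:
            continue
        grp = group_by_score[sid]
        contrib = X[:, j] * beta[j]
        if grp is not None:
            contrib = contrib * (diagnosis == grp)
        liability += contrib
    liability = liability + config.noise_sd * rng.standard_normal(n)

    # fixed case/control margins: top n_cases liabilities become cases
    order = np.argsort(liability, kind="stable")
    ppd = np.zeros(n, dtype=int)
    ppd[order[n - config.n_cases:]] = 1

    pheno = pd.DataFrame(
        {"ppd": ppd, "diagnosis": diagnosis},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = GroundTruth(
        true_effect_vector=pd.Series(beta, index=scores.columns, name="beta"),
        latent_liability=pd.Series(liability, index=scores.index, name="liability"),
        outcome_rule=(
            f"rank threshold: the {config.n_cases} subjects with the highest "
            f"liability X.beta + N(0, {config.noise_sd}^2) are cases"
        ),
    )
    return ScorePanel(scores, meta), PhenotypeTable(pheno), truth


def write_fixture(
    panel: ScorePanel,
    phenotypes: PhenotypeTable,
    truth: GroundTruth | None,
    directory: str | Path,
) -> dict[str, Path]:
    """Write ``scores.tsv``, ``score_meta.tsv``, ``phenotypes.tsv`` (and
    ``ground_truth.tsv`` when a truth object is given) to ``directory``."""
    if panel.n_scores == 0:
        raise ConfigurationError("refusing to write an empty panel (p = 0)")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = _io.write_panel(panel, phenotypes, directory)
    if truth is not None:
        tpath = directory / "ground_truth.tsv"
        pd.DataFrame(
            {"beta": truth.true_effect_vector}
        ).rename_axis("score_id").to_csv(tpath, sep="\t")
        paths["ground_truth"] = tpath
    return paths


def config_from_dict(d: dict) -> SimConfig:
    """Build a :class:`SimConfig` from a plain mapping (e.g. parsed YAML)."""
    d = dict(d)
    if "block_spec" in d and d["block_spec"] is not None:
        d["block_spec"] = [BlockSpec(**b) for b in d["block_spec"]]
    if "signal_spec" in d and d["signal_spec"] is not None:
        d["signal_spec"] = [SignalSpec(**s) for s in d["signal_spec"]]
    valid = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - valid
    if unknown:
        raise ConfigurationError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimConfig(**d)
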