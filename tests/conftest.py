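import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import mpgs_pls as m

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_shaped():
    """Default-configuration synthetic study: 178 x 341, 62 cases."""
    cfg = m.SimConfig(seed=11)
    panel, pheno, truth = m.generate_panel(cfg)
    return cfg, panel, pheno, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_design(rng, n=20, p=8):
    """Small random regression problem wrapped in panel/phenotype objects."""
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p)
    y = (X @ beta + rng.standard_normal(n) > 0).astype(int)
    if y.sum() in (0, n):  # both classes required
        y[0], y[1] = 0, 1
    sample_ids = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    score_ids = pd.Index([f"SC{j:04d}" for j in range(p)], name="score_id")
    panel = m.ScorePanel(
        pd.DataFrame(X, index=sample_ids, columns=score_ids),
        pd.DataFrame(
            {"phenotype": [f"ph{j}" for j in range(p)],
             "category": ["psychiatric"] * p},
            index=score_ids,
        ),
    )
    diag = np.where(rng.random(n) < 0.5, "MDD", "BD")
    pheno = m.PhenotypeTable(
        pd.DataFrame({"ppd": y, "diagnosis": diag}, index=sample_ids)
    )
    return panel, pheno


@pytest.fixture()
def small_panel(rng):
    return random_design(rng)
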