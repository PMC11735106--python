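import numpy as np
import pandas as pd
import pytest

from sigloss import ExpressionMatrix, SampleGroups, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded 300-gene, 60-sample lognormal cohort with planted signal."""
    cfg = SimConfig(n_samples=60, n_genes=300, n_planted_up=20, n_planted_down=20,
                    effect_log2=2.0, seed=3)
    return simulate_cohort(cfg)


@pytest.fixture
def toy_matrix():
    """Deterministic 6-gene, 8-sample matrix for arithmetic checks."""
    rng = np.random.default_rng(42)
    vals = rng.lognormal(3.0, 0.5, size=(6, 8))
    return ExpressionMatrix(
        pd.DataFrame(vals, index=[f"g{i}" for i in range(6)],
                     columns=[f"s{i}" for i in range(8)]))


@pytest.fixture
def toy_groups():
    return SampleGroups(low=[f"s{i}" for i in range(4)],
                        high=[f"s{i}" for i in range(4, 8)])
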