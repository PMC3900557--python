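import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import ionsig as isg

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def small_cohort():
    """A deterministic 6-gene x 8-sample cohort with a 4-pair design."""
    rng = np.random.default_rng(42)
    genes = [f"G{i}" for i in range(6)]
    normal = [f"P{i}N" for i in range(4)]
    tumor = [f"P{i}T" for i in range(4)]
    mat = pd.DataFrame(rng.normal(8, 1, (6, 8)), index=genes,
                       columns=normal + tumor)
    pairing = {f"P{i}": (normal[i], tumor[i]) for i in range(4)}
    return isg.ExpressionCohort(mat, pairing=pairing, cohort_name="toy")


@pytest.fixture
def paired_sim():
    """Planted paired cohort: 30 effects with |log2 fc| >= 1, 60 pairs."""
    cfg = isg.SimulationConfig(n_genes=400, n_de=30, n_pairs=60,
                               log2fc_range=(1.0, 2.5), sigma_gene=0.5,
                               seed=11)
    cohort, truth = isg.generate_paired(cfg)
    return cfg, cohort, truth
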