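import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from microdelta.core_io import CohortMetadata, FeatureTable
from microdelta.simulate import SimulationConfig, simulate_cohort


@pytest.fixture
def toy_tree():
    """((A:1,B:1):1,C:2); — the worked Faith-PD example tree."""
    return TreeNode.read(io.StringIO("((A:1,B:1):1,C:2);"))


@pytest.fixture
def star_tree():
    """Two-leaf star with unit branches."""
    return TreeNode.read(io.StringIO("(A:1,B:1);"))


def make_paired_cohort(base: np.ndarray, end: np.ndarray, arm="UDCA",
                       sex="M", prefix="P") -> tuple[FeatureTable, CohortMetadata]:
    """Wrap matched baseline/end count matrices as a one-arm paired cohort."""
    n, d = base.shape
    sids = [f"{prefix}{i:03d}.B" for i in range(n)] + [
        f"{prefix}{i:03d}.E" for i in range(n)]
    table = FeatureTable(
        pd.DataFrame(np.vstack([base, end]), index=sids,
                     columns=[f"F{j}" for j in range(d)])
    )
    meta = CohortMetadata(pd.DataFrame({
        "subject_id": [f"{prefix}{i:03d}" for i in range(n)] * 2,
        "arm": arm,
        "timepoint": ["baseline"] * n + ["end"] * n,
        "sex": sex, "age": 60.0, "aspirin": 0, "batch_mismatch": 0,
        "storage_years": 15.0, "outcome_any": 0, "outcome_advanced": 0,
    }, index=sids))
    return table, meta


@pytest.fixture(scope="session")
def small_cohort():
    """A 20/20-subject, 40-feature synthetic cohort shared across tests."""
    cfg = SimulationConfig(n_udca=20, n_placebo=20, n_features=40, seed=7)
    return simulate_cohort(cfg)
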