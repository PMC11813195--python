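import numpy as np
import pandas as pd
import pytest

from burnoutprev import cohort, pipeline


@pytest.fixture(scope="session")
def small_cohort():
    """A 250-physician MNAR cohort shared by pipeline-level tests."""
    cfg = cohort.example_config(250, seed=7, mnar_strength=-0.6)
    return cohort.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_analysis(small_cohort):
    records, features, truth = small_cohort
    cfg = pipeline.PipelineConfig.with_seed(7, n_boot=30)
    return pipeline.analyze_cohort(records, features, cfg), truth


def make_feature_table(x: np.ndarray, ids=None, waves=None) -> pd.DataFrame:
    """Wrap a plain numeric matrix as a feature table."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[0]
    return pd.DataFrame(
        {
            "physician_id": ids if ids is not None else [f"p{i}" for i in range(n)],
            "wave": waves if waves is not None else np.ones(n, dtype=int),
            **{f"x{j}": x[:, j] for j in range(x.shape[1])},
        }
    )
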