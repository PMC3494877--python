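import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mirpair.preprocess import ExpressionDataset, LOG2, RAW

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_dataset(values: np.ndarray, scale: str = LOG2,
                 tissues: list[str] | None = None) -> ExpressionDataset:
    """Minimal ExpressionDataset around a plain numpy matrix."""
    n_feat, n_samp = values.shape
    cols = pd.Index([f"s{j}" for j in range(n_samp)], name="sample_id")
    ann = pd.DataFrame({
        "patient": [f"p{j}" for j in range(n_samp)],
        "tissue": tissues or ["tumour"] * n_samp,
        "subtype": "X",
        "replicate_of": "",
        "pt_stage": 1,
    }, index=cols)
    vals = pd.DataFrame(values, index=pd.Index([f"f{i}" for i in range(n_feat)],
                                               name="feature_id"), columns=cols)
    return ExpressionDataset(values=vals, sample_annotation=ann, scale=scale)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def null_cohort():
    """A small fully-matched cohort with no planted effects (log2 scale)."""
    from mirpair.cli import preprocess_cohort
    from mirpair.synthio import CohortConfig, generate_mir_cohort

    cfg = CohortConfig(n_pairs_per_subtype=20, n_mirs=400, n_planted=0,
                       noise_sigma=0.5, n_replicated_samples=8,
                       subtypes=("HER2+",), seed=42)
    ds, truth = generate_mir_cohort(cfg)
    return preprocess_cohort(ds, lowess=False), truth, cfg


@pytest.fixture(scope="session")
def planted_cohort():
    """A fully-matched cohort with 5% planted miRs at effect 2x measurement SD."""
    from mirpair.cli import preprocess_cohort
    from mirpair.synthio import CohortConfig, generate_mir_cohort

    cfg = CohortConfig(n_pairs_per_subtype=20, n_mirs=400, n_planted=20,
                       effect_size=1.0, noise_sigma=0.5, n_replicated_samples=8,
                       subtypes=("HER2+",), seed=7)
    ds, truth = generate_mir_cohort(cfg)
    return preprocess_cohort(ds, lowess=False), truth, cfg
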