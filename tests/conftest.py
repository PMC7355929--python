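import numpy as np
import pytest

from oliveauth.feature_table import filter_blank_features, merge_duplicates
from oliveauth.pipeline import PipelineConfig, run_pipeline
from oliveauth.splitting import kennard_stone
from oliveauth.synthetic import SyntheticSpec, generate


@pytest.fixture(scope="session")
def bundle():
    """Default seeded synthetic study bundle (65 samples, 6 QC, 4 blanks)."""
    return generate(SyntheticSpec())


@pytest.fixture(scope="session")
def curated(bundle):
    """Blank-filtered, duplicate-merged default table."""
    return merge_duplicates(filter_blank_features(bundle.table))


@pytest.fixture(scope="session")
def split(curated):
    """Kennard-Stone 51/14 division of the curated default table."""
    return kennard_stone(curated, 51)


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """Full default pipeline run (including the 20-permutation test)."""
    out = tmp_path_factory.mktemp("pipeline")
    config = PipelineConfig(out_dir=str(out), seed=42, n_permutations=20)
    return run_pipeline(config)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
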