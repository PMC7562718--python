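import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture()
def small_config():
    """A scaled-down synthetic configuration for fast structural tests."""
    from phasiscan.synthetic import SyntheticConfig

    return SyntheticConfig(
        seed=11,
        n_transcripts=12,
        transcript_len_range=(700, 1100),
        n_intergenic=1,
        intergenic_len=6000,
        n_phas21=4,
        n_phas24=1,
        n_planted_targets=6,
    )


@pytest.fixture()
def small_run(small_config, tmp_path):
    from phasiscan.pipeline import PipelineConfig, run_pipeline

    cfg = PipelineConfig(synthetic=small_config, threshold_sweep=())
    return run_pipeline(cfg, tmp_path / "bundle")
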