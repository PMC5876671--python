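"""Shared fixtures: one default-scale pipeline run reused across tests."""

from pathlib import Path

import pytest
from hypothesis import settings

from litchi_hsi.pipeline import PipelineConfig, run_all

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_run(tmp_path_factory) -> tuple[PipelineConfig, Path]:
    """Full pipeline at default scale (120 modeling + 80 external samples)."""
    out = tmp_path_factory.mktemp("pipeline_default")
    cfg = PipelineConfig(seed=42, out_dir=str(out))
    run_all(cfg)
    return cfg, out


@pytest.fixture(scope="session")
def small_cfg_kwargs() -> dict:
    """Reduced problem size for tests that run the pipeline repeatedly."""
    return {
        "n_per_class": 4,
        "n_external_per_class": 2,
        "max_latent": 4,
        "gamma_grid": (100.0,),
        "sigma2_grid": (10.0,),
    }
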