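import numpy as np
import pandas as pd
import pytest

from hs27pipe.synthetic import GeneratorConfig, generate_cohort


def small_generator_config(**overrides) -> GeneratorConfig:
    """64x64 two-frame config: full model, cheap enough for unit tests."""
    defaults = dict(frame_height=64, frame_width=64, frames_per_biopsy=2)
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@pytest.fixture
def small_config() -> GeneratorConfig:
    return small_generator_config()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A 27/10/6 cohort at reduced frame size, shared across tests."""
    cfg = small_generator_config(frame_height=96, frame_width=96, frames_per_biopsy=3)
    return cfg, generate_cohort(cfg, seed=42)


def annotations_table(cohort) -> pd.DataFrame:
    rows = [
        {
            "biopsy_id": b.biopsy_id,
            "site": k,
            "cellularity": a.tumor_cellularity,
            "stromal_pct": a.stromal_percent,
            "til_pct": a.til_percent_of_stroma,
        }
        for b in cohort
        for k, a in enumerate(b.annotations)
    ]
    return pd.DataFrame(rows)
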