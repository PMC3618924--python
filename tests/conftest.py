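import numpy as np
import pytest

from mammica import study, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def smoke_patches():
    """Small density-graded patch set shared by pipeline-level tests."""
    cfg = synthetic.SyntheticConfig(
        seed=7, n_images_per_density=16, mass_fraction=0.5, image_side=160
    )
    return synthetic.generate_patch_dataset(cfg, patch_side=32, n_normal_per_image=1)


@pytest.fixture(scope="session")
def desk_study_summary():
    """One reduced density study, shared by the acceptance-level checks.

    4 density grades x ~150 patches (64 px), 10 ICA components, 10-fold CV,
    reduced classifier grids, both classifier families, all five strata.
    """
    config = study.make_config("desk", seed=1)
    return study.run_full_study(config)
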