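import numpy as np
import pytest

import sgascore as sg


@pytest.fixture
def rng():
    return np.random.default_rng(20170)


@pytest.fixture(scope="session")
def small_noisy_screen():
    """One control + one query, 200 strains, realistic noise and artifacts."""
    cfg = sg.ScreenSimConfig(
        n_strains=200,
        induction_effect_per_query=(1.0, 0.6),
        noise_cv=0.1,
        planted_fraction=0.05,
        planted_factor_ranges=((0.3, 0.5), (1.8, 2.2)),
        spatial_gradient_amplitude=0.3,
        outlier_prob=0.02,
        missing_prob=0.01,
        seed=11,
    )
    plates, layouts, truth = sg.generate_screen(cfg)
    return cfg, plates, layouts, truth


def uniform_grid(value=500.0, shape=(32, 48), **kw):
    kw.setdefault("plate_id", "p")
    kw.setdefault("query_id", "q")
    kw.setdefault("condition", "uninduced")
    kw.setdefault("medium", "")
    return sg.PlateGrid(area=np.full(shape, float(value)), **kw)
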