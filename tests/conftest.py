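import numpy as np
import pytest

from mgquant import synthetic as syn


@pytest.fixture(scope="session")
def small_stack_spec():
    """A quick-to-render stack: ~1 s total across the suite."""
    return syn.StackSpec(shape_xyz=(128, 128, 20), n_cells=5, min_separation=25.0)


@pytest.fixture(scope="session")
def default_slide():
    spec = syn.SlideSpec()
    rgb, truth = syn.generate_ihc_slide(spec, 11)
    return spec, rgb, truth


@pytest.fixture(scope="session")
def fish_slide_208():
    spec = syn.FishSpec(target_percent_area=2.08)
    sig, tissue, true_pct = syn.generate_fish_slide(spec, 5)
    return spec, sig, tissue, true_pct


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
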