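import numpy as np
import pytest

from adipo.synthetic import CohortTableSpec, TissueSpec, generate_cohort_table, generate_tissue_image


def small_spec(**kw) -> TissueSpec:
    """A quick-to-pack tissue spec for tests (384 px at 0.5 um/px)."""
    defaults = dict(
        width_px=384,
        height_px=384,
        um_per_px=0.5,
        max_attempts=15_000,
        seed=11,
    )
    defaults.update(kw)
    return TissueSpec(**defaults)


@pytest.fixture(scope="session")
def noisefree_tissue():
    spec = small_spec(noise_sd=0.0, speck_rate=0.0)
    return spec, *generate_tissue_image(spec)


@pytest.fixture(scope="session")
def noisy_tissue():
    spec = small_spec(seed=12)
    return spec, *generate_tissue_image(spec)


@pytest.fixture(scope="session")
def large_noisefree_tissue():
    """Big enough (~130 interior cells) for min-cell-count analyses."""
    spec = small_spec(
        width_px=768, height_px=768, noise_sd=0.0, speck_rate=0.0,
        max_attempts=40_000, seed=13,
    )
    return spec, *generate_tissue_image(spec)


@pytest.fixture(scope="session")
def study_table():
    """Cohort table drawn under the default study-emulation conditions."""
    return generate_cohort_table(CohortTableSpec.study_default(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
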