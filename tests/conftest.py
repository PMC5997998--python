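import numpy as np
import pytest

from phystate.descriptors import select_descriptor_sets
from phystate.simulate import SyntheticConfig, generate_full_study
from phystate.statespace import DescriptorProfile

#: canonical seed used throughout the repository's examples and tests
SEED = 1


@pytest.fixture
def profile_p() -> DescriptorProfile:
    """Worked-example profile: alpha {0.5, 1.0, 1.5}, beta {2.5, 3.0, 3.5};
    epsilon = +1, gap theta = 1.0 centered at 2.0."""
    return DescriptorProfile(
        gene_id="P",
        axis="diurnal",
        q2_alpha=1.0,
        q2_beta=3.0,
        min_alpha=0.5,
        max_alpha=1.5,
        min_beta=2.5,
        max_beta=3.5,
    )


@pytest.fixture(scope="session")
def default_study():
    """The default three-stage synthetic stress test (fixed seed)."""
    return generate_full_study(SyntheticConfig(seed=SEED))


@pytest.fixture(scope="session")
def default_sets(default_study):
    """Descriptor sets selected from the default study's stage 1."""
    return select_descriptor_sets(default_study.expr, default_study.meta)


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
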