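import numpy as np
import pytest

from codonbin import CommunitySpec, build_profile, generate_library


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_library():
    """A 6-species, 16-clone synthetic library with moderate clone depth."""
    spec = CommunitySpec(
        n_species=6,
        clones_per_species=[4, 3, 3, 2, 2, 2],
        codons_per_clone=(3_000, 6_000),
        target_distance_window=(0.08, 0.25),
        seed=42,
    )
    return generate_library(spec)


@pytest.fixture(scope="session")
def small_profiles(small_library):
    return [build_profile(r) for r in small_library.clone_records]
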