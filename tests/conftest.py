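import numpy as np
import pytest

import biofilmflow as bf
from biofilmflow.preprocess import filter_saturated, transform_sample


@pytest.fixture(scope="session")
def panel():
    return bf.build_default_panel()


@pytest.fixture(scope="session")
def profiles(panel):
    return bf.default_profiles(panel)


@pytest.fixture(scope="session")
def field_samples_small(panel):
    """Six field-analog samples, 5,000 events each, site D spiked at 1%."""
    samples = bf.field_analog_samples(n_per_site=5_000, seed=11,
                                      spike_site="D", spike_fraction=0.01,
                                      panel=panel)
    return [transform_sample(filter_saturated(s)[0]) for s in samples]


@pytest.fixture(scope="session")
def two_component_map(panel, profiles):
    """Map of two well-separated phenotypes, 2,000 points, bh engine."""
    spec = bf.CommunitySpec(((profiles["green_algae"], 0.5),
                             (profiles["microplastic"], 0.5)))
    sample, _ = bf.simulate_community(spec, 2_000, seed=7, panel=panel,
                                      sample_id="2comp")
    sample = transform_sample(sample)
    pool = bf.subsample_equal([sample], 2_000, seed=0)
    return bf.compute_visne(pool, seed=3, engine="bh")
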