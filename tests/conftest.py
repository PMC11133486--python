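import numpy as np
import pytest

import cohortwin as cw
from cohortwin.networks import NetConfig, build_model
from cohortwin.panel_schema import encode_batch


@pytest.fixture(scope="session")
def small_cohort():
    cohort, truth = cw.generate(cw.SynthConfig(n_patients=60, seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def small_split(small_cohort):
    cohort, _ = small_cohort
    return cw.split_cohort(cohort, 0.8, seed=5)


@pytest.fixture(scope="session")
def small_transform(small_split):
    train, _ = small_split
    return cw.fit_transform(train)


@pytest.fixture(scope="session")
def small_batch(small_split, small_transform):
    train, _ = small_split
    return encode_batch(train, small_transform)


@pytest.fixture()
def untrained_model(small_batch, small_transform):
    config = NetConfig(d_s=small_batch.s.shape[1], d_x=small_batch.x.shape[2],
                       d_hs=6, d_ht=12, seed=3)
    return build_model(config, small_transform)
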