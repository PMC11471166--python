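from __future__ import annotations

import numpy as np
import pytest

from pevol import BinaryMask, ProbabilityVolume


@pytest.fixture
def rng():
    return np.random.default_rng(20240919)


def prob_volume(data, spacing=(1.0, 1.0, 1.0), case_id="case"):
    affine = np.diag([*spacing, 1.0])
    return ProbabilityVolume(data=np.asarray(data, dtype=float), affine=affine,
                             case_id=case_id)


def binary_mask(data, spacing=(1.0, 1.0, 1.0), case_id="case"):
    affine = np.diag([*spacing, 1.0])
    return BinaryMask(data=np.asarray(data), affine=affine, case_id=case_id)


@pytest.fixture
def make_prob_volume():
    return prob_volume


@pytest.fixture
def make_mask():
    return binary_mask
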