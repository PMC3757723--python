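import numpy as np
import pytest

from tbmtools import (
    EffectSpec,
    RegistrationConfig,
    SubjectRecord,
    make_template_phantom,
    synthesize_subject_volume,
)


@pytest.fixture(scope="session")
def template32():
    return make_template_phantom((32, 32, 32))


@pytest.fixture(scope="session")
def template48():
    return make_template_phantom((48, 48, 48))


@pytest.fixture(scope="session")
def clean_effect():
    """Implanted deficit with no nuisance warp and no intensity noise."""
    return EffectSpec(nuisance_warp_mm=0.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def dose2_subject48(template48, clean_effect):
    """A dose-2 subject (-12% white-matter deficit), noiseless."""
    rec = SubjectRecord("T2", 2, 75.0, 1, homocysteine=11.7)
    return synthesize_subject_volume(template48, rec, clean_effect, seed=0)
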