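import numpy as np
import pytest

from cpts.synth import (GenerationConfig, generate_cohort, generate_profile)

COHORT_SEED = 7
COHORT_N = 20


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """20-participant synthetic cohort (10 AU-style, 10 NL-style), fixed seed.

    Temperature logs carry 0.3 degC measurement noise; all other streams are
    noise-free, so recovery errors reflect algorithmic quantisation, not
    tuning.
    """
    out = tmp_path_factory.mktemp("cohort")
    generate_cohort(COHORT_N, COHORT_SEED, out, n_au=COHORT_N // 2,
                    noise_sd_temperature=0.3)
    return out


@pytest.fixture(scope="session")
def cohort_manifest(cohort_dir):
    import json
    from cpts.synth import GroundTruthManifest
    return GroundTruthManifest.from_json_dict(
        json.loads((cohort_dir / "manifest.json").read_text()))


@pytest.fixture
def au_profile():
    return generate_profile(11, GenerationConfig.au_study())


@pytest.fixture
def nl_profile():
    return generate_profile(12, GenerationConfig.nl_study())


def fixed_profile(**overrides):
    """A profile with every generator target pinned, for analytic checks."""
    from cpts.synth import ParticipantProfile
    base = dict(
        id="FIX001", true_adherence=0.5, true_daily_strides=2000,
        pti_in_device=66.2, pti_non_device=72.2,
        ppp_in_device=140.6, ppp_non_device=178.7,
        tsr_in_device=0.66, tsr_non_device=1.45,
        wear_schedule=[(8.0, 20.0)], monitoring_days=6,
    )
    base.update(overrides)
    return ParticipantProfile(**base)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
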