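import numpy as np
import pytest

from myopassive import (BundleModel, ECMParams, FibreLawParams,
                        GeneratorConfig, VolumeFractions)

# parameters of the pooled fibre fit and printed study design, reused across tests
POOLED_FIBRE = dict(A=6.93, L0=2.44)
STUDY_FRACTIONS = (0.425, 0.425, 0.15)


@pytest.fixture
def pooled_fibre_params():
    return FibreLawParams(**POOLED_FIBRE)


@pytest.fixture
def study_fractions():
    return VolumeFractions(*STUDY_FRACTIONS)


@pytest.fixture
def bundle_model(pooled_fibre_params, study_fractions):
    """Bundle with pooled fibre law for both types and a moderate ECM."""
    return BundleModel(
        fast=pooled_fibre_params,
        slow=pooled_fibre_params,
        ecm=ECMParams(beta=13.9, k_v=5.0, L0b=1.60),
        fractions=study_fractions,
    )


@pytest.fixture
def noiseless_config():
    return GeneratorConfig(specimen_cv=0.0, noise_rel=0.0, noise_abs=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
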