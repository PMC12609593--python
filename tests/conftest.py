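import numpy as np
import pytest

from rdnacn import CohortSpec, DonorTruth, default_reference
from rdnacn.synth import simulate_reads


@pytest.fixture(scope="session")
def ref():
    return default_reference()


@pytest.fixture()
def donor():
    """A donor with a 50/50 active/inactive copy mixture."""
    return DonorTruth(
        sample_id="S001", group="NSP", true_abs_cn=236.0, true_active_fraction=0.5,
        active_mode_p=0.02, inactive_mode_p=0.60, age=39.0, bmi=26.0,
        volume_ml=3.0, conc_mio_per_ml=80.0, motility_pct=60.0,
        morphology_pct=8.0, pregnancy="yes",
    )


@pytest.fixture(scope="session")
def small_spec():
    """A desk-scale cohort for pipeline tests."""
    return CohortSpec(n_nsp=8, n_asp=8, n_unknown_pregnancy=1)


@pytest.fixture()
def clean_reads(donor, ref):
    """Error-free simulated reads with their truth sidecar."""
    return simulate_reads(
        donor, ref, n_reads=120, conversion_failure_rate=0.0,
        seq_error_rate=0.0, minor_allele_fraction=0.05, seed=11,
    )
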