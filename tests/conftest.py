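import pytest

from wardmon.synth import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Six-patient synthetic cohort shared across tests."""
    cfg = SynthConfig(n_patients=6, seed=11)
    device, nurse, episodes, truth = generate_cohort(cfg)
    return cfg, device, nurse, episodes, truth


@pytest.fixture(scope="session")
def clean_small_cohort(small_cohort):
    """QC-filtered view of the shared cohort."""
    from wardmon.qc import apply_qc

    cfg, device, nurse, episodes, truth = small_cohort
    clean, flags, rates = apply_qc(device)
    return cfg, clean, flags, nurse, episodes, truth
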