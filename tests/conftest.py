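import pytest

import trisskit as tk


@pytest.fixture(scope="session")
def library():
    return tk.default_library()


@pytest.fixture(scope="session")
def small_registry():
    """A modest default-parameter synthetic registry shared across tests."""
    params = tk.default_params(n=4000, seed=20260926)
    records, truth = tk.simulate_registry(params)
    return records, truth


@pytest.fixture
def healthy_patient():
    """Uninjured young patient with maximal physiology codes."""
    return tk.PatientRecord(
        patient_id="H1",
        site="SDEUA",
        age_years=30,
        mechanism="blunt",
        gcs_total=15,
        bmr=6,
        sbp_mmhg=120,
        rr_bpm=16,
        spo2_pct=99,
        injuries=(),
        survived=True,
    )
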