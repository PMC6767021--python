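import pytest

import triqrs as tq


@pytest.fixture(scope="session")
def cfg360() -> tq.DetectorConfig:
    return tq.derive_config(360)


@pytest.fixture(scope="session")
def clean_record():
    """60 s clean synthetic ECG at 60 bpm: exactly 60 ground-truth beats."""
    return tq.generate(60.0, 360.0, 60.0, 0.0, *tq.preset("clean"), seed=11)
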