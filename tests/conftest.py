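import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_openface_csv(tmp_path):
    """A small well-formed OpenFace-dialect CSV on disk."""
    def _make(rows, header="frame, timestamp, confidence, success, AU06_r, AU12_r",
              name="subj.csv"):
        path = tmp_path / name
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        return path
    return _make
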