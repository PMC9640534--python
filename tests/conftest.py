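import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_ped_map(tmp_path):
    """Hand-written 4-subject, 3-SNP PED/MAP pair."""
    map_text = (
        "17\trs1\t0\t43793600\n"
        "17\trs2\t0\t43900000\n"
        "17\trs3\t0\t44000000\n"
    )
    ped_text = (
        "F1 S1 0 0 1 2 A A C T 0 0\n"
        "F2 S2 0 0 2 0 A G T C G G\n"
        "F3 S3 0 0 1 3 A A C C G G\n"
        "F4 S4 0 0 2 1 G G T T G G\n"
    )
    ped = tmp_path / "toy.ped"
    mp = tmp_path / "toy.map"
    ped.write_text(ped_text)
    mp.write_text(map_text)
    return ped, mp
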