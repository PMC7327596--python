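import pytest

from gpworkload import base_case


@pytest.fixture
def telephone_base():
    return base_case("telephone")


@pytest.fixture
def econsult_base():
    return base_case("econsult")


@pytest.fixture
def video_base():
    return base_case("video")
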