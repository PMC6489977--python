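import pytest

from fdminer.testkit import example_relation


@pytest.fixture
def table():
    """The 7x5 worked-example relation (A <-> D, keys ABC / BCD / BCE)."""
    return example_relation()
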