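import pytest

from wuenic.config import Config
from wuenic.fixtures import egypt_fixture, scenario_figure3
from wuenic.knowledge_base import write_knowledge_base


@pytest.fixture
def config():
    return Config()


@pytest.fixture
def egypt_base():
    return egypt_fixture("base")


@pytest.fixture
def figure3():
    return scenario_figure3()


@pytest.fixture
def egypt_dir(tmp_path):
    """Egypt base knowledge base materialized as CSV files."""
    kb, expected = egypt_fixture("base")
    data_dir = tmp_path / "data"
    write_knowledge_base(kb, data_dir)
    return data_dir, expected
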