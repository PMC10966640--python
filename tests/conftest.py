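import pytest

from fragprop.fixtures import FIXTURE_NAMES, demo_queries, make_fixture
from fragprop.properties.basic import HeavyAtomsPlugin, MolWeightPlugin
from fragprop.properties.patterns import PatternSetPlugin
from fragprop.properties.rotbonds import RotatableBondsPlugin
from fragprop.properties.tpsa import TpsaPlugin


@pytest.fixture(scope="session")
def queries():
    return demo_queries()


@pytest.fixture(scope="session")
def pattern_plugin(queries):
    return PatternSetPlugin(queries)


@pytest.fixture(scope="session")
def all_plugins(pattern_plugin):
    return [
        HeavyAtomsPlugin(),
        MolWeightPlugin(),
        TpsaPlugin(),
        RotatableBondsPlugin(),
        pattern_plugin,
    ]


@pytest.fixture(scope="session")
def fixture_spaces():
    return {name: make_fixture(name) for name in FIXTURE_NAMES}


def tolerance_for(plugin_name: str) -> int:
    # one least-significant scaled unit for decimal-valued properties
    return 1 if plugin_name in ("tpsa", "mw", "tpsa_naive") else 0
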