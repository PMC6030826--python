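import pytest

from pathglyph.fixtures import make_fig1_fixture, make_fig4_fixture
from pathglyph.overlay import merge
from pathglyph.quadtree import index_layout


@pytest.fixture(scope="session")
def fig1_pair():
    return make_fig1_fixture()


@pytest.fixture(scope="session")
def fig1_context(fig1_pair):
    return merge(*fig1_pair)


@pytest.fixture(scope="session")
def fig4_layout():
    layout, probe = make_fig4_fixture()
    return layout, probe


@pytest.fixture()
def fig4_tree(fig4_layout):
    layout, probe = fig4_layout
    return index_layout(layout, capacity=2), probe
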