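import pytest

from nodeglyphs import NodeRecord, generate_fixture

WORKED_HEATSTRIP = (
    'heatstripchart: attributelist="gal1RGexp,gal4RGexp,gal80Rexp" '
    'colorlist="yellowblue" range="-3.0,3.0"'
)


@pytest.fixture
def expression_node():
    """A node carrying the three expression columns at the range extremes."""
    return NodeRecord(
        "YBR020W",
        scalars={"gal1RGexp": -3.0, "gal4RGexp": 0.0, "gal80Rexp": 3.0},
    )


@pytest.fixture
def gallery():
    return generate_fixture("gallery", n_nodes=9, seed=7)


@pytest.fixture
def expression():
    return generate_fixture("expression", n_nodes=12, seed=7)
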