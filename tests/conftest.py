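import pytest

import netloci as nl


@pytest.fixture(scope="session")
def toys():
    return nl.toy_graphs()


@pytest.fixture(scope="session")
def table2():
    return nl.table2_fixture()


@pytest.fixture(scope="session")
def small_planted():
    """Default planted synthetic network (seed 1) with whole-graph metrics."""
    net, genes = nl.plant_disease_genes(nl.GeneratorSpec(seed=1))
    lookup = {m.gene: m for m in nl.compute_all_metrics(net)}
    return net, genes, lookup
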