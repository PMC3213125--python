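import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_topology(rng, labels):
    """Random unrooted binary tree over labels with Exp(1) branch lengths."""
    import dendropy

    ns = dendropy.TaxonNamespace(sorted(labels))
    nodes = [dendropy.Node(taxon=ns.get_taxon(l)) for l in sorted(labels)]
    for node in nodes:
        node.edge.length = float(rng.exponential(1.0)) + 1e-3
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.exponential(1.0)) + 1e-3
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    seed = dendropy.Node()
    for n in nodes:
        seed.add_child(n)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = seed
    tree.is_rooted = False
    return tree
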