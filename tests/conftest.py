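import dendropy
import numpy as np
import pandas as pd
import pytest

from evoscreen import SimulationConfig


@pytest.fixture
def small_tree() -> dendropy.Tree:
    """((A:1.0,B:2.0):0.5,C:3.0); — the worked three-tip example."""
    return dendropy.Tree.get(
        data="((A:1.0,B:2.0):0.5,C:3.0);", schema="newick",
        preserve_underscores=True,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240101)


def star_tree(n: int, depth: float = 1.0) -> dendropy.Tree:
    """A star phylogeny: every tip attached directly to the root."""
    taxa = dendropy.TaxonNamespace([f"S{i}" for i in range(n)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    for i in range(n):
        child = tree.seed_node.new_child()
        child.edge.length = depth
        child.taxon = taxa[i]
    return tree


def random_binary_tree(n: int, rng: np.random.Generator) -> dendropy.Tree:
    """Random non-ultrametric binary tree with positive branch lengths."""
    taxa = dendropy.TaxonNamespace([f"S{i}" for i in range(n)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = [tree.seed_node.new_child(), tree.seed_node.new_child()]
    while len(nodes) < n:
        node = nodes.pop(int(rng.integers(len(nodes))))
        nodes.append(node.new_child())
        nodes.append(node.new_child())
    for i, leaf in enumerate(nodes):
        leaf.taxon = taxa[i]
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None:
            edge.length = float(rng.uniform(0.05, 2.0))
    return tree


def expression_matrix_from_arrays(values, gene_ids, groups, n_reps, unit):
    """Build an ExpressionMatrix from a raw array and a simple design."""
    from evoscreen import ExpressionMatrix

    design = pd.DataFrame(
        [
            {"sample_id": f"{g}_{r}", "group": g, "replicate": r}
            for g in groups
            for r in range(1, n_reps + 1)
        ]
    )
    df = pd.DataFrame(values, index=gene_ids, columns=design["sample_id"])
    return ExpressionMatrix(df, design, unit=unit)
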