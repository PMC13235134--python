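import numpy as np
import pytest

from biodrp import SyntheticSpec, generate_dataset
from biodrp.evaluation import prepare_model_inputs
from biodrp.hierarchy import BioHierarchy


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale benchmark spec shared across tests (64-bit fingerprints
    keep the output layer small)."""
    return SyntheticSpec(n_cells=40, n_genes=24, n_proteins=10, n_pathways=6,
                         n_drugs=4, n_driver_genes=4, fingerprint_bits=64,
                         signal_strength=4.0, noise_sd=0.3, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec)


@pytest.fixture(scope="session")
def small_inputs(small_dataset):
    """(features, masks, pruned hierarchy) for the small dataset."""
    return prepare_model_inputs(small_dataset.bundle)


@pytest.fixture(scope="session")
def easy_dataset():
    """Strong planted signal, zero noise, and a complete pathway->drug layer.

    The network's readout is additive in (cell, drug) — cell features pass
    through the masked layers without seeing the drug — so an *easy*
    benchmark must plant a signal inside that model class: with every
    pathway wired to every drug, all drivers reach all drugs and the
    planted score decomposes as cell effect + drug effect.
    """
    spec = SyntheticSpec(n_cells=250, n_drugs=8, signal_strength=6.0,
                         noise_sd=0.0, edge_density_pk=0.6,
                         edge_density_kd=1.0, fingerprint_bits=256, seed=7)
    return generate_dataset(spec)


def random_hierarchy(rng: np.random.Generator, n_g=8, n_p=5, n_k=4, n_d=3,
                     density=0.35) -> BioHierarchy:
    """Random (possibly disconnected) hierarchy for pruning tests."""
    genes = [f"g{i}" for i in range(n_g)]
    prots = [f"p{i}" for i in range(n_p)]
    paths = [f"k{i}" for i in range(n_k)]
    drugs = [f"d{i}" for i in range(n_d)]

    def wire(src, tgt):
        return {(s, t) for s in src for t in tgt if rng.random() < density}

    return BioHierarchy(genes=genes, proteins=prots, pathways=paths, drugs=drugs,
                        edges_gp=wire(genes, prots), edges_pk=wire(prots, paths),
                        edges_kd=wire(paths, drugs))


def bfs_full_path_nodes(h: BioHierarchy) -> set[str]:
    """Independent oracle: nodes on a complete gene->drug path, via
    networkx breadth-first search over the layered digraph."""
    import networkx as nx

    G = nx.DiGraph()
    G.add_nodes_from(("G", g) for g in h.genes)
    G.add_nodes_from(("P", p) for p in h.proteins)
    G.add_nodes_from(("K", k) for k in h.pathways)
    G.add_nodes_from(("D", d) for d in h.drugs)
    G.add_edges_from((("G", g), ("P", p)) for (g, p) in h.edges_gp)
    G.add_edges_from((("P", p), ("K", k)) for (p, k) in h.edges_pk)
    G.add_edges_from((("K", k), ("D", d)) for (k, d) in h.edges_kd)

    fwd = set()
    for g in h.genes:
        fwd |= {("G", g)} | nx.descendants(G, ("G", g))
    bwd = set()
    for d in h.drugs:
        if ("D", d) in fwd:
            bwd |= {("D", d)} | nx.ancestors(G, ("D", d))
    on_path = set()
    for kind, name in fwd & bwd:
        # a node is on a full path iff it reaches a drug AND is reached
        # from a gene AND those two facts chain through it
        node = (kind, name)
        reaches_drug = kind == "D" or any(
            ("D", d) in nx.descendants(G, node) for d in h.drugs)
        from_gene = kind == "G" or any(
            node in nx.descendants(G, ("G", g)) for g in h.genes)
        if reaches_drug and from_gene:
            on_path.add(name)
    return on_path
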