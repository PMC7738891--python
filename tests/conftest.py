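import numpy as np
import pandas as pd
import pytest

from dcmir import synth


@pytest.fixture(scope="session")
def small_config():
    return synth.SynthConfig(n_genes=80, n_mirnas=12, seed=11)


@pytest.fixture(scope="session")
def small_data(small_config):
    gene_counts, mirna_counts, sheet, truth = synth.generate_counts(
        small_config
    )
    return {
        "gene_counts": gene_counts,
        "mirna_counts": mirna_counts,
        "sheet": sheet,
        "truth": truth,
    }


@pytest.fixture
def paired_sheet():
    def make(n_donors: int) -> pd.DataFrame:
        rows = []
        for d in range(1, n_donors + 1):
            rows.append((f"D{d}_control", f"D{d}", "control"))
            rows.append((f"D{d}_treated", f"D{d}", "treated"))
        return pd.DataFrame(rows,
                            columns=["sample_id", "donor", "condition"])
    return make


def random_weighted_graph(rng: np.random.Generator, n_max: int = 12):
    """Connected weighted graph with node weights, for oracle checks."""
    import networkx as nx

    n = int(rng.integers(3, n_max + 1))
    G = nx.Graph()
    names = [f"n{i}" for i in range(n)]
    for i, name in enumerate(names):
        cls = "miRNA" if i % 3 == 0 else "protein_coding"
        G.add_node(name, **{"class": cls,
                            "weight": float(rng.uniform(0, 5))})
    # random spanning tree keeps it connected, then extra edges
    order = rng.permutation(n)
    for i in range(1, n):
        a, b = names[order[i]], names[order[int(rng.integers(0, i))]]
        rho = float(rng.uniform(0.05, 0.95))
        G.add_edge(a, b, rho=rho, length=1.0 - rho, type="activation")
    n_extra = int(rng.integers(0, n))
    for _ in range(n_extra):
        i, j = rng.integers(0, n, size=2)
        if i == j or G.has_edge(names[i], names[j]):
            continue
        rho = float(rng.uniform(0.05, 0.95))
        G.add_edge(names[i], names[j], rho=rho, length=1.0 - rho,
                   type="activation")
    return G
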