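import numpy as np
import pytest

from scamnet import FeatureSpec, ModelConfig, init_params, parse_smiles, to_graph


@pytest.fixture(scope="session")
def spec():
    return FeatureSpec()


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale model used by most tests: small but structurally complete."""
    return ModelConfig(num_layers=2, hidden_dim=16, final_widths=(16, 8, 2))


@pytest.fixture(scope="session")
def small_params(small_config, spec):
    return init_params(small_config, spec, seed=0)


@pytest.fixture(scope="session")
def molecules():
    smiles = [
        "C",
        "CC",
        "CCO",
        "c1ccccc1",
        "Oc1ccccn1",
        "Oc1cccnc1",
        "CC(=O)O",
        "Oc1c(I)cc(Cl)c2cccnc12",
        "CCN(CC)CC",
        "O=C(OC)c1ccc(O)nc1",
    ]
    return [parse_smiles(s) for s in smiles]


@pytest.fixture(scope="session")
def graphs(molecules, spec):
    return [to_graph(m, spec) for m in molecules]


def random_graph(rng: np.random.Generator, spec: FeatureSpec):
    """A random connected valid-shape featurized graph (not necessarily a
    chemically valid molecule) for pure tensor-level tests."""
    from scamnet import FeaturizedGraph

    n = int(rng.integers(1, 12))
    X = np.zeros((n, spec.node_dim))
    X[np.arange(n), rng.integers(0, len(spec.elements), size=n)] = 1.0
    X[:, len(spec.elements)] = rng.integers(1, 4, size=n)
    edges = []
    feats = []
    for j in range(1, n):  # random spanning tree keeps it connected
        i = int(rng.integers(0, j))
        ef = np.zeros(spec.edge_dim)
        ef[rng.integers(0, 4)] = 1.0
        edges += [(i, j), (j, i)]
        feats += [ef, ef]
    return FeaturizedGraph(
        node_features=X,
        edge_index=np.array(edges, dtype=np.int64) if edges else np.zeros((0, 2), dtype=np.int64),
        edge_features=np.array(feats) if feats else np.zeros((0, spec.edge_dim)),
    )
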