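import json

import numpy as np
import pytest

from gatfp.msio import FragmentNode, FragmentationTree
from gatfp.synthetic_data import make_toy_fixture


@pytest.fixture(scope="session")
def toy_corpus():
    """Fixed 3-tree, 4-fragment corpus with hand-checkable statistics."""
    return make_toy_fixture()


def random_tree(rng: np.random.Generator, sample_id: str, n_nodes: int,
                formulas: list[dict] | None = None) -> FragmentationTree:
    """Small random rooted tree over a CHO fragment pool."""
    if formulas is None:
        formulas = [
            {"C": int(rng.integers(1, 6)), "H": int(rng.integers(1, 8)),
             "O": int(rng.integers(0, 3)) or 1}
            for _ in range(n_nodes)
        ]
    inten = rng.uniform(0.05, 1.0, size=n_nodes)
    inten /= inten.max()
    nodes = [
        FragmentNode(node_id=k, formula=formulas[k],
                     mz=10.0 + 12 * sum(formulas[k].values()) + rng.uniform(0, 1),
                     rel_intensity=float(inten[k]))
        for k in range(n_nodes)
    ]
    edges = [(int(rng.integers(0, k)), k) for k in range(1, n_nodes)]
    return FragmentationTree(sample_id=sample_id, nodes=nodes, edges=edges,
                             precursor_mass=nodes[0].mz,
                             precursor_formula=dict(nodes[0].formula))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def sirius_tree_file(tmp_path):
    """A 3-fragment chain tree in SIRIUS-style JSON."""
    doc = {
        "fragments": [
            {"id": 0, "molecularFormula": "C6H12O6", "mz": 180.063,
             "relativeIntensity": 0.8},
            {"id": 1, "molecularFormula": "C5H8O4", "mz": 132.042,
             "relativeIntensity": 0.4},
            {"id": 2, "molecularFormula": "C2H4O2", "mz": 60.021,
             "relativeIntensity": 0.1},
        ],
        "losses": [{"source": 0, "target": 1}, {"source": 1, "target": 2}],
        "precursorMass": 180.063,
        "precursorFormula": "C6H12O6",
    }
    p = tmp_path / "chain.json"
    p.write_text(json.dumps(doc))
    return p
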