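import warnings

import numpy as np
import pandas as pd
import pytest

from abtau_modnet.containers import Abundance, Embedding, WeightedNetwork
from abtau_modnet.synthio import SynthConfig


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """The generators and estimators emit informational UserWarnings
    (dropped columns, coarse bins); keep test output readable."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def default_config() -> SynthConfig:
    return SynthConfig(seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_abundance(rng) -> Abundance:
    """20 samples x 8 proteins of iid noise with mixed diagnoses."""
    samples = [f"S{i:02d}" for i in range(20)]
    proteins = [f"G{j}" for j in range(8)]
    values = pd.DataFrame(rng.normal(10, 1, (20, 8)), index=samples, columns=proteins)
    meta = pd.DataFrame(
        {
            "diagnosis": ["MCI", "AD-dementia", "NCI", "other"] * 5,
            "mmse": list(range(15, 35)),
        },
        index=samples,
    )
    meta["mmse"] = meta["mmse"].clip(0, 30)
    return Abundance(values=values, meta=meta)


def clique_edges(nodes, w=1.0):
    return [
        {"node_a": a, "node_b": b, "weight": w}
        for i, a in enumerate(nodes)
        for b in nodes[i + 1 :]
    ]


@pytest.fixture
def two_clique_network() -> WeightedNetwork:
    """Two 5-cliques joined by one weak edge."""
    A = [f"A{i}" for i in range(5)]
    B = [f"B{i}" for i in range(5)]
    edges = clique_edges(A) + clique_edges(B) + [{"node_a": "A0", "node_b": "B0", "weight": 0.1}]
    return WeightedNetwork(nodes=A + B, edges=pd.DataFrame(edges))


@pytest.fixture
def random_embedding(rng) -> Embedding:
    names = [f"N{i:03d}" for i in range(30)]
    feats = pd.DataFrame(rng.normal(size=(30, 5)), index=names, columns=[f"f{j+1}" for j in range(5)])
    return Embedding(features=feats, zscored=False)
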