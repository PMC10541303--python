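import numpy as np
import pandas as pd
import pytest

from phytonet.drug_likeness import score_compounds


def random_adjacency(rng: np.random.Generator, n_nodes: int, p: float) -> dict[str, set[str]]:
    """Symmetric adjacency mapping of an Erdős–Rényi graph on named nodes."""
    nodes = [f"N{i}" for i in range(n_nodes)]
    adj: dict[str, set[str]] = {v: set() for v in nodes}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                adj[nodes[i]].add(nodes[j])
                adj[nodes[j]].add(nodes[i])
    return adj


@pytest.fixture
def toy_compounds() -> pd.DataFrame:
    """Five-compound table with a duplicate appearing under two herbs."""
    rows = [
        # id, name, herbs, mw, alogp, hba, hbd, psa, rotb, arom, alerts, ob
        ("C1", "aspirin-like", "HerbA", 180.16, 1.2, 4, 1, 63.6, 2, 1, 0, True),
        ("C2", "greasy", "HerbA", 610.0, 7.5, 2, 0, 20.0, 14, 3, 2, False),
        ("C3", "ok-but-no-ob", "HerbB", 320.0, 2.0, 5, 2, 80.0, 4, 2, 0, False),
        ("C4", "dup", "HerbB", 250.0, 1.8, 3, 1, 55.0, 3, 1, 0, True),
        ("C4", "dup", "HerbC", 250.0, 1.8, 3, 1, 55.0, 3, 1, 0, True),
    ]
    df = pd.DataFrame(
        rows,
        columns=["compound_id", "name", "herbs", "mw", "alogp", "hba", "hbd",
                 "psa", "rotb", "arom", "alerts", "ob"],
    )
    df.insert(3, "formula", "")
    df.insert(4, "smiles", "")
    return score_compounds(df)
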