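import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from reladyn.tracks import Track


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_track(values, dt=10.0, t0_index=None, **meta):
    """Build a Track whose grid places t=0 at ``t0_index`` (default: start)."""
    values = np.asarray(values, dtype=float)
    start = -dt * t0_index if t0_index else 0.0
    times = start + dt * np.arange(len(values))
    return Track(times=times, values=values, **meta)


def enumerate_dags(nodes):
    """All DAGs over ``nodes`` (25 for three nodes): brute-force oracle."""
    pairs = list(itertools.combinations(nodes, 2))
    for states in itertools.product((0, 1, 2), repeat=len(pairs)):
        arcs = []
        for (u, v), s in zip(pairs, states):
            if s == 1:
                arcs.append((u, v))
            elif s == 2:
                arcs.append((v, u))
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(arcs)
        if nx.is_directed_acyclic_graph(g):
            yield arcs


def adjusted_rand_index(labels_a, labels_b):
    from sklearn.metrics import adjusted_rand_score

    return adjusted_rand_score(np.asarray(labels_a), np.asarray(labels_b))


@pytest.fixture
def sirna_auc_table():
    """Small AUC table with NT reference and a target siRNA, two strata."""
    rows = []
    for rep in ("R1", "R2"):
        for sirna, aucs in (("NT", [2.0, 4.0]), ("GENEX", [3.0, 9.0])):
            for i, a in enumerate(aucs):
                rows.append({
                    "cell_line": "MIAPaCa2", "bio_rep": rep, "sirna": sirna,
                    "treatment": "TNFa", "well": f"W{i}", "auc": a,
                })
    return pd.DataFrame(rows)
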