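"""Directed Gaussian dependency networks over single-cell feature tables.

Heterogeneous single-cell imaging data — nuclear RELA intensity alongside
cytoskeletal and cell-shape measurements — carry statistical dependencies
that can be summarised as a Bayesian network: a directed acyclic graph
(DAG) in which an arc ``u -> v`` means ``v``'s conditional distribution
depends on ``u``. This module learns such networks with a hybrid
restrict/maximise strategy:

1. *Restrict*: a constraint-based phase prunes the candidate skeleton
   using Fisher-z partial-correlation independence tests with conditioning
   sets up to a configurable size.
2. *Maximise*: greedy hill climbing over arc additions, deletions and
   reversals confined to the restricted skeleton, maximising the Gaussian
   BIC, with acyclicity enforced at every move and lexicographic
   tie-breaking so the result is a deterministic function of the input.

Arc strengths are per-observation BIC deltas on arc removal (negative =
removal worsens the fit, i.e. a strong arc).  Dependency matrices collect,
per data context, the signed ``log2(|strength|)`` of every arc touching the
nuclear-RELA node, with the sign encoding orientation.  Recovery against a
planted truth is scored on the Markov equivalence class (CPDAG), because a
single covariance-equivalent arc reversal is not an error.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RELA_NODE",
    "METADATA_COLUMNS",
    "NetworkConfig",
    "NetworkModel",
    "RecoveryReport",
    "balanced_subsample",
    "learn_network",
    "arc_strengths",
    "rela_dependency_matrix",
    "compare_to_truth",
    "cpdag",
    "structural_hamming_distance",
]

#: Canonical name of the nuclear RELA mean-intensity node.
RELA_NODE = "nuc_rela_mean"

#: Columns treated as stratification metadata, never as network nodes.
METADATA_COLUMNS = (
    "cell_id", "cell_line", "sirna", "treatment", "dose_ng_ml",
    "bio_rep", "well", "time_min",
)

_EPS = 1e-10  # minimum strict score improvement accepted by hill climbing


@dataclass(frozen=True)
class NetworkConfig:
    """Settings for hybrid structure learning.

    restrict_alpha
        Significance level of the Fisher-z partial-correlation tests in the
        constraint phase (an edge survives only if every test rejects
        independence).
    max_sepset_size
        Largest conditioning-set cardinality tried when attempting to
        separate a pair of nodes.
    seed
        Recorded for provenance; the learner itself is deterministic.
    """

    restrict_alpha: float = 0.05
    max_sepset_size: int = 3
    score: str = "bic-g"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.restrict_alpha < 1:
            raise ValueError("restrict_alpha must lie in (0, 1)")
        if self.max_sepset_size < 0:
            raise ValueError("max_sepset_size must be >= 0")
        if self.score != "bic-g":
            raise ValueError(f"unsupported score: {self.score!r}")


@dataclass
class NetworkModel:
    """A learned (or planted) DAG with optional per-arc strengths."""

    nodes: list[str]
    arcs: list[tuple[str, str]]
    strengths: dict[tuple[str, str], float] | None = None
    config: NetworkConfig | None = None

    def __post_init__(self) -> None:
        self.arcs = [tuple(a) for a in self.arcs]
        node_set = set(self.nodes)
        for u, v in self.arcs:
            if u not in node_set or v not in node_set:
                raise ValueError(f"arc endpoint not in node set: {(u, v)}")
        if len(set(self.arcs)) != len(self.arcs):
            raise ValueError("duplicate arcs")
        g = nx.DiGraph(self.arcs)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("arc set contains a cycle")

    def parents(self, node: str) -> list[str]:
        return sorted(u for u, v in self.arcs if v == node)

    def children(self, node: str) -> list[str]:
        return sorted(v for u, v in self.arcs if u == node)

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "nodes": list(self.nodes),
            "arcs": [list(a) for a in sorted(self.arcs)],
        }
        if self.strengths is not None:
            d["strengths"] = {f"{u}->{v}": s for (u, v), s in sorted(self.strengths.items())}
        if self.config is not None:
            d["config"] = asdict(self.config)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkModel":
        if d.get("kind") == "network":  # truth-file wrapper
            d = d["data"]
        strengths = None
        if "strengths" in d:
            strengths = {}
            for key, s in d["strengths"].items():
                u, v = key.split("->")
                strengths[(u, v)] = s
        config = NetworkConfig(**d["config"]) if "config" in d else None
        return cls(
            nodes=list(d["nodes"]),
            arcs=[tuple(a) for a in d["arcs"]],
            strengths=strengths,
            config=config,
        )

    @classmethod
    def from_json(cls, path) -> "NetworkModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dot(self) -> str:
        lines = ["digraph dependency_network {"]
        for node in self.nodes:
            lines.append(f'  "{node}";')
        for u, v in sorted(self.arcs):
            if self.strengths and (u, v) in self.strengths:
                lines.append(f'  "{u}" -> "{v}" [label="{self.strengths[(u, v)]:.4g}"];')
            else:
                lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        return "\n".join(lines) + "\n"


@dataclass
class RecoveryReport:
    """Structure-recovery metrics of a learned DAG against a planted truth."""

    shd: int
    skeleton_precision: float
    skeleton_recall: float
    orientation_precision: float
    orientation_recall: float
    n_arcs_true: int
    n_arcs_learned: int

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Stratified subsampling
# ---------------------------------------------------------------------------

def balanced_subsample(
    table: pd.DataFrame,
    strata: tuple[str, ...] = ("cell_line", "dose_ng_ml", "bio_rep"),
    n: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sample ``n`` cells per stratum without replacement.

    Strata smaller than ``n`` are kept in full with a warning; cells are
    never upsampled.  With a fixed seed the selection is deterministic
    regardless of traversal order, because each stratum draws from its own
    child generator spawned in sorted-key order.
    """
    missing = [c for c in strata if c not in table.columns]
    if missing:
        raise KeyError(f"strata columns absent from table: {missing}")
    rng = np.random.default_rng(seed)
    keys = sorted(table.groupby(list(strata), sort=True).groups.items(),
                  key=lambda kv: str(kv[0]))
    chunks = []
    for key, idx in keys:
        idx = np.asarray(sorted(idx))
        if len(idx) <= n:
            if len(idx) < n:
                warnings.warn(
                    f"stratum {key} has {len(idx)} < {n} cells; keeping all",
                    stacklevel=2,
                )
            chunks.append(idx)
        else:
            chunks.append(np.sort(rng.choice(idx, size=n, replace=False)))
    return table.loc[np.concatenate(chunks)]


# ---------------------------------------------------------------------------
# Gaussian BIC scoring
# ---------------------------------------------------------------------------

class GaussianBICScorer:
    """Decomposable Gaussian BIC over a fixed data matrix.

    Per node: ``loglik(node | parents) - k/2 * log(n)`` with
    ``k = |parents| + 2`` (regression coefficients, intercept and residual
    variance).  Residual variances come from the ML covariance matrix, so a
    node score is a cheap Schur complement rather than a fresh regression.
    """

    def __init__(self, table: pd.DataFrame, nodes: list[str]):
        X = table[nodes].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError("table contains undefined values; impute or drop first")
        self.n = X.shape[0]
        self.nodes = list(nodes)
        self._idx = {name: i for i, name in enumerate(nodes)}
        self.cov = np.cov(X.T, ddof=0)
        sd = np.sqrt(np.diag(self.cov))
        if np.any(sd <= 0):
            bad = [nodes[i] for i in np.flatnonzero(sd <= 0)]
            raise ValueError(f"constant node(s): {bad}")
        corr = self.cov / np.outer(sd, sd)
        if np.min(np.linalg.eigvalsh(corr)) < 1e-10:
            raise ValueError(
                "singular covariance: de-duplicate or drop collinear features"
            )
        self.corr = corr
        self._cache: dict[tuple, float] = {}

    def node_score(self, node: str, parents: tuple[str, ...] | list[str]) -> float:
        key = (node, tuple(sorted(parents)))
        if key in self._cache:
            return self._cache[key]
        i = self._idx[node]
        if parents:
            p = [self._idx[q] for q in key[1]]
            cpp = self.cov[np.ix_(p, p)]
            cpn = self.cov[p, i]
            sigma2 = self.cov[i, i] - cpn @ np.linalg.solve(cpp, cpn)
        else:
            sigma2 = self.cov[i, i]
        sigma2 = max(float(sigma2), 1e-300)
        loglik = -0.5 * self.n * (math.log(2 * math.pi * sigma2) + 1.0)
        k = len(parents) + 2
        score = loglik - 0.5 * k * math.log(self.n)
        self._cache[key] = score
        return score

    def total_score(self, arcs: list[tuple[str, str]]) -> float:
        parents: dict[str, list[str]] = {v: [] for v in self.nodes}
        for u, v in arcs:
            parents[v].append(u)
        return sum(self.node_score(v, ps) for v, ps in parents.items())


# ---------------------------------------------------------------------------
# Restrict phase: Fisher-z partial-correlation skeleton
# ---------------------------------------------------------------------------

def _fisher_z_pvalue(corr: np.ndarray, n: int, i: int, j: int, S: tuple[int, ...]) -> float:
    idx = [i, j, *S]
    sub = corr[np.ix_(idx, idx)]
    prec = np.linalg.pinv(sub)
    denom = math.sqrt(abs(prec[0, 0] * prec[1, 1]))
    r = 0.0 if denom == 0 else -prec[0, 1] / denom
    r = min(max(r, -1 + 1e-12), 1 - 1e-12)
    dof = n - len(S) - 3
    if dof <= 0:
        return 1.0
    z = 0.5 * math.log((1 + r) / (1 - r)) * math.sqrt(dof)
    return 2 * stats.norm.sf(abs(z))


def _restrict_skeleton(
    corr: np.ndarray, n: int, nodes: list[str], alpha: float, max_sepset: int
) -> set[frozenset[str]]:
    """Candidate skeleton by iterative conditional-independence pruning.

    Classic PC-style deletion: an edge i-j is removed as soon as some
    conditioning set S drawn from the current neighbourhood of i or of j
    (|S| grows from 0 to ``max_sepset``) fails to reject independence.
    Traversal order is lexicographic throughout, so the result is
    deterministic; the surviving adjacencies are symmetric by construction.
    """
    p = len(nodes)
    adj: dict[int, set[int]] = {i: set(range(p)) - {i} for i in range(p)}
    for level in range(max_sepset + 1):
        pairs = [(i, j) for i in range(p) for j in range(i + 1, p) if j in adj[i]]
        for i, j in pairs:
            if j not in adj[i]:
                continue
            removed = False
            for base in (sorted(adj[i] - {j}), sorted(adj[j] - {i})):
                if removed or len(base) < level:
                    continue
                for S in itertools.combinations(base, level):
                    if _fisher_z_pvalue(corr, n, i, j, S) > alpha:
                        adj[i].discard(j)
                        adj[j].discard(i)
                        removed = True
                        break
                if removed:
                    break
    return {
        frozenset((nodes[i], nodes[j]))
        for i in range(p) for j in adj[i] if i < j
    }


# ---------------------------------------------------------------------------
# Maximise phase: hill climbing within the restricted skeleton
# ---------------------------------------------------------------------------

def _creates_cycle(arcs: set[tuple[str, str]], candidate: tuple[str, str]) -> bool:
    g = nx.DiGraph(list(arcs))
    g.add_edge(*candidate)
    return not nx.is_directed_acyclic_graph(g)


def _hill_climb(
    scorer: GaussianBICScorer,
    skeleton: set[frozenset[str]],
    nodes: list[str],
) -> list[tuple[str, str]]:
    allowed = sorted(
        {(u, v) for pair in skeleton for u, v in itertools.permutations(sorted(pair))}
    )
    arcs: set[tuple[str, str]] = set()
    parents: dict[str, tuple[str, ...]] = {v: () for v in nodes}

    def delta_set_parents(v: str, new_parents: tuple[str, ...]) -> float:
        return scorer.node_score(v, new_parents) - scorer.node_score(v, parents[v])

    while True:
        best: tuple[float, str, tuple[str, str]] | None = None
        for u, v in allowed:
            arc = (u, v)
            if arc not in arcs and (v, u) not in arcs:
                if _creates_cycle(arcs, arc):
                    continue
                d = delta_set_parents(v, tuple(sorted((*parents[v], u))))
                move = ("add", arc, d)
            elif arc in arcs:
                d = delta_set_parents(v, tuple(p for p in parents[v] if p != u))
                move = ("delete", arc, d)
            else:
                continue
            kind, arc, d = move
            if d > _EPS and (best is None or d > best[0] + _EPS):
                best = (d, kind, arc)
        # reversals, in the same lexicographic (from, to) order of the arc reversed
        for u, v in allowed:
            if (v, u) not in arcs:
                continue
            without = {a for a in arcs if a != (v, u)}
            if _creates_cycle(without, (u, v)):
                continue
            d = (
                scorer.node_score(v, tuple(sorted((*parents[v], u))))
                - scorer.node_score(v, parents[v])
                + scorer.node_score(u, tuple(p for p in parents[u] if p != v))
                - scorer.node_score(u, parents[u])
            )
            if d > _EPS and (best is None or d > best[0] + _EPS):
                best = (d, "reverse", (v, u))
        if best is None:
            break
        _, kind, arc = best
        u, v = arc
        if kind == "add":
            arcs.add(arc)
        elif kind == "delete":
            arcs.discard(arc)
        else:  # reverse u->v into v->u
            arcs.discard(arc)
            arcs.add((v, u))
        parents = {w: () for w in nodes}
        tmp: dict[str, list[str]] = {w: [] for w in nodes}
        for a, b in arcs:
            tmp[b].append(a)
        parents = {w: tuple(sorted(ps)) for w, ps in tmp.items()}
        assert nx.is_directed_acyclic_graph(nx.DiGraph(list(arcs)))
    return sorted(arcs)


def _infer_nodes(table: pd.DataFrame) -> list[str]:
    nodes = [
        c for c in table.columns
        if c not in METADATA_COLUMNS and pd.api.types.is_numeric_dtype(table[c])
    ]
    if not nodes:
        raise ValueError("no numeric feature columns found")
    return nodes


def learn_network(
    table: pd.DataFrame,
    config: NetworkConfig | None = None,
    nodes: list[str] | None = None,
) -> NetworkModel:
    """Learn a DAG over the feature columns of ``table``.

    Restrict (Fisher-z partial correlations at ``restrict_alpha``) then
    maximise (BIC hill climbing within the skeleton).  Deterministic for a
    fixed ``(table, config)``.
    """
    config = config or NetworkConfig()
    nodes = list(nodes) if nodes is not None else _infer_nodes(table)
    n = len(table)
    if n <= len(nodes) + config.max_sepset_size + 3:
        raise ValueError(
            f"need more than {len(nodes) + config.max_sepset_size + 3} rows, got {n}"
        )
    scorer = GaussianBICScorer(table, nodes)
    skeleton = _restrict_skeleton(
        scorer.corr, scorer.n, nodes, config.restrict_alpha, config.max_sepset_size
    )
    arcs = _hill_climb(scorer, skeleton, nodes)
    return NetworkModel(nodes=nodes, arcs=arcs, config=config)


# ---------------------------------------------------------------------------
# Arc strengths and the RELA dependency matrix
# ---------------------------------------------------------------------------

def arc_strengths(model: NetworkModel, table: pd.DataFrame) -> NetworkModel:
    """Per-observation BIC delta on removing each arc.

    ``strength(u -> v) = (score without the arc - score with it) / n``;
    negative values mean removal worsens the fit, so more-negative arcs are
    stronger.  Returns a new model carrying the strengths.
    """
    scorer = GaussianBICScorer(table, model.nodes)
    strengths: dict[tuple[str, str], float] = {}
    for u, v in model.arcs:
        with_parents = tuple(model.parents(v))
        without_parents = tuple(p for p in with_parents if p != u)
        delta = scorer.node_score(v, without_parents) - scorer.node_score(v, with_parents)
        strengths[(u, v)] = delta / scorer.n
    return NetworkModel(
        nodes=list(model.nodes), arcs=list(model.arcs),
        strengths=strengths, config=model.config,
    )


def rela_dependency_matrix(
    models: dict[str, NetworkModel],
    rela_node: str = RELA_NODE,
) -> pd.DataFrame:
    """Signed log2 dependency strengths of arcs touching the RELA node.

    Rows are contexts, columns features.  An entry exists only when the
    context's model has an arc between the feature and ``rela_node``:
    ``log2(|strength|)``, multiplied by -1 when the arc points from RELA to
    the feature (the feature depends on RELA).  Zero-magnitude strengths
    are undefined and left missing with a warning.
    """
    features = sorted(
        {n for m in models.values() for n in m.nodes if n != rela_node}
    )
    out = pd.DataFrame(np.nan, index=sorted(models), columns=features)
    for context in sorted(models):
        model = models[context]
        if rela_node not in model.nodes:
            raise ValueError(f"model for context {context!r} lacks node {rela_node!r}")
        if model.strengths is None:
            raise ValueError(f"model for context {context!r} has no arc strengths")
        for (u, v), s in model.strengths.items():
            if rela_node not in (u, v):
                continue
            if s == 0:
                warnings.warn(
                    f"zero-magnitude strength for {(u, v)} in context {context!r}; "
                    "entry left undefined", stacklevel=2,
                )
                continue
            feature = v if u == rela_node else u
            value = math.log2(abs(s))
            if u == rela_node:  # feature depends on RELA
                value = -value
            out.loc[context, feature] = value
    return out


# ---------------------------------------------------------------------------
# CPDAG machinery and recovery scoring
# ---------------------------------------------------------------------------

def cpdag(
    nodes: list[str], arcs: list[tuple[str, str]]
) -> tuple[set[frozenset[str]], set[tuple[str, str]]]:
    """Markov-equivalence-class representative of a DAG.

    Returns ``(skeleton, directed)`` where ``skeleton`` is the full set of
    undirected adjacencies and ``directed`` the compelled arcs: the
    v-structure arcs plus the closure under Meek's orientation rules R1-R3
    (starting from the pattern of a DAG, R4 never fires).
    """
    skeleton = {frozenset(a) for a in arcs}
    parents: dict[str, set[str]] = {v: set() for v in nodes}
    for u, v in arcs:
        parents[v].add(u)
    directed: set[tuple[str, str]] = set()
    for z in nodes:
        for x, y in itertools.combinations(sorted(parents[z]), 2):
            if frozenset((x, y)) not in skeleton:
                directed.add((x, z))
                directed.add((y, z))

    def undirected_neighbours(x: str) -> set[str]:
        out = set()
        for pair in skeleton:
            if x in pair:
                (y,) = pair - {x}
                if (x, y) not in directed and (y, x) not in directed:
                    out.add(y)
        return out

    changed = True
    while changed:
        changed = False
        for x, y in list(directed):
            # R1: x -> y, y - z, x and z non-adjacent  =>  y -> z
            for z in undirected_neighbours(y):
                if z != x and frozenset((x, z)) not in skeleton:
                    directed.add((y, z))
                    changed = True
        for pair in skeleton:
            a, b = sorted(pair)
            for x, y in ((a, b), (b, a)):
                if (x, y) in directed or (y, x) in directed:
                    continue
                # R2: x -> w -> y with x - y  =>  x -> y
                if any((x, w) in directed and (w, y) in directed for w in nodes):
                    directed.add((x, y))
                    changed = True
                    continue
                # R3: x - y with x - z1, x - z2, z1 -> y, z2 -> y,
                # z1 and z2 non-adjacent  =>  x -> y
                zs = [
                    z for z in undirected_neighbours(x)
                    if (z, y) in directed
                ]
                if any(
                    frozenset((z1, z2)) not in skeleton
                    for z1, z2 in itertools.combinations(zs, 2)
                ):
                    directed.add((x, y))
                    changed = True
    return skeleton, directed


def _edge_type(
    pair: frozenset[str],
    skeleton: set[frozenset[str]],
    directed: set[tuple[str, str]],
):
    if pair not in skeleton:
        return None
    a, b = sorted(pair)
    if (a, b) in directed:
        return (a, b)
    if (b, a) in directed:
        return (b, a)
    return "undirected"


def structural_hamming_distance(
    learned: NetworkModel, truth: NetworkModel
) -> int:
    """SHD between the CPDAGs of two DAGs (one count per differing pair)."""
    skel_l, dir_l = cpdag(learned.nodes, learned.arcs)
    skel_t, dir_t = cpdag(truth.nodes, truth.arcs)
    shd = 0
    for pair in skel_l | skel_t:
        if _edge_type(pair, skel_l, dir_l) != _edge_type(pair, skel_t, dir_t):
            shd += 1
    return shd


def compare_to_truth(learned: NetworkModel, truth: NetworkModel) -> RecoveryReport:
    """Score a learned DAG against a planted truth on the CPDAG scale."""
    if set(learned.nodes) != set(truth.nodes):
        raise ValueError("node sets differ between learned and truth models")
    skel_l, dir_l = cpdag(learned.nodes, learned.arcs)
    skel_t, dir_t = cpdag(truth.nodes, truth.arcs)

    tp_skel = len(skel_l & skel_t)
    skel_precision = tp_skel / len(skel_l) if skel_l else 1.0
    skel_recall = tp_skel / len(skel_t) if skel_t else 1.0

    tp_dir = len(dir_l & dir_t)
    orient_precision = tp_dir / len(dir_l) if dir_l else 1.0
    orient_recall = tp_dir / len(dir_t) if dir_t else 1.0

    return RecoveryReport(
        shd=structural_hamming_distance(learned, truth),
        skeleton_precision=skel_precision,
        skeleton_recall=skel_recall,
        orientation_precision=orient_precision,
        orientation_recall=orient_recall,
        n_arcs_true=len(truth.arcs),
        n_arcs_learned=len(learned.arcs),
    )
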