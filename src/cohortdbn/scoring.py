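"""DAG structures and Bayesian-Dirichlet (BDeu) marginal-likelihood scoring.

The posterior over structures is ``P(G | D) ∝ P(D | G) P(G)`` with a
uniform structure prior over the DAGs allowed by an :class:`EdgeConstraint`
(a blacklist/whitelist plus an in-degree bound).  ``P(D | G)`` is the BDeu
marginal likelihood, which decomposes over node families and assigns equal
scores to Markov-equivalent DAGs — the property the CPDAG summaries rely
on.  For a node with ``r`` states and ``q`` joint parent configurations,
the family contribution is

    log Π_j [ Γ(α_j) / Γ(α_j + n_j) · Π_k Γ(α_jk + n_jk) / Γ(α_jk) ]

with ``α_j = ess/q`` and ``α_jk = ess/(q r)``; ``ess`` is the equivalent
sample size of the Dirichlet prior (default 1).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import gammaln

from .datamodel import FactorSpec, SchemaError

__all__ = [
    "DAG",
    "EdgeConstraint",
    "CategoricalData",
    "ScoreCache",
    "bdeu_family_score",
    "dag_log_score",
    "load_constraint",
    "save_constraint",
]

NEG_INF = float("-inf")


class CyclicGraphError(ValueError):
    pass


class DAG:
    """An immutable labelled DAG given by per-node parent sets."""

    __slots__ = ("nodes", "_parents", "_key", "_hash")

    def __init__(self, nodes: Sequence[str], parent_sets: Mapping[str, Iterable[str]]):
        nodes = tuple(nodes)
        if len(set(nodes)) != len(nodes):
            raise ValueError("duplicate node names")
        node_set = set(nodes)
        parents: dict[str, frozenset[str]] = {}
        for v in nodes:
            ps = frozenset(parent_sets.get(v, ()))
            if v in ps:
                raise CyclicGraphError(f"self-loop at {v}")
            if not ps <= node_set:
                raise ValueError(f"unknown parents {ps - node_set} for node {v}")
            parents[v] = ps
        self.nodes = nodes
        self._parents = parents
        # Kahn's algorithm to reject cycles
        indeg = {v: len(parents[v]) for v in nodes}
        children: dict[str, list[str]] = {v: [] for v in nodes}
        for v in nodes:
            for u in parents[v]:
                children[u].append(v)
        queue = [v for v in nodes if indeg[v] == 0]
        seen = 0
        while queue:
            u = queue.pop()
            seen += 1
            for w in children[u]:
                indeg[w] -= 1
                if indeg[w] == 0:
                    queue.append(w)
        if seen != len(nodes):
            raise CyclicGraphError("parent sets contain a directed cycle")
        self._key = tuple((v, tuple(sorted(parents[v]))) for v in nodes)
        self._hash = hash(self._key)

    def parents(self, node: str) -> frozenset[str]:
        return self._parents[node]

    def edges(self) -> list[tuple[str, str]]:
        return [(u, v) for v in self.nodes for u in sorted(self._parents[v])]

    def key(self) -> str:
        """Canonical text serialisation (used for modal counting / tie-breaks)."""
        return ";".join(f"{v}<-{','.join(ps)}" for v, ps in self._key)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges())
        return g

    def topological_order(self) -> list[str]:
        remaining = {v: set(self._parents[v]) for v in self.nodes}
        order: list[str] = []
        placed: set[str] = set()
        while remaining:
            ready = sorted(v for v, ps in remaining.items() if ps <= placed)
            order.extend(ready)
            placed.update(ready)
            for v in ready:
                del remaining[v]
        return order

    def __eq__(self, other) -> bool:
        return isinstance(other, DAG) and self._key == other._key

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:
        return f"DAG({self.key()})"


@dataclass(frozen=True)
class EdgeConstraint:
    """Structure-prior support: forbidden/required edges and an in-degree cap.

    The prior is uniform over DAGs containing no forbidden edge, every
    required edge, and at most ``max_parents`` parents per node; all other
    DAGs have prior probability zero.
    """

    forbidden: frozenset[tuple[str, str]] = frozenset()
    required: frozenset[tuple[str, str]] = frozenset()
    max_parents: int = 4

    def __post_init__(self):
        object.__setattr__(self, "forbidden", frozenset(map(tuple, self.forbidden)))
        object.__setattr__(self, "required", frozenset(map(tuple, self.required)))
        if self.forbidden & self.required:
            raise ValueError("an edge cannot be both forbidden and required")
        if self.max_parents < 1:
            raise ValueError("max_parents must be positive")
        # required edges must be jointly acyclic
        nodes = {u for u, _ in self.required} | {v for _, v in self.required}
        try:
            DAG(
                sorted(nodes),
                {v: {u for u, w in self.required if w == v} for v in nodes},
            )
        except CyclicGraphError as exc:
            raise ValueError("required edges form a cycle") from exc

    def violations(self, dag: DAG) -> list[str]:
        out = []
        edge_set = set(dag.edges())
        for e in sorted(self.forbidden & edge_set):
            out.append(f"forbidden edge {e[0]}->{e[1]} present")
        for e in sorted(self.required - edge_set):
            if e[0] in dag.nodes and e[1] in dag.nodes:
                out.append(f"required edge {e[0]}->{e[1]} absent")
        for v in dag.nodes:
            if len(dag.parents(v)) > self.max_parents:
                out.append(f"node {v} exceeds max_parents={self.max_parents}")
        return out

    def allows(self, dag: DAG) -> bool:
        return not self.violations(dag)


class CategoricalData:
    """Integer-coded complete categorical dataset.

    Wraps a DataFrame of category labels plus the declared level lists, so
    scores see the full cardinality even when a level is unobserved.
    """

    def __init__(self, df: pd.DataFrame, levels: Mapping[str, Sequence[str]]):
        self.columns = tuple(levels.keys())
        missing = [c for c in self.columns if c not in df.columns]
        if missing:
            raise SchemaError(f"dataset missing columns {missing}")
        self.n_rows = len(df)
        self.levels = {c: tuple(levels[c]) for c in self.columns}
        self.cards = {c: len(self.levels[c]) for c in self.columns}
        codes = {}
        for c in self.columns:
            idx = {lab: i for i, lab in enumerate(self.levels[c])}
            col = df[c]
            if col.isna().any():
                raise SchemaError(f"column {c!r} contains missing values")
            try:
                codes[c] = np.array([idx[v] for v in col], dtype=np.int64)
            except KeyError as exc:
                raise SchemaError(
                    f"column {c!r}: value {exc.args[0]!r} not in levels"
                ) from exc
        self._codes = codes

    def codes(self, column: str) -> np.ndarray:
        return self._codes[column]

    @classmethod
    def from_specs(cls, df: pd.DataFrame, specs: Sequence[FactorSpec]):
        return cls(df, {s.name: s.levels for s in specs})


def bdeu_family_score(
    node: str,
    parent_set: Iterable[str],
    data: CategoricalData,
    ess: float = 1.0,
) -> float:
    """BDeu log marginal-likelihood contribution of one node family."""
    if ess <= 0:
        raise ValueError("ess must be positive")
    parents = sorted(parent_set)
    for c in (node, *parents):
        if c not in data.cards:
            raise SchemaError(f"unknown column {c!r}")
    r = data.cards[node]
    cards = [data.cards[p] for p in parents]
    q = int(np.prod(cards)) if parents else 1
    if data.n_rows == 0:
        return 0.0
    if parents:
        j = np.zeros(data.n_rows, dtype=np.int64)
        for p, card in zip(parents, cards):
            j = j * card + data.codes(p)
    else:
        j = np.zeros(data.n_rows, dtype=np.int64)
    njk = np.bincount(j * r + data.codes(node), minlength=q * r).reshape(q, r)
    nj = njk.sum(axis=1)
    a_j = ess / q
    a_jk = ess / (q * r)
    score = np.sum(gammaln(a_j) - gammaln(a_j + nj))
    score += np.sum(gammaln(a_jk + njk) - gammaln(a_jk))
    return float(score)


class ScoreCache:
    """Memoised family scores for one (dataset, ess) pair."""

    def __init__(self, data: CategoricalData, ess: float = 1.0):
        if ess <= 0:
            raise ValueError("ess must be positive")
        self.data = data
        self.ess = float(ess)
        self._cache: dict[tuple[str, frozenset[str]], float] = {}

    def family_score(self, node: str, parent_set: Iterable[str]) -> float:
        key = (node, frozenset(parent_set))
        hit = self._cache.get(key)
        if hit is None:
            hit = bdeu_family_score(node, key[1], self.data, self.ess)
            self._cache[key] = hit
        return hit


def dag_log_score(
    dag: DAG,
    data: CategoricalData,
    ess: float = 1.0,
    constraint: EdgeConstraint | None = None,
    cache: ScoreCache | None = None,
) -> float:
    """Unnormalised log posterior score of a DAG.

    With a uniform prior over allowed DAGs the log prior is an additive
    constant, so the returned value is the sum of BDeu family scores —
    or ``-inf`` when the DAG lies outside the constraint's support.
    """
    if constraint is not None and not constraint.allows(dag):
        return NEG_INF
    if cache is None:
        cache = ScoreCache(data, ess)
    return sum(cache.family_score(v, dag.parents(v)) for v in dag.nodes)


def load_constraint(path: str | Path) -> tuple[EdgeConstraint, float | None]:
    """Load an :class:`EdgeConstraint` (and optional ess) from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    con = EdgeConstraint(
        forbidden=frozenset(tuple(e) for e in raw.get("forbidden", [])),
        required=frozenset(tuple(e) for e in raw.get("required", [])),
        max_parents=int(raw.get("max_parents", 4)),
    )
    ess = raw.get("ess")
    return con, (float(ess) if ess is not None else None)


def save_constraint(
    constraint: EdgeConstraint, path: str | Path, ess: float | None = None
) -> None:
    raw = {
        "forbidden": sorted(list(e) for e in constraint.forbidden),
        "required": sorted(list(e) for e in constraint.required),
        "max_parents": constraint.max_parents,
    }
    if ess is not None:
        raw["ess"] = ess
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def allowed_parent_sets(
    node: str,
    nodes: Sequence[str],
    constraint: EdgeConstraint,
) -> list[frozenset[str]]:
    """All parent sets of ``node`` allowed by the constraint, smallest first."""
    required = {u for u, v in constraint.required if v == node}
    candidates = [
        u
        for u in nodes
        if u != node and (u, node) not in constraint.forbidden and u not in required
    ]
    if len(required) > constraint.max_parents:
        return []
    out = []
    for k in range(constraint.max_parents - len(required) + 1):
        for extra in itertools.combinations(candidates, k):
            out.append(frozenset(required) | frozenset(extra))
    return out
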