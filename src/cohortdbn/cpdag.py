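"""Markov-equivalence summaries: CPDAG conversion and edge-direction tables.

A CPDAG represents a Markov equivalence class: *compelled* edges keep the
orientation shared by every member DAG, *reversible* edges are left
undirected because either orientation yields the same posterior score.
Conversion uses Chickering's edge-labelling algorithm (topological edge
ordering + compelled/reversible propagation), which is exact for
unconstrained DAGs.

For two-slice transition graphs the temporal blacklist is background
knowledge: a ``@t -> @t1`` edge can never be reversed, so cross-slice edges
are kept directed after conversion and Meek orientation rules R1-R3 are
closed over to propagate the extra orientations to contemporaneous edges.

Directional edge probabilities follow the convention that an undirected
CPDAG edge counts at full weight toward *both* directions — so the two
directed probabilities of one pair may sum above 1.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .datamodel import T1_SUFFIX, T_SUFFIX
from .scoring import DAG
from .structure import PosteriorSample

__all__ = [
    "CPDAG",
    "dag_to_cpdag",
    "consistent_extension",
    "summarize_directional_probabilities",
    "map_summary_graph",
    "SummaryGraph",
    "SummaryEdge",
]

logger = logging.getLogger(__name__)

DOMAIN_COLORS = {
    "function": "green",
    "suicidality": "blue",
    "substance": "gold",
    "physical": "grey",
    "syndrome": "orange",
    "demographic": "white",
}


@dataclass(frozen=True)
class CPDAG:
    """Partially directed graph: compelled (directed) + reversible edges."""

    nodes: tuple[str, ...]
    directed: frozenset[tuple[str, str]]
    undirected: frozenset[tuple[str, str]]  # stored with u < v

    def __post_init__(self):
        und = frozenset(tuple(sorted(e)) for e in self.undirected)
        object.__setattr__(self, "undirected", und)
        pairs_d = {tuple(sorted(e)) for e in self.directed}
        if pairs_d & set(und):
            raise ValueError("an edge cannot be both directed and undirected")

    def key(self) -> str:
        d = ",".join(f"{u}>{v}" for u, v in sorted(self.directed))
        u = ",".join(f"{a}-{b}" for a, b in sorted(self.undirected))
        return f"D[{d}]U[{u}]"

    def has_edge(self, u: str, v: str) -> bool:
        """True if u->v compelled or u-v reversible."""
        return (u, v) in self.directed or tuple(sorted((u, v))) in self.undirected

    def skeleton(self) -> frozenset[tuple[str, str]]:
        return frozenset(
            {tuple(sorted(e)) for e in self.directed} | set(self.undirected)
        )


def _order_edges(dag: DAG) -> list[tuple[str, str]]:
    topo = {v: i for i, v in enumerate(dag.topological_order())}
    edges = dag.edges()
    return sorted(edges, key=lambda e: (topo[e[1]], -topo[e[0]]))


def _label_edges(dag: DAG) -> dict[tuple[str, str], str]:
    """Chickering's compelled/reversible labelling."""
    ordered = _order_edges(dag)
    order_idx = {e: i for i, e in enumerate(ordered)}
    label: dict[tuple[str, str], str] = {}
    for edge in ordered:
        if edge in label:
            continue
        x, y = edge
        done = False
        # parents w of x with w->x compelled, in edge order
        wlist = sorted(
            (w for w in dag.parents(x) if label.get((w, x)) == "compelled"),
            key=lambda w: order_idx[(w, x)],
        )
        for w in wlist:
            if w not in dag.parents(y):
                for z in dag.parents(y):
                    label[(z, y)] = "compelled"
                done = True
                break
            label[(w, y)] = "compelled"
        if done:
            continue
        if any(z != x and z not in dag.parents(x) for z in dag.parents(y)):
            verdict = "compelled"
        else:
            verdict = "reversible"
        for z in dag.parents(y):
            label.setdefault((z, y), verdict)
        label[(x, y)] = label.get((x, y), verdict)
    return label


def _meek_closure(
    nodes: Sequence[str],
    directed: set[tuple[str, str]],
    undirected: set[tuple[str, str]],
) -> None:
    """Meek rules R1-R3, in place, until fixpoint."""

    def adjacent(a, b):
        return (
            (a, b) in directed
            or (b, a) in directed
            or tuple(sorted((a, b))) in undirected
        )

    changed = True
    while changed:
        changed = False
        for a, b in sorted(undirected):
            for u, v in ((a, b), (b, a)):
                orient = False
                # R1: w->u, u-v, w not adjacent to v  =>  u->v
                if any(
                    (w, u) in directed and not adjacent(w, v)
                    for w in nodes
                    if w not in (u, v)
                ):
                    orient = True
                # R2: u->w->v and u-v  =>  u->v
                elif any(
                    (u, w) in directed and (w, v) in directed
                    for w in nodes
                    if w not in (u, v)
                ):
                    orient = True
                # R3: u-w1, u-w2, w1->v, w2->v, w1,w2 non-adjacent  =>  u->v
                else:
                    ws = [
                        w
                        for w in nodes
                        if w not in (u, v)
                        and tuple(sorted((u, w))) in undirected
                        and (w, v) in directed
                    ]
                    for i in range(len(ws)):
                        for j in range(i + 1, len(ws)):
                            if not adjacent(ws[i], ws[j]):
                                orient = True
                if orient:
                    undirected.discard((a, b))
                    directed.add((u, v))
                    changed = True
                    break
            if changed:
                break


def _auto_background(dag: DAG) -> frozenset[tuple[str, str]]:
    """Cross-slice edges of a two-slice DAG (temporal background knowledge)."""
    if all(v.endswith(T_SUFFIX) or v.endswith(T1_SUFFIX) for v in dag.nodes):
        return frozenset(
            (u, v)
            for u, v in dag.edges()
            if u.endswith(T_SUFFIX) and v.endswith(T1_SUFFIX)
        )
    return frozenset()


def dag_to_cpdag(
    dag: DAG,
    directed_background: Iterable[tuple[str, str]] | None = None,
) -> CPDAG:
    """Convert a DAG to the CPDAG of its Markov equivalence class.

    ``directed_background`` lists edges whose orientation is fixed by
    prior knowledge (defaults to the cross-slice edges when node names
    carry ``@t``/``@t1`` suffixes); these stay directed and their
    orientations are propagated with Meek rules R1-R3.
    """
    label = _label_edges(dag)
    directed = {e for e, l in label.items() if l == "compelled"}
    undirected = {tuple(sorted(e)) for e, l in label.items() if l == "reversible"}
    background = (
        frozenset(directed_background)
        if directed_background is not None
        else _auto_background(dag)
    )
    forced = {e for e in background if tuple(sorted(e)) in undirected}
    if forced:
        for e in forced:
            undirected.discard(tuple(sorted(e)))
            directed.add(e)
        _meek_closure(dag.nodes, directed, undirected)
    return CPDAG(
        nodes=dag.nodes,
        directed=frozenset(directed),
        undirected=frozenset(undirected),
    )


def consistent_extension(cpdag: CPDAG) -> DAG:
    """Orient all reversible edges into a DAG of the represented class.

    Dor–Tarsi algorithm; raises if the CPDAG admits no consistent
    extension (i.e. is not a valid equivalence-class representative).
    """
    directed = set(cpdag.directed)
    undirected = {tuple(sorted(e)) for e in cpdag.undirected}
    remaining = set(cpdag.nodes)
    oriented: set[tuple[str, str]] = set(directed)

    def nbrs(x):
        out = set()
        for u, v in directed:
            if u == x and v in remaining:
                out.add(v)
            if v == x and u in remaining:
                out.add(u)
        for u, v in undirected:
            if u == x and v in remaining:
                out.add(v)
            if v == x and u in remaining:
                out.add(u)
        return out

    while remaining:
        found = None
        for x in sorted(remaining):
            if any(u == x and v in remaining for u, v in directed):
                continue  # x must be a sink of the directed part
            und_nb = {
                (set(e) - {x}).pop()
                for e in undirected
                if x in e and (set(e) - {x}).pop() in remaining
            }
            all_nb = nbrs(x)
            if all(
                all(y == z or z in nbrs(y) or y in nbrs(z) for z in all_nb - {y})
                for y in und_nb
            ):
                found = x
                break
        if found is None:
            raise ValueError("CPDAG admits no consistent extension")
        for e in list(undirected):
            if found in e:
                other = (set(e) - {found}).pop()
                if other in remaining:
                    oriented.add((other, found))
                    undirected.discard(e)
        directed = {e for e in directed if found not in e}
        remaining.discard(found)

    parent_sets: dict[str, set[str]] = {v: set() for v in cpdag.nodes}
    for u, v in oriented:
        parent_sets[v].add(u)
    return DAG(cpdag.nodes, parent_sets)


def summarize_directional_probabilities(
    sample: PosteriorSample,
    directed_background: Iterable[tuple[str, str]] | None = None,
) -> dict[tuple[str, str], float]:
    """Per-direction edge probabilities over the sample's CPDAGs.

    Each sampled DAG is converted to its CPDAG; a compelled ``u -> v``
    counts toward (u, v) only, an undirected ``u - v`` counts at full
    weight toward both (u, v) and (v, u).
    """
    counts: Counter = Counter()
    cache: dict[DAG, CPDAG] = {}
    for dag in sample.dags:
        cp = cache.get(dag)
        if cp is None:
            cp = dag_to_cpdag(dag, directed_background)
            cache[dag] = cp
        for e in cp.directed:
            counts[e] += 1
        for a, b in cp.undirected:
            counts[(a, b)] += 1
            counts[(b, a)] += 1
    n = len(sample.dags)
    out = {e: c / n for e, c in counts.items()}
    for u in sample.nodes:
        for v in sample.nodes:
            if u != v:
                out.setdefault((u, v), 0.0)
    return out


@dataclass(frozen=True)
class SummaryEdge:
    source: str
    target: str
    probability: float
    style: str  # "solid" (in MAP CPDAG) or "dashed"


@dataclass
class SummaryGraph:
    """Posterior summary for export: MAP CPDAG plus probable edges."""

    nodes: tuple[str, ...]
    edges: list[SummaryEdge]
    map_cpdag: CPDAG
    threshold: float
    domain_groups: Mapping[str, str] = field(default_factory=dict)

    def to_dot(self) -> str:
        lines = ["digraph summary {"]
        for v in self.nodes:
            group = self.domain_groups.get(v.split("@")[0], "")
            color = DOMAIN_COLORS.get(group, "white")
            lines.append(
                f'  "{v}" [style=filled, fillcolor="{color}", domain_group="{group}"];'
            )
        for e in self.edges:
            alpha = int(round(255 * e.probability))
            lines.append(
                f'  "{e.source}" -> "{e.target}" '
                f'[style={e.style}, probability="{e.probability:.4f}", '
                f'color="#000000{alpha:02x}"];'
            )
        lines.append("}")
        return "\n".join(lines)

    def to_graphml(self, path) -> None:
        import networkx as nx

        g = nx.DiGraph()
        for v in self.nodes:
            group = self.domain_groups.get(v.split("@")[0], "")
            g.add_node(v, domain_group=group)
        for e in self.edges:
            g.add_edge(
                e.source, e.target, probability=e.probability, style=e.style
            )
        nx.write_graphml(g, path)


def map_summary_graph(
    sample: PosteriorSample,
    threshold: float = 0.1,
    directed_background: Iterable[tuple[str, str]] | None = None,
    domain_groups: Mapping[str, str] | None = None,
) -> SummaryGraph:
    """Summarise a posterior sample the way the network figures are drawn.

    The MAP estimate is the modal CPDAG among the sampled CPDAGs (ties
    broken by lexicographically smallest serialisation, with a warning).
    Edges with directional probability above ``threshold`` are annotated
    ``solid`` when present in the MAP CPDAG and ``dashed`` otherwise;
    probability doubles as a transparency weight for export.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    cache: dict[DAG, CPDAG] = {}
    keys: Counter = Counter()
    by_key: dict[str, CPDAG] = {}
    for dag in sample.dags:
        cp = cache.get(dag)
        if cp is None:
            cp = dag_to_cpdag(dag, directed_background)
            cache[dag] = cp
        k = cp.key()
        keys[k] += 1
        by_key[k] = cp
    top = max(keys.values())
    modal_keys = sorted(k for k, c in keys.items() if c == top)
    if len(modal_keys) > 1:
        logger.warning(
            "tie for modal CPDAG (%d candidates); using lexicographically "
            "smallest serialisation",
            len(modal_keys),
        )
    map_cpdag = by_key[modal_keys[0]]
    probs = summarize_directional_probabilities(sample, directed_background)
    edges = [
        SummaryEdge(
            source=u,
            target=v,
            probability=p,
            style="solid" if map_cpdag.has_edge(u, v) else "dashed",
        )
        for (u, v), p in sorted(probs.items())
        if p > threshold
    ]
    return SummaryGraph(
        nodes=sample.nodes,
        edges=edges,
        map_cpdag=map_cpdag,
        threshold=threshold,
        domain_groups=dict(domain_groups or {}),
    )
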