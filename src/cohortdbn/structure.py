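"""Posterior sampling over DAG structures.

Two routes to the structure posterior ``P(G | D)``:

* :func:`enumerate_dag_posterior` — exact, by enumerating every allowed DAG
  (guarded to at most 5 nodes); used as the oracle the sampler is tested
  against.
* :class:`PartitionMCMCSampler` / :func:`partition_mcmc_sample` — partition
  MCMC.  The chain's state is an ordered partition (λ₁, …, λ_m) of the node
  set: the canonical layering of a DAG in which λ₁ holds the parentless
  nodes and every node of λ_i (i > 1) has at least one parent in λ_{i-1}
  and all parents in earlier layers.  Each DAG belongs to exactly one
  layering, so sampling partitions with probability proportional to the
  summed scores of their consistent DAGs, then drawing a DAG conditionally
  within the partition, yields unbiased draws from ``P(G | D)``.

Moves are proposed uniformly from a neighbourhood built from single-node
relocations, adjacent-element swaps, and binary splits/joins of elements
(size-capped symmetrically), with a Metropolis–Hastings correction for the
neighbourhood sizes.  Nodes that cannot have parents under the constraint
are pinned to the first element; any state placing them elsewhere has zero
posterior mass, so excluding such states from the proposal support leaves
the stationary law unchanged.
"""

from __future__ import annotations

import gzip
import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .scoring import (
    DAG,
    NEG_INF,
    CategoricalData,
    EdgeConstraint,
    ScoreCache,
    allowed_parent_sets,
)

__all__ = [
    "count_dags",
    "enumerate_dag_posterior",
    "exact_edge_probabilities",
    "PosteriorSample",
    "PartitionMCMCSampler",
    "partition_mcmc_sample",
    "edge_probabilities",
    "save_posterior",
    "load_posterior",
]


def count_dags(n: int) -> int:
    """Exact number of labelled DAGs on ``n`` nodes (Robinson's recurrence).

    a(n) = Σ_{k=1..n} (-1)^{k+1} C(n,k) 2^{k(n-k)} a(n-k), a(0) = 1.
    Grows super-exponentially: already ~10^18 at n = 10, which is why
    structure inference is posed as posterior sampling rather than
    exhaustive search.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    a = [1]
    for m in range(1, n + 1):
        total = 0
        for k in range(1, m + 1):
            term = math.comb(m, k) * (1 << (k * (m - k))) * a[m - k]
            total += term if k % 2 == 1 else -term
        a.append(total)
    return a[n]


# ---------------------------------------------------------------------------
# Exact enumeration oracle


def _acyclic(parent_masks: Sequence[int], n: int) -> bool:
    """Kahn's check on bitmask parent sets."""
    masks = list(parent_masks)
    remaining = (1 << n) - 1
    while remaining:
        progressed = False
        for i in range(n):
            bit = 1 << i
            if remaining & bit and not (masks[i] & remaining):
                remaining &= ~bit
                progressed = True
        if not progressed:
            return False
    return True


def enumerate_dag_posterior(
    data: CategoricalData,
    constraint: EdgeConstraint | None = None,
    ess: float = 1.0,
    max_nodes: int = 5,
) -> dict[DAG, float]:
    """Exact structure posterior by enumerating all allowed DAGs.

    Intended as an oracle: refuses more than ``max_nodes`` (default 5)
    nodes, where the DAG count is already 29281.
    """
    nodes = list(data.columns)
    n = len(nodes)
    if n > max_nodes:
        raise ValueError(
            f"exact enumeration refused for {n} nodes (guard: {max_nodes})"
        )
    constraint = constraint or EdgeConstraint(max_parents=max(1, n - 1))
    cache = ScoreCache(data, ess)
    idx = {v: i for i, v in enumerate(nodes)}
    per_node: list[list[tuple[int, frozenset, float]]] = []
    for v in nodes:
        entries = []
        for ps in allowed_parent_sets(v, nodes, constraint):
            mask = 0
            for u in ps:
                mask |= 1 << idx[u]
            entries.append((mask, ps, cache.family_score(v, ps)))
        per_node.append(entries)

    dags: list[DAG] = []
    logs: list[float] = []
    chosen: list[tuple[int, frozenset, float]] = []

    def rec(i: int):
        if i == n:
            if _acyclic([c[0] for c in chosen], n):
                dag = DAG(nodes, {v: chosen[k][1] for k, v in enumerate(nodes)})
                dags.append(dag)
                logs.append(sum(c[2] for c in chosen))
            return
        for entry in per_node[i]:
            chosen.append(entry)
            rec(i + 1)
            chosen.pop()

    rec(0)
    if not dags:
        raise ValueError("constraint admits no DAG")
    logs_arr = np.array(logs)
    probs = np.exp(logs_arr - logsumexp(logs_arr))
    return dict(zip(dags, probs))


def exact_edge_probabilities(
    posterior: Mapping[DAG, float]
) -> dict[tuple[str, str], float]:
    """Per-ordered-pair edge probabilities under an exact posterior."""
    out: dict[tuple[str, str], float] = {}
    for dag, p in posterior.items():
        for e in dag.edges():
            out[e] = out.get(e, 0.0) + p
    nodes = next(iter(posterior)).nodes
    for u in nodes:
        for v in nodes:
            if u != v:
                out.setdefault((u, v), 0.0)
    return out


# ---------------------------------------------------------------------------
# Posterior samples


@dataclass
class PosteriorSample:
    """Ordered list of DAG draws plus the metadata to reproduce them."""

    dags: list[DAG]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.dags:
            raise ValueError("a posterior sample must contain at least one DAG")

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.dags[0].nodes

    def __len__(self) -> int:
        return len(self.dags)


def edge_probabilities(sample: PosteriorSample) -> dict[tuple[str, str], float]:
    """Edge frequency: occurrences across sampled DAGs / number of samples."""
    counts: dict[tuple[str, str], int] = {}
    for dag in sample.dags:
        for e in dag.edges():
            counts[e] = counts.get(e, 0) + 1
    n = len(sample.dags)
    out = {e: c / n for e, c in counts.items()}
    for u in sample.nodes:
        for v in sample.nodes:
            if u != v:
                out.setdefault((u, v), 0.0)
    return out


# ---------------------------------------------------------------------------
# Partition MCMC

State = tuple[tuple[int, ...], ...]  # ordered partition of node indices


class _PartitionModel:
    """Score tables and partition-space operations for one problem."""

    def __init__(
        self,
        data: CategoricalData,
        constraint: EdgeConstraint,
        ess: float,
        split_cap: int = 9,
    ):
        self.nodes = list(data.columns)
        self.n = len(self.nodes)
        self.constraint = constraint
        self.split_cap = split_cap
        idx = {v: i for i, v in enumerate(self.nodes)}
        cache = ScoreCache(data, ess)
        self.pmasks: list[np.ndarray] = []
        self.pscores: list[np.ndarray] = []
        self.psets: list[list[frozenset]] = []
        for v in self.nodes:
            sets = allowed_parent_sets(v, self.nodes, constraint)
            masks = np.zeros(len(sets), dtype=np.int64)
            scores = np.zeros(len(sets))
            for k, ps in enumerate(sets):
                m = 0
                for u in ps:
                    m |= 1 << idx[u]
                masks[k] = m
                scores[k] = cache.family_score(v, ps)
            self.pmasks.append(masks)
            self.pscores.append(scores)
            self.psets.append(sets)
        # nodes whose only allowed parent set is empty can never leave layer 1
        self.exogenous = frozenset(
            i
            for i in range(self.n)
            if len(self.psets[i]) == 1 and not self.psets[i][0]
        )
        self.empty_idx = [
            next((k for k, s in enumerate(self.psets[i]) if not s), None)
            for i in range(self.n)
        ]

    # -- scoring -----------------------------------------------------------

    def node_log_sum(self, i: int, u_mask: int, prev_mask: int) -> float:
        """logsumexp of family scores over parent sets valid for this layer."""
        if prev_mask == 0:
            k = self.empty_idx[i]
            return self.pscores[i][k] if k is not None else NEG_INF
        masks = self.pmasks[i]
        valid = ((masks & ~u_mask) == 0) & ((masks & prev_mask) != 0)
        if not valid.any():
            return NEG_INF
        return float(logsumexp(self.pscores[i][valid]))

    def log_score(self, state: State) -> float:
        total = 0.0
        u_mask = 0
        prev_mask = 0
        for elem in state:
            for i in elem:
                s = self.node_log_sum(i, u_mask, prev_mask)
                if s == NEG_INF:
                    return NEG_INF
                total += s
            elem_mask = 0
            for i in elem:
                elem_mask |= 1 << i
            prev_mask = elem_mask
            u_mask |= elem_mask
        return total

    def draw_dag(self, state: State, rng: np.random.Generator) -> DAG:
        """One DAG from the partition's conditional distribution."""
        parent_sets: dict[str, frozenset] = {}
        u_mask = 0
        prev_mask = 0
        for elem in state:
            for i in elem:
                if prev_mask == 0:
                    parent_sets[self.nodes[i]] = frozenset()
                    continue
                masks = self.pmasks[i]
                valid = ((masks & ~u_mask) == 0) & ((masks & prev_mask) != 0)
                scores = self.pscores[i][valid]
                probs = np.exp(scores - logsumexp(scores))
                sets = [s for s, ok in zip(self.psets[i], valid) if ok]
                k = int(rng.choice(len(sets), p=probs))
                parent_sets[self.nodes[i]] = sets[k]
            elem_mask = 0
            for i in elem:
                elem_mask |= 1 << i
            prev_mask = elem_mask
            u_mask |= elem_mask
        return DAG(self.nodes, parent_sets)

    # -- state space -------------------------------------------------------

    def initial_state(self) -> State:
        req = self.constraint.required
        if not req:
            return (tuple(range(self.n)),)
        # longest-path layering of the required-edge graph
        idx = {v: i for i, v in enumerate(self.nodes)}
        req_parents = {i: set() for i in range(self.n)}
        for u, v in req:
            if u in idx and v in idx:
                req_parents[idx[v]].add(idx[u])
        depth = {}

        def d(i):
            if i not in depth:
                depth[i] = (
                    0
                    if not req_parents[i]
                    else 1 + max(d(p) for p in req_parents[i])
                )
            return depth[i]

        for i in range(self.n):
            d(i)
        layers: dict[int, list[int]] = {}
        for i in range(self.n):
            layers.setdefault(depth[i], []).append(i)
        state = tuple(tuple(sorted(layers[k])) for k in sorted(layers))
        if self.log_score(state) == NEG_INF:
            raise ValueError(
                "no valid starting partition: required edges conflict with the "
                "constraint"
            )
        return state

    def _valid_exo(self, state: State) -> bool:
        if not self.exogenous:
            return True
        return self.exogenous <= set(state[0])

    def neighbors(self, state: State) -> list[State]:
        """Symmetric move neighbourhood (deduplicated, deterministic order)."""
        out: set[State] = set()
        m = len(state)
        # single-node relocations
        for i, elem in enumerate(state):
            for v in elem:
                rest = tuple(x for x in elem if x != v)
                base = list(state)
                if rest:
                    base[i] = rest
                else:
                    del base[i]
                for j, tgt in enumerate(base):
                    cand = list(base)
                    cand[j] = tuple(sorted(tgt + (v,)))
                    out.add(tuple(cand))
                for g in range(len(base) + 1):
                    cand = list(base)
                    cand.insert(g, (v,))
                    out.add(tuple(cand))
        # adjacent swaps
        for i in range(m - 1):
            cand = list(state)
            cand[i], cand[i + 1] = cand[i + 1], cand[i]
            out.add(tuple(cand))
        # full order reversal: connects mirror-image layerings (e.g. the two
        # end-rooted orientations of a chain) that local moves only reach
        # through deep score valleys
        if m > 1:
            out.add(tuple(reversed(state)))
        # binary ordered splits (capped) and adjacent joins (capped)
        for i, elem in enumerate(state):
            if 1 < len(elem) <= self.split_cap:
                items = list(elem)
                for r in range(1, len(items)):
                    for first in itertools.combinations(items, r):
                        second = tuple(x for x in items if x not in first)
                        cand = list(state)
                        cand[i : i + 1] = [tuple(sorted(first)), second]
                        out.add(tuple(cand))
        for i in range(m - 1):
            if len(state[i]) + len(state[i + 1]) <= self.split_cap:
                cand = list(state)
                cand[i : i + 2] = [tuple(sorted(state[i] + state[i + 1]))]
                out.add(tuple(cand))
        out.discard(state)
        return sorted(s for s in out if self._valid_exo(s))


class PartitionMCMCSampler(BaseEstimator):
    """Partition-MCMC posterior sampler over DAG structures.

    Parameters
    ----------
    ess : equivalent sample size of the BDeu prior.
    max_parents : in-degree cap (ignored if ``constraint`` provides one).
    constraint : optional :class:`EdgeConstraint`; defaults to only the
        in-degree cap.
    n_iter, burn_in, thin : chain length, burn-in (default 20% of
        ``n_iter``) and thinning interval, per chain.
    n_chains : independent chains; draws are pooled, and the maximum
        cross-chain edge-probability gap is reported as a convergence
        diagnostic.
    levels : optional mapping column -> level labels; inferred from the
        data when omitted.
    random_state : required integer seed; chain ``c`` uses the
        deterministic stream ``SeedSequence([random_state, c])``.

    Attributes (after :meth:`fit`)
    ------------------------------
    posterior_ : :class:`PosteriorSample` of pooled draws.
    edge_probabilities_ : dict ``(u, v) -> frequency``.
    convergence_gap_ : max absolute cross-chain edge-probability difference
        (0.0 for a single chain).
    """

    def __init__(
        self,
        ess: float = 1.0,
        max_parents: int = 4,
        constraint: EdgeConstraint | None = None,
        n_iter: int = 100_000,
        burn_in: int | None = None,
        thin: int = 100,
        n_chains: int = 2,
        levels: Mapping[str, Sequence[str]] | None = None,
        random_state: int | None = None,
    ):
        self.ess = ess
        self.max_parents = max_parents
        self.constraint = constraint
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.n_chains = n_chains
        self.levels = levels
        self.random_state = random_state

    def _effective_constraint(self) -> EdgeConstraint:
        if self.constraint is not None:
            return self.constraint
        return EdgeConstraint(max_parents=self.max_parents)

    def fit(self, X, y=None):
        """Run the chains on a complete categorical DataFrame ``X``."""
        if self.random_state is None:
            raise ValueError(
                "random_state must be set: posterior samples are required to "
                "be reproducible"
            )
        burn = self.burn_in if self.burn_in is not None else self.n_iter // 5
        if self.n_iter <= burn:
            raise ValueError("n_iter must exceed burn_in")
        if isinstance(X, CategoricalData):
            data = X
        else:
            levels = self.levels or {
                c: tuple(sorted(map(str, X[c].unique()))) for c in X.columns
            }
            data = CategoricalData(X, levels)
        constraint = self._effective_constraint()
        model = _PartitionModel(data, constraint, self.ess)
        per_chain: list[list[DAG]] = []
        for c in range(self.n_chains):
            rng = np.random.default_rng(np.random.SeedSequence([self.random_state, c]))
            per_chain.append(self._run_chain(model, rng, burn))
        draws = [d for chain in per_chain for d in chain]
        self.model_ = model
        self.posterior_ = PosteriorSample(
            dags=draws,
            meta={
                "seed": self.random_state,
                "n_iter": self.n_iter,
                "burn_in": burn,
                "thin": self.thin,
                "n_chains": self.n_chains,
                "ess": self.ess,
                "constraint_hash": hash(constraint),
                "nodes": list(model.nodes),
            },
        )
        self.edge_probabilities_ = edge_probabilities(self.posterior_)
        gap = 0.0
        if self.n_chains > 1:
            tables = [
                edge_probabilities(PosteriorSample(chain, {}))
                for chain in per_chain
            ]
            keys = set().union(*(t.keys() for t in tables))
            for k in keys:
                vals = [t.get(k, 0.0) for t in tables]
                gap = max(gap, max(vals) - min(vals))
        self.convergence_gap_ = gap
        return self

    def _run_chain(
        self, model: _PartitionModel, rng: np.random.Generator, burn: int
    ) -> list[DAG]:
        state = model.initial_state()
        score = model.log_score(state)
        nbrs = model.neighbors(state)
        draws: list[DAG] = []
        for it in range(self.n_iter):
            if nbrs:
                prop = nbrs[int(rng.integers(len(nbrs)))]
                prop_score = model.log_score(prop)
                if prop_score > NEG_INF:
                    prop_nbrs = model.neighbors(prop)
                    log_alpha = (
                        prop_score
                        - score
                        + math.log(len(nbrs))
                        - math.log(len(prop_nbrs))
                    )
                    if math.log(rng.random()) < log_alpha:
                        state, score, nbrs = prop, prop_score, prop_nbrs
            if it >= burn and (it - burn) % self.thin == 0:
                draws.append(model.draw_dag(state, rng))
        return draws

    @staticmethod
    def log_acceptance_ratio(
        model: _PartitionModel, state_a: State, state_b: State
    ) -> float:
        """log of the MH ratio for a -> b (before the min with 0)."""
        if state_b not in model.neighbors(state_a):
            raise ValueError("states are not neighbours")
        return (
            model.log_score(state_b)
            - model.log_score(state_a)
            + math.log(len(model.neighbors(state_a)))
            - math.log(len(model.neighbors(state_b)))
        )


def partition_mcmc_sample(
    data: CategoricalData,
    constraint: EdgeConstraint | None = None,
    ess: float = 1.0,
    n_iter: int = 100_000,
    burn_in: int | None = None,
    thin: int = 100,
    seed: int | None = None,
    n_chains: int = 2,
) -> PosteriorSample:
    """Functional wrapper over :class:`PartitionMCMCSampler`."""
    sampler = PartitionMCMCSampler(
        ess=ess,
        constraint=constraint,
        max_parents=(constraint.max_parents if constraint else 4),
        n_iter=n_iter,
        burn_in=burn_in,
        thin=thin,
        n_chains=n_chains,
        random_state=seed,
    )
    sampler.fit(data)
    return sampler.posterior_


# ---------------------------------------------------------------------------
# Serialisation: JSON-lines, one DAG per line, metadata header


def save_posterior(sample: PosteriorSample, path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write(json.dumps({"meta": sample.meta, "nodes": list(sample.nodes)}) + "\n")
        for dag in sample.dags:
            fh.write(
                json.dumps({v: sorted(dag.parents(v)) for v in dag.nodes}) + "\n"
            )


def load_posterior(path: str | Path) -> PosteriorSample:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        header = json.loads(fh.readline())
        nodes = header["nodes"]
        dags = [DAG(nodes, json.loads(line)) for line in fh if line.strip()]
    return PosteriorSample(dags=dags, meta=header.get("meta", {}))
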