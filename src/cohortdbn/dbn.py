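"""Dynamic Bayesian network learning for longitudinal cohorts.

The DBN has two parts: an *initial network* over the factors at first
presentation (t = 0), and a *transition network* over the two-slice node
set ``{factor@t} ∪ {factor@t1}`` learned from stacked consecutive
timepoint pairs.  The transition model is homogeneous: the same network is
assumed to link every pair of consecutive timepoints.

Slice constraints in the transition network:

* no edges into any ``@t`` node (slice-t variables are exogenous — their
  marginals are the initial network's job);
* edges among ``@t1`` nodes only in the secondary, *contemporaneous*
  regime (``allow_contemporaneous=True``); the primary regime assumes the
  t+1 factors conditionally independent given slice t.

With contemporaneous edges disabled every allowed graph is bipartite and
automatically acyclic, so the structure posterior factorises exactly over
the ``@t1`` families; :class:`ExactTransitionPosterior` computes it in
closed form and serves as the oracle the MCMC route is validated against.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .datamodel import (
    T1_SUFFIX,
    T_SUFFIX,
    CohortTable,
    FactorSpec,
    TransitionDataset,
    build_initial_dataset,
    build_transition_dataset,
)
from .scoring import (
    DAG,
    CategoricalData,
    EdgeConstraint,
    ScoreCache,
    allowed_parent_sets,
)
from .structure import (
    PartitionMCMCSampler,
    PosteriorSample,
    edge_probabilities,
)
from sklearn.base import BaseEstimator

__all__ = [
    "TransitionNetworkConfig",
    "TwoSliceDAG",
    "two_slice_constraint",
    "transition_levels",
    "InitialNetworkLearner",
    "TransitionNetworkLearner",
    "learn_initial_network",
    "learn_transition_network",
    "ExactTransitionPosterior",
    "exact_transition_posterior",
]


@dataclass(frozen=True)
class TransitionNetworkConfig:
    """Settings for transition-network learning."""

    allow_contemporaneous: bool = False
    ess: float = 1.0
    max_parents: int = 4
    extra_forbidden: frozenset[tuple[str, str]] = frozenset()
    extra_required: frozenset[tuple[str, str]] = frozenset()
    include_static: bool = False  # demographic factors as exogenous @t nodes


class TwoSliceDAG(DAG):
    """A DAG over ``{f@t} ∪ {f@t1}`` respecting the slice constraints."""

    __slots__ = ()

    def __init__(self, nodes, parent_sets, allow_contemporaneous: bool = True):
        super().__init__(nodes, parent_sets)
        for v in self.nodes:
            if not (v.endswith(T_SUFFIX) or v.endswith(T1_SUFFIX)):
                raise ValueError(f"node {v!r} lacks a slice suffix")
            ps = self.parents(v)
            if v.endswith(T_SUFFIX) and ps:
                raise ValueError(f"slice-t node {v!r} must be exogenous")
            if v.endswith(T1_SUFFIX) and not allow_contemporaneous:
                bad = [u for u in ps if u.endswith(T1_SUFFIX)]
                if bad:
                    raise ValueError(
                        f"contemporaneous parents {bad} of {v!r} not allowed"
                    )

    @property
    def t_nodes(self) -> list[str]:
        return [v for v in self.nodes if v.endswith(T_SUFFIX)]

    @property
    def t1_nodes(self) -> list[str]:
        return [v for v in self.nodes if v.endswith(T1_SUFFIX)]


def _transition_factors(
    specs: Sequence[FactorSpec], config: TransitionNetworkConfig
) -> tuple[list[FactorSpec], list[FactorSpec]]:
    """Split specs into dynamic factors (both slices) and static @t-only ones."""
    dynamic = [s for s in specs if s.domain_group != "demographic"]
    static = (
        [s for s in specs if s.domain_group == "demographic"]
        if config.include_static
        else []
    )
    return dynamic, static


def two_slice_constraint(
    specs: Sequence[FactorSpec], config: TransitionNetworkConfig
) -> tuple[EdgeConstraint, list[str]]:
    """Build the slice blacklist; returns (constraint, node order)."""
    dynamic, static = _transition_factors(specs, config)
    t_nodes = [s.name + T_SUFFIX for s in dynamic] + [
        s.name + T_SUFFIX for s in static
    ]
    t1_nodes = [s.name + T1_SUFFIX for s in dynamic]
    nodes = t_nodes + t1_nodes
    forbidden = set(config.extra_forbidden)
    for v in t_nodes:  # slice t is exogenous
        for u in nodes:
            if u != v:
                forbidden.add((u, v))
    if not config.allow_contemporaneous:
        for u in t1_nodes:
            for v in t1_nodes:
                if u != v:
                    forbidden.add((u, v))
    constraint = EdgeConstraint(
        forbidden=frozenset(forbidden),
        required=frozenset(config.extra_required),
        max_parents=config.max_parents,
    )
    return constraint, nodes


def transition_levels(
    specs: Sequence[FactorSpec], config: TransitionNetworkConfig
) -> dict[str, tuple[str, ...]]:
    dynamic, static = _transition_factors(specs, config)
    levels: dict[str, tuple[str, ...]] = {}
    for s in dynamic + static:
        levels[s.name + T_SUFFIX] = s.levels
    for s in dynamic:
        levels[s.name + T1_SUFFIX] = s.levels
    return levels


class InitialNetworkLearner(BaseEstimator):
    """Posterior over the network of dependencies at first presentation.

    ``fit`` takes a :class:`CohortTable`; the complete-case t = 0 dataset
    is built internally and partition MCMC is run on it.
    """

    def __init__(
        self,
        specs: Sequence[FactorSpec],
        ess: float = 1.0,
        constraint: EdgeConstraint | None = None,
        max_parents: int = 4,
        n_iter: int = 100_000,
        burn_in: int | None = None,
        thin: int = 100,
        n_chains: int = 2,
        random_state: int | None = None,
    ):
        self.specs = specs
        self.ess = ess
        self.constraint = constraint
        self.max_parents = max_parents
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.n_chains = n_chains
        self.random_state = random_state

    def fit(self, X: CohortTable, y=None):
        dataset = build_initial_dataset(X, self.specs)
        data = CategoricalData(
            dataset.rows, {s.name: s.levels for s in self.specs}
        )
        constraint = self.constraint or EdgeConstraint(max_parents=self.max_parents)
        sampler = PartitionMCMCSampler(
            ess=self.ess,
            constraint=constraint,
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            thin=self.thin,
            n_chains=self.n_chains,
            random_state=self.random_state,
        )
        sampler.fit(data)
        self.dataset_ = dataset
        self.posterior_ = sampler.posterior_
        self.edge_probabilities_ = sampler.edge_probabilities_
        self.convergence_gap_ = sampler.convergence_gap_
        return self


class TransitionNetworkLearner(BaseEstimator):
    """Posterior over the two-slice transition network.

    Only the ``@t1`` families carry information (slice-t nodes are
    exogenous with empty parent sets), so the learned edges describe how
    each factor at t + 1 depends on the previous timepoint and — in the
    contemporaneous regime — on other t + 1 factors.
    """

    def __init__(
        self,
        specs: Sequence[FactorSpec],
        config: TransitionNetworkConfig = TransitionNetworkConfig(),
        n_iter: int = 100_000,
        burn_in: int | None = None,
        thin: int = 100,
        n_chains: int = 2,
        random_state: int | None = None,
    ):
        self.specs = specs
        self.config = config
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.n_chains = n_chains
        self.random_state = random_state

    def fit(self, X: CohortTable, y=None):
        dataset = build_transition_dataset(X, self.specs)
        constraint, nodes = two_slice_constraint(self.specs, self.config)
        levels = transition_levels(self.specs, self.config)
        data = CategoricalData(dataset.rows, levels)
        sampler = PartitionMCMCSampler(
            ess=self.config.ess,
            constraint=constraint,
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            thin=self.thin,
            n_chains=self.n_chains,
            random_state=self.random_state,
        )
        sampler.fit(data)
        self.dataset_ = dataset
        self.constraint_ = constraint
        self.posterior_ = sampler.posterior_
        self.edge_probabilities_ = sampler.edge_probabilities_
        self.convergence_gap_ = sampler.convergence_gap_
        return self


def learn_initial_network(
    table: CohortTable,
    specs: Sequence[FactorSpec],
    constraint: EdgeConstraint | None = None,
    ess: float = 1.0,
    **mcmc,
) -> PosteriorSample:
    learner = InitialNetworkLearner(specs, ess=ess, constraint=constraint, **mcmc)
    learner.fit(table)
    return learner.posterior_


def learn_transition_network(
    table: CohortTable,
    specs: Sequence[FactorSpec],
    config: TransitionNetworkConfig = TransitionNetworkConfig(),
    **mcmc,
) -> PosteriorSample:
    learner = TransitionNetworkLearner(specs, config=config, **mcmc)
    learner.fit(table)
    return learner.posterior_


class ExactTransitionPosterior:
    """Exact factorised posterior for the temporal-only transition network.

    With contemporaneous edges disabled the graph is bipartite and every
    combination of per-node parent sets is acyclic, so under the uniform
    structure prior the posterior factorises as independent distributions
    over each ``@t1`` node's parent set, each proportional to the BDeu
    family score.
    """

    def __init__(
        self,
        dataset: TransitionDataset,
        specs: Sequence[FactorSpec],
        config: TransitionNetworkConfig = TransitionNetworkConfig(),
    ):
        if config.allow_contemporaneous:
            raise ValueError(
                "exact factorisation requires allow_contemporaneous=False"
            )
        constraint, nodes = two_slice_constraint(specs, config)
        levels = transition_levels(specs, config)
        data = CategoricalData(dataset.rows, levels)
        cache = ScoreCache(data, config.ess)
        self.nodes = nodes
        self.t_nodes = [v for v in nodes if v.endswith(T_SUFFIX)]
        self.t1_nodes = [v for v in nodes if v.endswith(T1_SUFFIX)]
        self.constraint = constraint
        self.node_posteriors: dict[str, list[tuple[frozenset, float]]] = {}
        for v in self.t1_nodes:
            sets = allowed_parent_sets(v, nodes, constraint)
            logs = np.array([cache.family_score(v, s) for s in sets])
            probs = np.exp(logs - logsumexp(logs))
            self.node_posteriors[v] = list(zip(sets, probs))

    def map_parent_sets(self) -> dict[str, frozenset]:
        """Highest-posterior parent set per @t1 node."""
        return {
            v: max(entries, key=lambda e: e[1])[0]
            for v, entries in self.node_posteriors.items()
        }

    def edge_probabilities(self) -> dict[tuple[str, str], float]:
        out: dict[tuple[str, str], float] = {}
        for u in self.nodes:
            for v in self.nodes:
                if u != v:
                    out[(u, v)] = 0.0
        for v, entries in self.node_posteriors.items():
            for ps, p in entries:
                for u in ps:
                    out[(u, v)] += float(p)
        return out

    def sample(self, n_draws: int, seed: int) -> PosteriorSample:
        """Independent DAG draws from the exact posterior."""
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(n_draws):
            parent_sets: dict[str, frozenset] = {v: frozenset() for v in self.t_nodes}
            for v, entries in self.node_posteriors.items():
                probs = np.array([p for _, p in entries])
                k = int(rng.choice(len(entries), p=probs / probs.sum()))
                parent_sets[v] = entries[k][0]
            draws.append(DAG(self.nodes, parent_sets))
        return PosteriorSample(
            dags=draws, meta={"seed": seed, "exact_factorised": True}
        )


def exact_transition_posterior(
    dataset: TransitionDataset,
    specs: Sequence[FactorSpec],
    config: TransitionNetworkConfig = TransitionNetworkConfig(),
) -> ExactTransitionPosterior:
    return ExactTransitionPosterior(dataset, specs, config)
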