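"""Posterior-averaged interventional effect estimation.

For every sampled structure ``G`` the conditional probability tables are
set to their Dirichlet posterior means (BDeu-consistent hyperparameters,
so every CPT entry is strictly positive and relative risks stay finite).
The effect of factor A on factor B is the interventional relative risk

    RR_G = P(B = true | do(A = true)) / P(B = true | do(A = false))

computed by truncated factorisation (drop the intervened node's CPT,
clamp its value, marginalise the rest exactly by variable elimination).
Three-level diagnosis factors are collapsed to binary — true for sub- and
full-threshold — before the ratio is taken; for a three-level *source* the
point intervention is replaced by a soft intervention that sets the source
to its model marginal restricted to the truthy (resp. falsy) levels.

The posterior summary is the mean µ of ``{RR_G}`` over the sample and the
95% highest-density interval (the shortest window of sorted draws holding
the requested mass).  Pairs whose HDI contains 1 are flagged as not
reportable, matching the convention of only presenting effects whose
credible interval excludes no effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import T1_SUFFIX, T_SUFFIX, FactorSpec
from .scoring import DAG, CategoricalData
from .structure import PosteriorSample

__all__ = [
    "ParameterisedBN",
    "EffectEstimate",
    "fit_parameters",
    "interventional_marginal",
    "hdi",
    "causal_rr",
    "rr_matrix",
]


@dataclass
class ParameterisedBN:
    """A DAG plus posterior-mean CPTs.

    ``cpts[v]`` has shape ``(*parent_cards, r_v)`` with parents in sorted
    name order; every row is a strictly positive distribution.
    """

    dag: DAG
    levels: dict[str, tuple[str, ...]]
    parent_order: dict[str, tuple[str, ...]]
    cpts: dict[str, np.ndarray]

    def card(self, node: str) -> int:
        return len(self.levels[node])


def fit_parameters(
    dag: DAG,
    data: CategoricalData,
    prior_ess: float = 1.0,
    rng: np.random.Generator | None = None,
) -> ParameterisedBN:
    """Dirichlet posterior-mean CPTs: (n_jk + ess/(q r)) / (n_j + ess/q).

    When ``rng`` is given, each CPT row is instead *drawn* from its
    Dirichlet posterior — propagating parameter uncertainty into
    posterior-averaged effects rather than plugging in the mean.
    """
    if prior_ess <= 0:
        raise ValueError("prior_ess must be positive")
    if data.n_rows == 0:
        warnings.warn("empty dataset: returning prior-mean CPTs")
    levels = {v: data.levels[v] for v in dag.nodes}
    parent_order: dict[str, tuple[str, ...]] = {}
    cpts: dict[str, np.ndarray] = {}
    for v in dag.nodes:
        parents = tuple(sorted(dag.parents(v)))
        parent_order[v] = parents
        r = data.cards[v]
        cards = [data.cards[p] for p in parents]
        q = int(np.prod(cards)) if parents else 1
        if data.n_rows:
            j = np.zeros(data.n_rows, dtype=np.int64)
            for p, card in zip(parents, cards):
                j = j * card + data.codes(p)
            njk = np.bincount(j * r + data.codes(v), minlength=q * r).reshape(q, r)
        else:
            njk = np.zeros((q, r))
        a_jk = prior_ess / (q * r)
        if rng is None:
            post = (njk + a_jk) / (njk.sum(axis=1, keepdims=True) + prior_ess / q)
        else:
            post = rng.gamma(njk + a_jk)
            post = post / post.sum(axis=1, keepdims=True)
            post = np.clip(post, 1e-12, None)
            post = post / post.sum(axis=1, keepdims=True)
        cpts[v] = post.reshape(*cards, r)
    return ParameterisedBN(dag=dag, levels=levels, parent_order=parent_order, cpts=cpts)


# ---------------------------------------------------------------------------
# Exact inference by variable elimination


@dataclass
class _Factor:
    vars: tuple[str, ...]
    table: np.ndarray


def _multiply(factors: list[_Factor], cards: Mapping[str, int]) -> _Factor:
    union: list[str] = []
    for f in factors:
        for v in f.vars:
            if v not in union:
                union.append(v)
    shape = tuple(cards[v] for v in union)
    out = np.ones(shape)
    for f in factors:
        idx = [union.index(v) for v in f.vars]
        expand = f.table
        order = np.argsort(idx)
        expand = np.transpose(expand, axes=order)
        full = [slice(None) if i in idx else np.newaxis for i in range(len(union))]
        out = out * expand[tuple(full)]
    return _Factor(tuple(union), out)


def _eliminate_all(
    factors: list[_Factor], keep: set[str], cards: Mapping[str, int]
) -> _Factor:
    factors = list(factors)
    while True:
        elim = sorted(
            {v for f in factors for v in f.vars} - keep,
            key=lambda v: (
                int(
                    np.prod(
                        [
                            cards[u]
                            for u in {
                                w for f in factors if v in f.vars for w in f.vars
                            }
                        ]
                    )
                ),
                v,
            ),
        )
        if not elim:
            break
        v = elim[0]
        related = [f for f in factors if v in f.vars]
        rest = [f for f in factors if v not in f.vars]
        prod = _multiply(related, cards)
        axis = prod.vars.index(v)
        summed = _Factor(
            tuple(u for u in prod.vars if u != v), prod.table.sum(axis=axis)
        )
        factors = rest + [summed]
    return _multiply(factors, cards)


def _relevant_nodes(dag: DAG, targets: Iterable[str]) -> set[str]:
    """Ancestral closure: barren nodes cannot affect the targets."""
    out = set(targets)
    frontier = list(out)
    while frontier:
        v = frontier.pop()
        for u in dag.parents(v):
            if u not in out:
                out.add(u)
                frontier.append(u)
    return out


def interventional_marginal(
    pbn: ParameterisedBN,
    do: Mapping[str, object],
    target: str,
) -> dict[str, float]:
    """P(target | do(assignments)) by truncated factorisation.

    ``do`` maps node -> level label (point intervention) or
    node -> {level: prob} (soft intervention).  Exact: agrees with full
    joint enumeration up to floating-point error.
    """
    if target in do:
        raise ValueError("target cannot be among the intervened nodes")
    for v in (target, *do):
        if v not in pbn.levels:
            raise ValueError(f"unknown node {v!r}")
    cards = {v: pbn.card(v) for v in pbn.dag.nodes}
    relevant = _relevant_nodes(pbn.dag, [target])
    factors: list[_Factor] = []
    for v in relevant:
        if v in do:
            continue
        parents = pbn.parent_order[v]
        factors.append(_Factor(parents + (v,), pbn.cpts[v]))
    for v, val in do.items():
        if v not in relevant:
            continue
        table = np.zeros(cards[v])
        if isinstance(val, Mapping):
            for lab, p in val.items():
                table[pbn.levels[v].index(lab)] = p
            table = table / table.sum()
        else:
            table[pbn.levels[v].index(val)] = 1.0
        factors.append(_Factor((v,), table))
    result = _eliminate_all(factors, {target}, cards)
    dist = result.table
    if result.vars != (target,):
        dist = np.asarray(dist).reshape(cards[target])
    dist = dist / dist.sum()
    return {lab: float(p) for lab, p in zip(pbn.levels[target], dist)}


def _conditional_prob_true(
    pbn: ParameterisedBN,
    source: str,
    source_levels: Sequence[str],
    target: str,
    truthy_target: Sequence[str],
) -> float:
    """Observational P(target in truthy | source in source_levels)."""
    cards = {v: pbn.card(v) for v in pbn.dag.nodes}
    relevant = _relevant_nodes(pbn.dag, [target, source])
    factors = [
        _Factor(pbn.parent_order[v] + (v,), pbn.cpts[v]) for v in relevant
    ]
    ev = np.zeros(cards[source])
    for lab in source_levels:
        ev[pbn.levels[source].index(lab)] = 1.0
    factors.append(_Factor((source,), ev))
    joint = _eliminate_all(factors, {target}, cards)
    dist = joint.table / joint.table.sum()
    return float(
        sum(dist[pbn.levels[target].index(lab)] for lab in truthy_target)
    )


def hdi(values: Sequence[float], mass: float = 0.95) -> tuple[float, float]:
    """Highest-density interval: shortest window of sorted draws with the mass."""
    if not 0 < mass < 1:
        raise ValueError("mass must lie in (0, 1)")
    vals = np.sort(np.asarray(values, dtype=float))
    n = len(vals)
    if n < 2:
        raise ValueError("need at least 2 values")
    k = ceil(mass * n)
    widths = vals[k - 1 :] - vals[: n - k + 1]
    i = int(np.argmin(widths))
    return float(vals[i]), float(vals[i + k - 1])


@dataclass
class EffectEstimate:
    """Relative risk of B given an intervention on A, posterior-averaged."""

    source: str
    target: str
    rr_mean: float
    rr_hdi: tuple[float, float]
    rr_values: np.ndarray

    @property
    def reportable(self) -> bool:
        low, high = self.rr_hdi
        return not (low <= 1.0 <= high)


def _spec_for(node: str, specs: Sequence[FactorSpec]) -> FactorSpec:
    base = node
    for suf in (T1_SUFFIX, T_SUFFIX):
        if base.endswith(suf):
            base = base[: -len(suf)]
            break
    for s in specs:
        if s.name == base:
            return s
    raise KeyError(f"no factor spec for node {node!r}")


def _do_value(
    pbn: ParameterisedBN, node: str, levels: Sequence[str]
) -> object:
    """Point intervention when unambiguous, soft (restricted marginal) otherwise."""
    if len(levels) == 1:
        return levels[0]
    marg = interventional_marginal(pbn, {}, node)
    return {lab: marg[lab] for lab in levels}


def _rr_for_pbn(
    pbn: ParameterisedBN,
    A: str,
    B: str,
    spec_a: FactorSpec,
    spec_b: FactorSpec,
    mode: str,
) -> float:
    truthy_a = [l for l in spec_a.levels if l in spec_a.truthy_levels]
    falsy_a = [l for l in spec_a.levels if l not in spec_a.truthy_levels]
    truthy_b = list(spec_b.truthy_levels)
    if mode == "interventional":
        if A not in _relevant_nodes(pbn.dag, [B]):
            return 1.0  # B is not a descendant of A: intervening cannot move it
        p1_dist = interventional_marginal(pbn, {A: _do_value(pbn, A, truthy_a)}, B)
        p0_dist = interventional_marginal(pbn, {A: _do_value(pbn, A, falsy_a)}, B)
        p1 = sum(p1_dist[l] for l in truthy_b)
        p0 = sum(p0_dist[l] for l in truthy_b)
    elif mode == "observational":
        p1 = _conditional_prob_true(pbn, A, truthy_a, B, truthy_b)
        p0 = _conditional_prob_true(pbn, A, falsy_a, B, truthy_b)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return p1 / p0


def causal_rr(
    sample: PosteriorSample,
    data: CategoricalData,
    specs: Sequence[FactorSpec],
    A: str,
    B: str,
    prior_ess: float = 1.0,
    mode: str = "interventional",
    hdi_mass: float = 0.95,
    sample_cpts: bool = False,
    random_state: int | None = None,
    _pbn_cache: dict[DAG, ParameterisedBN] | None = None,
) -> EffectEstimate:
    """Posterior-averaged relative risk of B under interventions on A.

    With ``sample_cpts=True`` a fresh CPT draw from the Dirichlet posterior
    is taken for every structure draw (one RR per (structure, parameter)
    draw), so the HDI reflects parameter as well as structure uncertainty;
    the default plugs in posterior-mean CPTs (structure uncertainty only).
    """
    if A == B:
        raise ValueError("source and target must differ")
    spec_a = _spec_for(A, specs)
    spec_b = _spec_for(B, specs)
    for node, spec in ((A, spec_a), (B, spec_b)):
        codes = data.codes(node)
        if len(codes) and len(np.unique(codes)) == 1:
            warnings.warn(
                f"factor {node!r} has a single observed level; the estimate "
                "rests entirely on Dirichlet smoothing"
            )
    if sample_cpts and random_state is None:
        raise ValueError("sample_cpts=True requires random_state")
    rng = np.random.default_rng(random_state) if sample_cpts else None
    cache = _pbn_cache if _pbn_cache is not None else {}
    rr_by_dag: dict[DAG, float] = {}
    values = np.empty(len(sample.dags))
    for i, dag in enumerate(sample.dags):
        if sample_cpts:
            pbn = fit_parameters(dag, data, prior_ess, rng=rng)
            values[i] = _rr_for_pbn(pbn, A, B, spec_a, spec_b, mode)
            continue
        rr = rr_by_dag.get(dag)
        if rr is None:
            pbn = cache.get(dag)
            if pbn is None:
                pbn = fit_parameters(dag, data, prior_ess)
                cache[dag] = pbn
            rr = _rr_for_pbn(pbn, A, B, spec_a, spec_b, mode)
            rr_by_dag[dag] = rr
        values[i] = rr
    if len(values) >= 2:
        interval = hdi(values, hdi_mass)
    else:
        interval = (float(values[0]), float(values[0]))
    return EffectEstimate(
        source=A,
        target=B,
        rr_mean=float(values.mean()),
        rr_hdi=interval,
        rr_values=values,
    )


def rr_matrix(
    sample: PosteriorSample,
    data: CategoricalData,
    specs: Sequence[FactorSpec],
    prior_ess: float = 1.0,
    mode: str = "interventional",
    hdi_mass: float = 0.95,
    sample_cpts: bool = False,
    random_state: int | None = None,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Effect estimates for all ordered factor pairs, with suppression flags.

    For a two-slice sample the pairs run from ``@t`` sources to ``@t1``
    targets (same-factor persistence pairs included like any other); the
    ``reportable`` column is True iff the HDI excludes 1, which is the
    filter applied when rendering the matrix.
    """
    nodes = sample.nodes
    if pairs is None:
        t_nodes = [v for v in nodes if v.endswith(T_SUFFIX)]
        t1_nodes = [v for v in nodes if v.endswith(T1_SUFFIX)]
        if t_nodes and t1_nodes:
            pairs = [(a, b) for a in t_nodes for b in t1_nodes]
        else:
            pairs = [(a, b) for a in nodes for b in nodes if a != b]
    cache: dict[DAG, ParameterisedBN] = {}
    records = []
    for k, (a, b) in enumerate(pairs):
        est = causal_rr(
            sample, data, specs, a, b, prior_ess=prior_ess, mode=mode,
            hdi_mass=hdi_mass, sample_cpts=sample_cpts,
            random_state=(None if random_state is None else random_state + k),
            _pbn_cache=cache,
        )
        records.append(
            {
                "source": a,
                "target": b,
                "rr_mean": est.rr_mean,
                "hdi_low": est.rr_hdi[0],
                "hdi_high": est.rr_hdi[1],
                "reportable": est.reportable,
            }
        )
    return pd.DataFrame.from_records(records)
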