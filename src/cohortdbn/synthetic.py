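"""Synthetic longitudinal cohorts from a known ground-truth DBN.

The default ground truth emulates a youth mental-health cohort: ~16
categorical factors across five clinical domains (social/occupational
function, self-harm & suicidality, alcohol & substance use, physical
health, psychiatric syndromes) plus static demographic/history factors,
mostly binary with two three-level diagnosis factors
(none / subthreshold / full-threshold).  Every factor gets a strong
same-factor persistence edge across timepoints, and a documented set of
cross-domain edges (e.g. functioning -> ideation, ideation -> attempt) is
planted with interventional relative risks >= 1.5.

CPT rows are logistic in the active (truthy) parents:

    P(child truthy | parents) = sigmoid(logit(base) + Σ_i β_i [parent_i truthy])

with base prevalences drawn per factor from U(0.05, 0.35) — kept below
saturation so the planted multiplicative contrasts survive — persistence
weight β = 2.0 and cross-edge weight β = 1.8.  Three-level children split
their truthy mass 60/40 between subthreshold and full-threshold.

Attendance is irregular: whole records are deleted missing-completely-at-
random at ``missing_timepoint_rate`` (subjects can reappear after a gap),
and each subject drops out after a geometric number of timepoints.  An
optional outcome-dependent missingness mode deletes records preferentially
when a chosen factor is truthy, to probe the missing-at-random assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    SUBJECT_COL,
    T1_SUFFIX,
    T_SUFFIX,
    TIME_COL,
    CohortTable,
    FactorSpec,
)
from .effects import ParameterisedBN, _rr_for_pbn, interventional_marginal
from .scoring import DAG

__all__ = [
    "GroundTruthDBN",
    "SimulationConfig",
    "make_default_truth",
    "simulate_cohort",
    "structure_recovery_report",
    "analytic_transition_rr",
]

PERSISTENCE_BETA = 2.0
CROSS_BETA = 1.8


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return float(np.log(p / (1.0 - p)))


@dataclass
class GroundTruthDBN:
    """Known initial + transition networks used to generate cohorts."""

    specs: list[FactorSpec]
    initial: ParameterisedBN
    transition: ParameterisedBN
    cross_edges: list[tuple[str, str]]  # planted (factor@t, factor@t1), no persistence
    seed: int = 0

    @property
    def dynamic_factors(self) -> list[FactorSpec]:
        return [s for s in self.specs if s.domain_group != "demographic"]

    @property
    def static_factors(self) -> list[FactorSpec]:
        return [s for s in self.specs if s.domain_group == "demographic"]

    def transition_edges(self) -> list[tuple[str, str]]:
        return self.transition.dag.edges()

    def domain_groups(self) -> dict[str, str]:
        return {s.name: s.domain_group for s in self.specs}


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 2663
    n_timepoints: int = 4
    missing_timepoint_rate: float = 0.15
    dropout_rate: float = 0.15
    seed: int = 0
    mnar_factor: str | None = None  # outcome-dependent missingness probe
    mnar_extra_rate: float = 0.2

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_timepoints < 1:
            raise ValueError("n_subjects and n_timepoints must be >= 1")
        for r in (self.missing_timepoint_rate, self.dropout_rate):
            if not 0 <= r < 1:
                raise ValueError("rates must lie in [0, 1)")


def _default_specs() -> list[FactorSpec]:
    binary = ("false", "true")
    three = ("none", "subthreshold", "full-threshold")

    def b(name, group):
        return FactorSpec(name, binary, group, ("true",))

    return [
        b("sofas_good", "function"),
        b("neet", "function"),
        b("self_harm", "suicidality"),
        b("ideation", "suicidality"),
        b("attempt", "suicidality"),
        b("alcohol", "substance"),
        b("cannabis", "substance"),
        b("other_drug", "substance"),
        b("addiction", "substance"),
        b("physical_illness", "physical"),
        FactorSpec("depression", three, "syndrome", ("subthreshold", "full-threshold")),
        FactorSpec("anxiety", three, "syndrome", ("subthreshold", "full-threshold")),
        b("bipolar", "syndrome"),
        b("manic_like", "syndrome"),
        b("psychosis_like", "syndrome"),
        b("circadian", "syndrome"),
        # static covariates: initial network only (by default)
        b("age_over_18", "demographic"),
        b("family_history", "demographic"),
        b("childhood_onset", "demographic"),
    ]


INITIAL_EDGES = [
    ("childhood_onset", "depression"),
    ("family_history", "depression"),
    ("depression", "anxiety"),
    ("depression", "ideation"),
    ("ideation", "self_harm"),
    ("self_harm", "attempt"),
    ("attempt", "sofas_good"),
    ("sofas_good", "neet"),
    ("alcohol", "cannabis"),
    ("cannabis", "other_drug"),
    ("other_drug", "manic_like"),
    ("manic_like", "psychosis_like"),
    ("bipolar", "circadian"),
    ("age_over_18", "alcohol"),
]

CROSS_EDGES = [
    ("sofas_good", "ideation"),
    ("sofas_good", "self_harm"),
    ("ideation", "attempt"),
    ("ideation", "self_harm"),
    ("depression", "ideation"),
    ("alcohol", "cannabis"),
    ("cannabis", "other_drug"),
    ("other_drug", "manic_like"),
    ("manic_like", "psychosis_like"),
    ("bipolar", "circadian"),
]


def _build_cpts(
    dag: DAG,
    specs_by_name: Mapping[str, FactorSpec],
    base_prev: Mapping[str, float],
    betas: Mapping[tuple[str, str], float],
    strip_suffix: bool = False,
) -> ParameterisedBN:
    """Logistic CPTs over truthy-parent activations."""

    def base_name(node: str) -> str:
        if strip_suffix:
            for suf in (T1_SUFFIX, T_SUFFIX):
                if node.endswith(suf):
                    return node[: -len(suf)]
        return node

    levels = {v: specs_by_name[base_name(v)].levels for v in dag.nodes}
    parent_order = {v: tuple(sorted(dag.parents(v))) for v in dag.nodes}
    cpts: dict[str, np.ndarray] = {}
    for v in dag.nodes:
        spec = specs_by_name[base_name(v)]
        parents = parent_order[v]
        cards = [len(levels[p]) for p in parents]
        b0 = _logit(base_prev[base_name(v)])
        shape = (*cards, len(spec.levels))
        table = np.zeros(shape)
        for config in np.ndindex(*cards) if parents else [()]:
            z = b0
            for p, code in zip(parents, config):
                pspec = specs_by_name[base_name(p)]
                if pspec.levels[code] in pspec.truthy_levels:
                    z += betas[(p, v)]
            p_true = float(_sigmoid(z))
            if len(spec.levels) == 2:
                row = np.array([1.0 - p_true, p_true])
            else:  # none / subthreshold / full-threshold
                row = np.array([1.0 - p_true, 0.6 * p_true, 0.4 * p_true])
            table[config] = row
        cpts[v] = table
    return ParameterisedBN(
        dag=dag, levels=levels, parent_order=parent_order, cpts=cpts
    )


def make_default_truth(seed: int = 0) -> GroundTruthDBN:
    """Build the default ground-truth DBN (deterministic in ``seed``)."""
    rng = np.random.default_rng(seed)
    specs = _default_specs()
    by_name = {s.name: s for s in specs}
    base_prev = {
        s.name: float(rng.uniform(0.05, 0.35)) for s in specs
    }

    init_nodes = [s.name for s in specs]
    init_parents: dict[str, set[str]] = {v: set() for v in init_nodes}
    init_betas: dict[tuple[str, str], float] = {}
    for u, v in INITIAL_EDGES:
        init_parents[v].add(u)
        init_betas[(u, v)] = CROSS_BETA
    initial_dag = DAG(init_nodes, init_parents)
    initial = _build_cpts(initial_dag, by_name, base_prev, init_betas)

    dynamic = [s.name for s in specs if s.domain_group != "demographic"]
    nodes = [f + T_SUFFIX for f in dynamic] + [f + T1_SUFFIX for f in dynamic]
    parents: dict[str, set[str]] = {v: set() for v in nodes}
    betas: dict[tuple[str, str], float] = {}
    for f in dynamic:  # same-factor persistence for every factor
        parents[f + T1_SUFFIX].add(f + T_SUFFIX)
        betas[(f + T_SUFFIX, f + T1_SUFFIX)] = PERSISTENCE_BETA
    cross = []
    for u, v in CROSS_EDGES:
        parents[v + T1_SUFFIX].add(u + T_SUFFIX)
        betas[(u + T_SUFFIX, v + T1_SUFFIX)] = CROSS_BETA
        cross.append((u + T_SUFFIX, v + T1_SUFFIX))
    transition_dag = DAG(nodes, parents)
    transition = _build_cpts(
        transition_dag, by_name, base_prev, betas, strip_suffix=True
    )
    return GroundTruthDBN(
        specs=specs,
        initial=initial,
        transition=transition,
        cross_edges=cross,
        seed=seed,
    )


def make_small_truth(seed: int = 0, n_factors: int = 5) -> GroundTruthDBN:
    """Compact binary two-slice generator for effect-recovery studies.

    Independent factors at t = 0 (empty initial network, so the slice-t
    product-of-marginals assumption holds exactly), same-factor persistence
    for every factor, and one planted cross edge f0@t -> f1@t1.  The pair
    (f2, f3) shares no edge or common parent, giving an exact null.
    """
    if n_factors < 4:
        raise ValueError("need at least 4 factors")
    rng = np.random.default_rng(seed)
    binary = ("false", "true")
    specs = [
        FactorSpec(f"f{i}", binary, "syndrome", ("true",)) for i in range(n_factors)
    ]
    by_name = {s.name: s for s in specs}
    base_prev = {s.name: float(rng.uniform(0.1, 0.35)) for s in specs}
    initial_dag = DAG([s.name for s in specs], {})
    initial = _build_cpts(initial_dag, by_name, base_prev, {})
    nodes = [s.name + T_SUFFIX for s in specs] + [s.name + T1_SUFFIX for s in specs]
    parents: dict[str, set[str]] = {v: set() for v in nodes}
    betas: dict[tuple[str, str], float] = {}
    for s in specs:
        parents[s.name + T1_SUFFIX].add(s.name + T_SUFFIX)
        betas[(s.name + T_SUFFIX, s.name + T1_SUFFIX)] = PERSISTENCE_BETA
    cross = [("f0" + T_SUFFIX, "f1" + T1_SUFFIX)]
    parents["f1" + T1_SUFFIX].add("f0" + T_SUFFIX)
    betas[("f0" + T_SUFFIX, "f1" + T1_SUFFIX)] = CROSS_BETA
    transition = _build_cpts(
        DAG(nodes, parents), by_name, base_prev, betas, strip_suffix=True
    )
    return GroundTruthDBN(
        specs=specs,
        initial=initial,
        transition=transition,
        cross_edges=cross,
        seed=seed,
    )


def _sample_bn(
    pbn: ParameterisedBN,
    rng: np.random.Generator,
    n: int,
    given: Mapping[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Vectorised ancestral sampling; ``given`` pins exogenous node codes."""
    values: dict[str, np.ndarray] = dict(given or {})
    for v in pbn.dag.topological_order():
        if v in values:
            continue
        parents = pbn.parent_order[v]
        table = pbn.cpts[v]
        r = table.shape[-1]
        flat = table.reshape(-1, r)
        if parents:
            cards = [pbn.card(p) for p in parents]
            j = np.zeros(n, dtype=np.int64)
            for p, card in zip(parents, cards):
                j = j * card + values[p]
            rows = flat[j]
        else:
            rows = np.broadcast_to(flat[0], (n, r))
        u = rng.random(n)
        values[v] = (u[:, None] >= rows.cumsum(axis=1)).sum(axis=1)
    return values


def simulate_cohort(
    truth: GroundTruthDBN, config: SimulationConfig
) -> CohortTable:
    """Ancestral sampling of a cohort from the ground-truth DBN.

    t = 0 is drawn from the initial network; each later timepoint from the
    transition network given the previous one; static factors are carried
    forward.  Whole records are then deleted at the missing-timepoint rate
    and subjects truncated after a geometric dropout draw.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    state = _sample_bn(truth.initial, rng, n)
    dynamic = [s.name for s in truth.dynamic_factors]
    static = [s.name for s in truth.static_factors]
    slices = [dict(state)]
    for _ in range(1, config.n_timepoints):
        given = {f + T_SUFFIX: slices[-1][f] for f in dynamic}
        drawn = _sample_bn(truth.transition, rng, n, given=given)
        nxt = {f: drawn[f + T1_SUFFIX] for f in dynamic}
        for f in static:
            nxt[f] = slices[-1][f]
        slices.append(nxt)

    if config.dropout_rate > 0:
        horizon = rng.geometric(config.dropout_rate, size=n)
    else:
        horizon = np.full(n, config.n_timepoints)
    miss = rng.random((n, config.n_timepoints)) < config.missing_timepoint_rate
    levels = {s.name: s.levels for s in truth.specs}
    if config.mnar_factor is not None:
        spec = next(s for s in truth.specs if s.name == config.mnar_factor)
        truthy_codes = {spec.levels.index(l) for l in spec.truthy_levels}
        extra = rng.random((n, config.n_timepoints)) < config.mnar_extra_rate
        for t, sl in enumerate(slices):
            active = np.isin(sl[config.mnar_factor], list(truthy_codes))
            miss[:, t] |= extra[:, t] & active

    records = []
    factor_names = [s.name for s in truth.specs]
    for t, sl in enumerate(slices):
        keep = (~miss[:, t]) & (t < horizon)
        idx = np.nonzero(keep)[0]
        if not len(idx):
            continue
        rec = {SUBJECT_COL: [f"s{i:05d}" for i in idx], TIME_COL: t}
        for f in factor_names:
            labs = np.array(levels[f])
            rec[f] = labs[sl[f][idx]]
        records.append(pd.DataFrame(rec))
    df = pd.concat(records, ignore_index=True)
    return CohortTable(df, tuple(factor_names))


def analytic_transition_rr(truth: GroundTruthDBN, A: str, B: str) -> float:
    """Ground-truth interventional RR from ``A@t`` to ``B@t1``.

    Exact summation over the two-slice model with the slice-t factors at
    their initial-network marginals (treated as independent, which is the
    transition model's own assumption about slice t).
    """
    by_name = {s.name: s for s in truth.specs}
    a_node = A if A.endswith(T_SUFFIX) else A + T_SUFFIX
    b_node = B if B.endswith(T1_SUFFIX) else B + T1_SUFFIX
    pbn = _transition_with_marginals(truth)
    base_a = a_node[: -len(T_SUFFIX)]
    base_b = b_node[: -len(T1_SUFFIX)]
    return _rr_for_pbn(
        pbn, a_node, b_node, by_name[base_a], by_name[base_b], "interventional"
    )


def _transition_with_marginals(truth: GroundTruthDBN) -> ParameterisedBN:
    pbn = truth.transition
    cpts = dict(pbn.cpts)
    for f in (s.name for s in truth.dynamic_factors):
        marg = interventional_marginal(truth.initial, {}, f)
        cpts[f + T_SUFFIX] = np.array(
            [marg[l] for l in truth.initial.levels[f]]
        )
    return ParameterisedBN(
        dag=pbn.dag, levels=pbn.levels, parent_order=pbn.parent_order, cpts=cpts
    )


@dataclass
class RecoveryReport:
    edges: pd.DataFrame  # source, target, truth, probability
    tpr: float
    fpr: float
    auc: float


def structure_recovery_report(
    truth: GroundTruthDBN,
    learned: Mapping[tuple[str, str], float],
    threshold: float = 0.5,
) -> RecoveryReport:
    """Compare learned edge probabilities against the planted structure.

    Scored over the candidate ordered pairs of the transition problem
    (cross-slice pairs, plus within-t1 pairs when the truth contains
    contemporaneous edges).
    """
    true_edges = set(truth.transition_edges())
    nodes = truth.transition.dag.nodes
    t_nodes = [v for v in nodes if v.endswith(T_SUFFIX)]
    t1_nodes = [v for v in nodes if v.endswith(T1_SUFFIX)]
    pairs = [(a, b) for a in t_nodes for b in t1_nodes]
    if any(u.endswith(T1_SUFFIX) for u, _ in true_edges):
        pairs += [(a, b) for a in t1_nodes for b in t1_nodes if a != b]
    learned_nodes = {x for pair in learned for x in pair}
    if not set(nodes) <= learned_nodes:
        raise ValueError(
            f"node mismatch: learned table lacks {sorted(set(nodes) - learned_nodes)[:4]}"
        )
    rows = []
    for a, b in pairs:
        rows.append(
            {
                "source": a,
                "target": b,
                "truth": (a, b) in true_edges,
                "probability": float(learned.get((a, b), 0.0)),
            }
        )
    df = pd.DataFrame(rows)
    labels = df["truth"].to_numpy()
    probs = df["probability"].to_numpy()
    pred = probs > threshold
    tpr = float(pred[labels].mean()) if labels.any() else float("nan")
    fpr = float(pred[~labels].mean()) if (~labels).any() else float("nan")
    if labels.any() and (~labels).any():
        from sklearn.metrics import roc_auc_score

        auc = float(roc_auc_score(labels, probs))
    else:
        auc = float("nan")
    return RecoveryReport(edges=df, tpr=tpr, fpr=fpr, auc=auc)
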