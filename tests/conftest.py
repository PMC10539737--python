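"""Shared fixtures and brute-force helpers for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from cohortdbn import CohortTable, DAG, FactorSpec

BINARY = ("false", "true")
THREE = ("none", "subthreshold", "full-threshold")


def binary_spec(name: str, group: str = "syndrome") -> FactorSpec:
    return FactorSpec(name, BINARY, group, ("true",))


def diagnosis_spec(name: str) -> FactorSpec:
    return FactorSpec(name, THREE, "syndrome", ("subthreshold", "full-threshold"))


def all_dags(nodes: tuple[str, ...]) -> list[DAG]:
    """Every labelled DAG on the given nodes, by brute-force enumeration."""
    out: list[DAG] = []

    def rec(i: int, parents: list):
        if i == len(nodes):
            try:
                out.append(DAG(nodes, dict(zip(nodes, map(set, parents)))))
            except ValueError:
                pass
            return
        others = [x for x in nodes if x != nodes[i]]
        for k in range(len(others) + 1):
            for s in itertools.combinations(others, k):
                rec(i + 1, parents + [s])

    rec(0, [])
    return out


def skeleton_and_vstructures(dag: DAG):
    """Markov-equivalence invariants: shared skeleton and v-structures."""
    edges = set(dag.edges())
    skel = frozenset(frozenset(e) for e in edges)
    vs = set()
    for v in dag.nodes:
        for a, b in itertools.combinations(sorted(dag.parents(v)), 2):
            if (a, b) not in edges and (b, a) not in edges:
                vs.add((frozenset((a, b)), v))
    return skel, frozenset(vs)


def equivalence_classes(nodes: tuple[str, ...]) -> dict:
    classes: dict = {}
    for d in all_dags(nodes):
        classes.setdefault(skeleton_and_vstructures(d), []).append(d)
    return classes


def random_binary_frame(
    columns: tuple[str, ...], n: int, seed: int
) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {c: np.where(rng.random(n) < 0.5, "true", "false") for c in columns}
    )


@pytest.fixture
def tiny_cohort() -> tuple[CohortTable, list[FactorSpec]]:
    """3 subjects x 2 timepoints, two binary factors, no missingness."""
    specs = [binary_spec("a"), binary_spec("b")]
    rows = []
    for i, subj in enumerate(("s1", "s2", "s3")):
        for t in (0, 1):
            rows.append(
                {
                    "subject_id": subj,
                    "timepoint": t,
                    "a": "true" if (i + t) % 2 else "false",
                    "b": "false",
                }
            )
    return CohortTable(pd.DataFrame(rows), ("a", "b")), specs
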