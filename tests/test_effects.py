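"""CPT fitting, exact interventional inference, HDIs and relative risks."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cohortdbn import (
    DAG,
    CategoricalData,
    ParameterisedBN,
    PosteriorSample,
    causal_rr,
    fit_parameters,
    hdi,
    interventional_marginal,
    rr_matrix,
)
from cohortdbn.effects import _rr_for_pbn

from conftest import binary_spec

LEVELS2 = ("f", "t")


def binary_data(frame):
    return CategoricalData(frame, {c: LEVELS2 for c in frame.columns})


def random_pbn(nodes, seed, max_parents=3):
    """Random binary network with uniform-random CPTs (ancestral order)."""
    rng = np.random.default_rng(seed)
    parents = {}
    for i, v in enumerate(nodes):
        pool = nodes[:i]
        k = min(len(pool), int(rng.integers(0, max_parents + 1)))
        parents[v] = (
            set(rng.choice(pool, size=k, replace=False)) if k else set()
        )
    dag = DAG(nodes, parents)
    po = {v: tuple(sorted(parents[v])) for v in nodes}
    cpts = {}
    for v in nodes:
        shape = tuple(2 for _ in po[v])
        p = rng.uniform(0.05, 0.95, size=shape)
        cpts[v] = np.stack([1 - p, p], axis=-1)
    levels = {v: LEVELS2 for v in nodes}
    return ParameterisedBN(dag, levels, po, cpts)


def brute_force_do(pbn, do_node, do_code, target):
    """Truncated-factorisation marginal by full joint enumeration."""
    nodes = pbn.dag.nodes
    tot = np.zeros(2)
    for assign in itertools.product([0, 1], repeat=len(nodes)):
        a = dict(zip(nodes, assign))
        if a[do_node] != do_code:
            continue
        p = 1.0
        for v in nodes:
            if v == do_node:
                continue
            idx = tuple(a[u] for u in pbn.parent_order[v]) + (a[v],)
            p *= pbn.cpts[v][idx]
        tot[a[target]] += p
    return tot / tot.sum()


class TestFitParameters:
    def test_posterior_mean_closed_form(self):
        # q=2, r=2, ess=1: alpha_jk=1/4, alpha_j=1/2; counts (3 true, 1 false)
        # at parent=true give P(t|parent=t) = 3.25/4.5
        rows = (
            [{"p": "t", "x": "t"}] * 3 + [{"p": "t", "x": "f"}] + [{"p": "f", "x": "f"}] * 2
        )
        data = binary_data(pd.DataFrame(rows))
        pbn = fit_parameters(DAG(("p", "x"), {"x": {"p"}}), data, prior_ess=1.0)
        assert pbn.cpts["x"][1, 1] == pytest.approx(3.25 / 4.5, abs=1e-12)

    def test_empty_data_returns_prior_mean_with_warning(self):
        data = binary_data(pd.DataFrame({"x": pd.Series([], dtype=str)}))
        with pytest.warns(UserWarning, match="prior-mean"):
            pbn = fit_parameters(DAG(("x",), {}), data)
        assert pbn.cpts["x"] == pytest.approx(np.array([0.5, 0.5]))

    def test_smoothing_keeps_cells_strictly_inside_unit_interval(self):
        data = binary_data(pd.DataFrame({"x": ["t"] * 5000}))
        pbn = fit_parameters(DAG(("x",), {}), data)
        assert 0.999 < pbn.cpts["x"][1] < 1.0

    def test_dirichlet_draws_are_valid_distributions(self):
        data = binary_data(pd.DataFrame({"p": ["t", "f"] * 20, "x": ["t", "t"] * 20}))
        pbn = fit_parameters(
            DAG(("p", "x"), {"x": {"p"}}), data, rng=np.random.default_rng(0)
        )
        rows = pbn.cpts["x"]
        assert np.all(rows > 0) and rows.sum(axis=-1) == pytest.approx(np.ones(2))


class TestInterventionalMarginal:
    def test_single_edge_do_parent_reads_cpt(self):
        pbn = random_pbn(("a", "b"), seed=1)
        pbn.dag = DAG(("a", "b"), {"b": {"a"}})
        pbn.parent_order = {"a": (), "b": ("a",)}
        p = np.array([[0.7, 0.3], [0.2, 0.8]])
        pbn.cpts = {"a": np.array([0.6, 0.4]), "b": p}
        out = interventional_marginal(pbn, {"a": "t"}, "b")
        assert out["t"] == pytest.approx(0.8)

    def test_do_child_leaves_parent_marginal(self):
        pbn = random_pbn(("a", "b"), seed=2)
        pbn.dag = DAG(("a", "b"), {"b": {"a"}})
        pbn.parent_order = {"a": (), "b": ("a",)}
        pbn.cpts = {"a": np.array([0.25, 0.75]), "b": np.array([[0.9, 0.1], [0.1, 0.9]])}
        out = interventional_marginal(pbn, {"b": "t"}, "a")
        assert out["t"] == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_joint_enumeration_on_random_networks(self, seed):
        nodes = tuple(f"x{i}" for i in range(8))
        pbn = random_pbn(nodes, seed=seed)
        do_node, target = nodes[seed % 3], nodes[-1]
        for code, lab in enumerate(LEVELS2):
            bf = brute_force_do(pbn, do_node, code, target)
            ve = interventional_marginal(pbn, {do_node: lab}, target)
            assert ve["t"] == pytest.approx(bf[1], abs=1e-10)

    def test_target_in_do_rejected(self):
        pbn = random_pbn(("a", "b"), seed=3)
        with pytest.raises(ValueError, match="target"):
            interventional_marginal(pbn, {"b": "t"}, "b")


class TestHdi:
    def test_degenerate_values(self):
        assert hdi([3.0, 3.0, 3.0]) == (3.0, 3.0)

    def test_integer_ramp_window(self):
        low, high = hdi(list(range(1, 101)), 0.95)
        assert high - low == 94

    def test_matches_exhaustive_window_search(self):
        rng = np.random.default_rng(4)
        values = rng.gamma(2.0, size=500)
        k = math.ceil(0.9 * len(values))
        s = np.sort(values)
        widths = [(s[i + k - 1] - s[i], s[i], s[i + k - 1]) for i in range(len(s) - k + 1)]
        expected = min(widths)[1:]
        assert hdi(values, 0.9) == pytest.approx(expected)

    def test_normal_draws_bracket_known_quantiles(self):
        vals = np.random.default_rng(5).normal(size=10000)
        low, high = hdi(vals)
        assert low == pytest.approx(-1.96, abs=0.1)
        assert high == pytest.approx(1.96, abs=0.1)

    def test_mass_validation(self):
        with pytest.raises(ValueError):
            hdi([1.0, 2.0], mass=1.5)
        with pytest.raises(ValueError):
            hdi([1.0])


class TestCausalRR:
    def test_single_draw_direct_ratio(self):
        pbn = random_pbn(("a", "b"), seed=6)
        pbn.dag = DAG(("a", "b"), {"b": {"a"}})
        pbn.parent_order = {"a": (), "b": ("a",)}
        pbn.cpts = {"a": np.array([0.5, 0.5]), "b": np.array([[0.8, 0.2], [0.2, 0.8]])}
        spec = binary_spec("a")  # levels (false, true) -- but pbn uses (f, t)
        pbn.levels = {"a": ("false", "true"), "b": ("false", "true")}
        rr = _rr_for_pbn(pbn, "a", "b", spec, binary_spec("b"), "interventional")
        assert rr == pytest.approx(4.0)

    def test_disconnected_pair_gives_exactly_one(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {
                "a": np.where(rng.random(200) < 0.4, "true", "false"),
                "b": np.where(rng.random(200) < 0.6, "true", "false"),
            }
        )
        data = CategoricalData(df, {c: ("false", "true") for c in df.columns})
        sample = PosteriorSample([DAG(("a", "b"), {})] * 5)
        est = causal_rr(sample, data, [binary_spec("a"), binary_spec("b")], "a", "b")
        assert est.rr_mean == 1.0 and est.rr_hdi == (1.0, 1.0)
        assert not est.reportable

    def test_pure_indirect_chain_recovers_analytic_rr(self):
        # A -> M -> B with no direct edge: the truncated factorisation
        # yields the total effect through the mediator
        truth = random_pbn(("A", "M", "B"), seed=8)
        truth.dag = DAG(("A", "M", "B"), {"M": {"A"}, "B": {"M"}})
        truth.parent_order = {"A": (), "M": ("A",), "B": ("M",)}
        truth.cpts = {
            "A": np.array([0.6, 0.4]),
            "M": np.array([[0.8, 0.2], [0.25, 0.75]]),
            "B": np.array([[0.85, 0.15], [0.3, 0.7]]),
        }
        analytic = (
            brute_force_do(truth, "A", 1, "B")[1]
            / brute_force_do(truth, "A", 0, "B")[1]
        )
        rng = np.random.default_rng(9)
        n = 5000
        a = rng.random(n) < 0.4
        m = np.where(a, rng.random(n) < 0.75, rng.random(n) < 0.2)
        b = np.where(m, rng.random(n) < 0.7, rng.random(n) < 0.15)
        df = pd.DataFrame(
            {
                "A": np.where(a, "true", "false"),
                "M": np.where(m, "true", "false"),
                "B": np.where(b, "true", "false"),
            }
        )
        data = CategoricalData(df, {c: ("false", "true") for c in df.columns})
        sample = PosteriorSample([truth.dag] * 10)
        specs = [binary_spec(x) for x in ("A", "M", "B")]
        est = causal_rr(sample, data, specs, "A", "B")
        assert est.rr_mean == pytest.approx(analytic, rel=0.10)

    def test_observational_mode_differs_under_confounding(self):
        # common cause c -> a, c -> b: no causal effect of a on b, but a
        # strong observational association
        pbn = random_pbn(("c", "a", "b"), seed=10)
        pbn.dag = DAG(("c", "a", "b"), {"a": {"c"}, "b": {"c"}})
        pbn.parent_order = {"c": (), "a": ("c",), "b": ("c",)}
        strong = np.array([[0.9, 0.1], [0.1, 0.9]])
        pbn.cpts = {"c": np.array([0.5, 0.5]), "a": strong, "b": strong}
        pbn.levels = {v: ("false", "true") for v in ("c", "a", "b")}
        sa, sb = binary_spec("a"), binary_spec("b")
        assert _rr_for_pbn(pbn, "a", "b", sa, sb, "interventional") == 1.0
        assert _rr_for_pbn(pbn, "a", "b", sa, sb, "observational") > 2.0

    def test_stronger_contrast_increases_rr(self):
        rrs = []
        for hi in (0.6, 0.75, 0.9):
            pbn = random_pbn(("a", "b"), seed=11)
            pbn.dag = DAG(("a", "b"), {"b": {"a"}})
            pbn.parent_order = {"a": (), "b": ("a",)}
            pbn.cpts = {
                "a": np.array([0.5, 0.5]),
                "b": np.array([[0.8, 0.2], [1 - hi, hi]]),
            }
            pbn.levels = {v: ("false", "true") for v in ("a", "b")}
            rrs.append(
                _rr_for_pbn(pbn, "a", "b", binary_spec("a"), binary_spec("b"), "interventional")
            )
        assert rrs[0] < rrs[1] < rrs[2]

    def test_three_level_source_uses_truthy_soft_intervention(self):
        from conftest import diagnosis_spec

        levels3 = ("none", "subthreshold", "full-threshold")
        dag = DAG(("d", "y"), {"y": {"d"}})
        po = {"d": (), "y": ("d",)}
        cpts = {
            "d": np.array([0.5, 0.3, 0.2]),
            "y": np.array([[0.9, 0.1], [0.5, 0.5], [0.2, 0.8]]),
        }
        pbn = ParameterisedBN(
            dag, {"d": levels3, "y": ("false", "true")}, po, cpts
        )
        rr = _rr_for_pbn(pbn, "d", "y", diagnosis_spec("d"), binary_spec("y"), "interventional")
        # truthy mass 0.3/0.2 renormalised: P1 = .6*.5 + .4*.8 = .62; P0 = .1
        assert rr == pytest.approx(0.62 / 0.1)


class TestRRMatrix:
    def test_reportable_flags_follow_hdi(self):
        rng = np.random.default_rng(12)
        n = 600
        a = rng.random(n) < 0.5
        b = np.where(a, rng.random(n) < 0.8, rng.random(n) < 0.2)
        c = rng.random(n) < 0.5
        df = pd.DataFrame(
            {k: np.where(v, "true", "false") for k, v in {"a": a, "b": b, "c": c}.items()}
        )
        data = CategoricalData(df, {k: ("false", "true") for k in df.columns})
        connected = DAG(("a", "b", "c"), {"b": {"a"}})
        sample = PosteriorSample([connected] * 20)
        specs = [binary_spec(x) for x in ("a", "b", "c")]
        mat = rr_matrix(
            sample, data, specs, sample_cpts=False
        ).set_index(["source", "target"])
        assert bool(mat.loc[("a", "b"), "reportable"])
        assert not bool(mat.loc[("a", "c"), "reportable"])  # rr exactly 1

    def test_two_slice_matrix_includes_same_factor_pairs(self):
        rows = []
        rng = np.random.default_rng(13)
        for i in range(200):
            x0 = rng.random() < 0.3
            x1 = rng.random() < (0.8 if x0 else 0.1)
            rows.append(
                {
                    "x@t": "true" if x0 else "false",
                    "x@t1": "true" if x1 else "false",
                }
            )
        df = pd.DataFrame(rows)
        data = CategoricalData(df, {c: ("false", "true") for c in df.columns})
        dag = DAG(("x@t", "x@t1"), {"x@t1": {"x@t"}})
        mat = rr_matrix(PosteriorSample([dag] * 5), data, [binary_spec("x")])
        assert mat[["source", "target"]].values.tolist() == [["x@t", "x@t1"]]
        assert mat["rr_mean"].iloc[0] > 2
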