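"""End-to-end pipeline: simulate → learn → summarise → effects.

A :class:`RunConfig` (YAML-loadable) drives the stages; every stage seed
is derived deterministically from the single top-level seed so stages can
be re-run in isolation, and the run manifest records input/output hashes
so a repeat run can be checked for bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .cpdag import map_summary_graph
from .datamodel import (
    T1_SUFFIX,
    T_SUFFIX,
    CohortTable,
    FactorSpec,
    build_transition_dataset,
    load_factor_specs,
    save_factor_specs,
)
from .dbn import (
    InitialNetworkLearner,
    TransitionNetworkConfig,
    TransitionNetworkLearner,
    transition_levels,
)
from .effects import rr_matrix
from .scoring import CategoricalData, EdgeConstraint, load_constraint
from .structure import save_posterior
from .synthetic import SimulationConfig, make_default_truth, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]


def stage_seed(seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed fan-out (kept below 2^31)."""
    return (seed * 9973 + 101 * stage_index + 7) % (2**31 - 1)


@dataclass
class RunConfig:
    output_dir: str
    seed: int = 0
    cohort_csv: str | None = None  # when None, a cohort is simulated
    specs_yaml: str | None = None
    constraint_yaml: str | None = None
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides
    factor_subset: list[str] | None = None  # analyse only these factors
    ess: float = 1.0
    max_parents: int = 4
    n_iter: int = 20_000
    burn_in: int | None = None
    thin: int = 20
    n_chains: int = 2
    threshold: float = 0.1
    hdi_mass: float = 0.95
    contemporaneous: bool = False
    secondary_contemporaneous: bool = False  # also run the secondary regime
    rr_all_cells: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        for p in (cfg.cohort_csv, cfg.specs_yaml, cfg.constraint_yaml):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_edge_probs(probs: Mapping[tuple[str, str], float], path: Path) -> None:
    rows = [
        {"source": u, "target": v, "probability": p}
        for (u, v), p in sorted(probs.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "inputs": {},
        "outputs": {},
    }

    def record(stage: str, t0: float, files: Sequence[Path]):
        manifest["stages"][stage] = {
            "seed": stage_seed(config.seed, list(STAGES).index(stage)),
            "wall_time_s": round(time.perf_counter() - t0, 3),
        }
        for f in files:
            manifest["outputs"][str(f.relative_to(out))] = _sha256(f)

    STAGES = ("simulate", "learn_initial", "learn_transition",
              "learn_transition_secondary", "summarize", "effects")
    try:
        # --- inputs / simulation ---------------------------------------
        t0 = time.perf_counter()
        if config.cohort_csv is None:
            truth = make_default_truth(stage_seed(config.seed, 0))
            sim = SimulationConfig(
                **{"seed": stage_seed(config.seed, 0), **config.simulate}
            )
            table = simulate_cohort(truth, sim)
            specs = truth.specs
            cohort_path = out / "cohort.csv"
            table.to_csv(cohort_path)
            specs_path = out / "factor_specs.yaml"
            save_factor_specs(specs, specs_path)
            truth_path = out / "truth_edges.json"
            truth_path.write_text(
                json.dumps(
                    {
                        "initial": truth.initial.dag.edges(),
                        "transition": truth.transition_edges(),
                        "provenance": {"seed": sim.seed, "config": asdict(sim)},
                    },
                    indent=2,
                    sort_keys=True,
                )
            )
            record("simulate", t0, [cohort_path, specs_path, truth_path])
        else:
            if config.specs_yaml is None:
                raise ValueError("specs_yaml is required with an external cohort")
            specs = load_factor_specs(config.specs_yaml)
            table = CohortTable.from_csv(config.cohort_csv, specs)
            manifest["inputs"]["cohort_csv"] = _sha256(Path(config.cohort_csv))
            manifest["inputs"]["specs_yaml"] = _sha256(Path(config.specs_yaml))

        if config.factor_subset:
            specs = [s for s in specs if s.name in set(config.factor_subset)]
            table = table.select_factors([s.name for s in specs])

        constraint = None
        if config.constraint_yaml is not None:
            constraint, con_ess = load_constraint(config.constraint_yaml)
            manifest["inputs"]["constraint_yaml"] = _sha256(
                Path(config.constraint_yaml)
            )
            if con_ess is not None:
                config.ess = con_ess

        mcmc = dict(
            n_iter=config.n_iter,
            burn_in=config.burn_in,
            thin=config.thin,
            n_chains=config.n_chains,
        )
        domain_groups = {s.name: s.domain_group for s in specs}

        # --- initial network -------------------------------------------
        t0 = time.perf_counter()
        init = InitialNetworkLearner(
            specs,
            ess=config.ess,
            constraint=constraint,
            max_parents=config.max_parents,
            random_state=stage_seed(config.seed, 1),
            **mcmc,
        ).fit(table)
        files = [out / "initial_posterior.jsonl", out / "initial_edge_probs.csv"]
        save_posterior(init.posterior_, files[0])
        _write_edge_probs(init.edge_probabilities_, files[1])
        record("learn_initial", t0, files)

        # --- transition network(s) -------------------------------------
        def run_transition(contemporaneous: bool, tag: str, idx: int):
            t0 = time.perf_counter()
            tcfg = TransitionNetworkConfig(
                allow_contemporaneous=contemporaneous,
                ess=config.ess,
                max_parents=config.max_parents,
            )
            learner = TransitionNetworkLearner(
                specs,
                config=tcfg,
                random_state=stage_seed(config.seed, idx),
                **mcmc,
            ).fit(table)
            files = [
                out / f"transition_posterior{tag}.jsonl",
                out / f"transition_edge_probs{tag}.csv",
            ]
            save_posterior(learner.posterior_, files[0])
            _write_edge_probs(learner.edge_probabilities_, files[1])
            record("learn_transition" + ("_secondary" if tag else ""), t0, files)
            return learner

        trans = run_transition(config.contemporaneous, "", 2)
        if config.secondary_contemporaneous and not config.contemporaneous:
            trans = run_transition(True, "_contemporaneous", 3)

        # --- CPDAG summaries -------------------------------------------
        t0 = time.perf_counter()
        files = []
        for name, sample in (
            ("initial", init.posterior_),
            ("transition", trans.posterior_),
        ):
            summary = map_summary_graph(
                sample, threshold=config.threshold, domain_groups=domain_groups
            )
            dot = out / f"{name}_summary.dot"
            dot.write_text(summary.to_dot())
            gml = out / f"{name}_summary.graphml"
            summary.to_graphml(gml)
            files += [dot, gml]
        record("summarize", t0, files)

        # --- effects ----------------------------------------------------
        t0 = time.perf_counter()
        tcfg = TransitionNetworkConfig(
            allow_contemporaneous=trans.config.allow_contemporaneous,
            ess=config.ess,
            max_parents=config.max_parents,
        )
        tdata = CategoricalData(
            trans.dataset_.rows, transition_levels(specs, tcfg)
        )
        rr = rr_matrix(
            trans.posterior_,
            tdata,
            specs,
            prior_ess=config.ess,
            hdi_mass=config.hdi_mass,
        )
        if not config.rr_all_cells:
            rr = rr[rr["reportable"]]
        rr_path = out / "rr_matrix.csv"
        rr.to_csv(rr_path, index=False)
        record("effects", t0, [rr_path])
    except Exception as exc:  # record partial completion before re-raising
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
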