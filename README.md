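# cohortdbn

Dynamic Bayesian network (DBN) inference for longitudinal categorical
cohorts — built for epidemiological follow-up data such as youth
mental-health service records, where a few thousand subjects are observed
at irregular visits on 15–20 categorical clinical factors (functioning,
self-harm and suicidality, substance use, physical health, psychiatric
syndromes) and the questions are *which factors depend on which*, at first
presentation and over time, and *how large the longitudinal effects are*.

The model has two parts:

* an **initial network** — a Bayesian network over the factors at first
  presentation (t = 0), learned from complete-case baseline records;
* a **transition network** — a two-slice network from factors at visit *t*
  to factors at visit *t + 1*, assumed homogeneous across consecutive visit
  pairs, learned from all stacked complete consecutive pairs.  In the
  primary regime the *t + 1* factors are conditionally independent given
  slice *t*; a secondary regime also allows contemporaneous edges among the
  *t + 1* factors.

Inference is fully Bayesian over structures.  With BDeu marginal
likelihood P(D | G) and a uniform prior over the DAGs allowed by an edge
blacklist, the posterior P(G | D) ∝ P(D | G) P(G) is sampled by **partition
MCMC**: a Markov chain over ordered node partitions (DAG layerings) with a
conditional DAG draw per recorded state.  Posterior samples are summarised
as:

* **edge probabilities** — the fraction of samples containing each edge,
  reported per direction after converting every sampled DAG to its CPDAG
  (completed partially directed acyclic graph), so that reversible edges
  count toward both directions;
* a **MAP summary graph** — the modal CPDAG, drawn with solid edges, plus
  dashed edges for directions above a probability threshold (default 0.1);
* **interventional relative risks** — for factors A, B the posterior mean µ
  and 95% highest-density interval of
  RR = P(B = true | do(A = true)) / P(B = true | do(A = false)),
  one RR per sampled structure (optionally per CPT draw), computed by
  truncated factorisation with exact variable elimination.  Cells whose
  HDI contains 1 are flagged not reportable.

Because clinical cohorts of this kind are rarely public, the package ships
a first-class synthetic-data module: a configurable ground-truth DBN
(~16 factors in five clinical domains, binary plus three-level diagnosis
factors, strong same-factor persistence, planted cross-domain effects,
irregular attendance and dropout) from which whole cohorts are simulated,
so the entire pipeline is testable end to end against known truth.

## Worked example

```python
import cohortdbn as cd

# a cohort from the default ground truth: 800 subjects, 4 visits,
# irregular attendance
truth = cd.make_default_truth(seed=0)
cohort = cd.simulate_cohort(truth, cd.SimulationConfig(
    n_subjects=800, n_timepoints=4, missing_timepoint_rate=0.15,
    dropout_rate=0.15, seed=1))

# learn the transition network (primary regime: temporal edges only)
learner = cd.TransitionNetworkLearner(
    truth.specs, n_iter=3000, burn_in=1000, thin=10, n_chains=2,
    random_state=2).fit(cohort)

p = learner.edge_probabilities_
print(f"P(ideation@t -> ideation@t1) = {p[('ideation@t', 'ideation@t1')]:.2f}")
print(f"P(sofas_good@t -> ideation@t1) = {p[('sofas_good@t', 'ideation@t1')]:.2f}")

# posterior-averaged interventional relative risk with 95% HDI
from cohortdbn.dbn import TransitionNetworkConfig, transition_levels
data = cd.CategoricalData(
    learner.dataset_.rows,
    transition_levels(truth.specs, TransitionNetworkConfig()))
est = cd.causal_rr(learner.posterior_, data, truth.specs,
                   "ideation@t", "ideation@t1",
                   sample_cpts=True, random_state=3)
print(f"RR = {est.rr_mean:.2f}, 95% HDI ({est.rr_hdi[0]:.2f}, {est.rr_hdi[1]:.2f})")
```

Output:

```
P(ideation@t -> ideation@t1) = 1.00
P(sofas_good@t -> ideation@t1) = 1.00
RR = 2.26, 95% HDI (2.00, 2.52)
```

The persistence and planted cross-domain edges are recovered with
posterior probability 1.00 at this sample size, and the same-factor
relative risk of ~2.3 says that suicidal ideation at one visit multiplies
the risk of ideation at the next visit by about 2.3 under the fitted
model, with the credible interval reflecting structure and parameter
uncertainty.

A command-line interface mirrors the library
(`cohortdbn simulate | learn-initial | learn-transition | summarize |
effects | run`); `cohortdbn run --config run.yaml` executes the whole
pipeline into a run directory with a reproducibility manifest.

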