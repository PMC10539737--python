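# Methods

## Model

A cohort is a set of subjects observed at integer visit indices
t = 0, 1, 2, … on categorical factors with 2 or 3 levels.  The joint model
is a dynamic Bayesian network: a Bayesian network over the factors at
t = 0 (the *initial network*) and a homogeneous two-slice conditional
model P(slice t+1 | slice t) (the *transition network*).  Visit indices
are treated as homogeneous steps — calendar spacing between visits is not
modelled, which is the stationarity assumption built into pooling all
consecutive pairs into one transition dataset.

Two complete-case datasets feed the two learners.  The initial dataset
keeps subjects whose t = 0 record has no missing factor.  The transition
dataset stacks one row per (subject, t) with complete records at both t
and t + 1; a missed visit breaks pairing, but later pairs of the same
subject still contribute, and a subject's multiple rows are treated as
exchangeable (no within-subject random effects).  No imputation is
performed anywhere; this is valid under missingness at random, and the
synthetic generator's optional outcome-dependent missingness mode exists
precisely to probe what happens when that assumption fails.

In the transition network the slice-t nodes are exogenous: only the
@t1 families are scored, since the marginal law of slice t is the initial
network's (or the empirical visit distribution's) job.  Factors in the
demographic domain (age group, family history, childhood onset) enter the
initial network only, unless `include_static=True` adds them as exogenous
@t nodes.

## Scoring and structure prior

Structures are scored by the BDeu marginal likelihood with equivalent
sample size `ess` (default 1.0, configurable) — chosen because it is
decomposable and *score equivalent*: Markov-equivalent DAGs receive
identical scores, which the CPDAG summaries presuppose.  For a node with
r states and q parent configurations the hyperparameters are
α_j = ess/q and α_jk = ess/(q·r); cardinalities come from the declared
factor levels, not the observed ones, so unobserved levels still shape
the prior.

The structure prior is uniform over the DAGs that satisfy an
`EdgeConstraint`: a forbidden-edge blacklist, an optional required-edge
whitelist, and an in-degree cap `max_parents` (default 4, which bounds the
per-node score tables at C(n−1, ≤4) entries and keeps exhaustive
parent-set enumeration cheap).  Blacklists ship as user-editable YAML;
a typical epidemiological rule forbids edges *into* fixed background
factors such as family history.

## Partition MCMC

The sampler's state is an ordered partition (λ₁, …, λ_m) of the node set —
the canonical layering of a DAG in which λ₁ holds the parentless nodes
and every node of λ_i (i > 1) has all parents in earlier layers and at
least one in λ_{i−1}.  Every DAG has exactly one layering, so sampling
partitions proportional to the sum of scores of their consistent DAGs and
then drawing a DAG from the partition's conditional distribution yields
unbiased posterior draws.  Per-node conditional sums are computed by
masked log-sum-exp over the precomputed parent-set score tables.

Proposals are uniform over a symmetric neighbourhood containing:

* single-node relocations to any other element or to a new singleton at
  any gap;
* adjacent-element swaps;
* binary ordered splits of an element and joins of adjacent elements,
  both only when the (combined) element size is at most 9, applied
  consistently in both directions so the neighbourhood stays symmetric;
* full reversal of the element order.  This move earns its place: the
  orientation modes of a Markov-equivalence class live in different
  layerings, and mirror-image layerings (e.g. the two end-rooted
  orientations of a chain) are otherwise only reachable through partitions
  whose score is many log-units lower.  Without the reversal move the
  chain allocates mass between those mode islands very slowly; with it,
  island hops accept at rate ≈ 1 and sampler-versus-enumeration agreement
  on 4-node problems tightens from worst-case ≈ 0.15 to < 0.02.

Acceptance is Metropolis–Hastings with the |N(λ)| / |N(λ′)| correction for
unequal neighbourhood sizes.  Nodes that cannot have parents under the
constraint are pinned to the first element: any state placing them
elsewhere has zero posterior mass, so excluding such states from the
proposal support leaves the stationary law untouched while sparing the
chain futile proposals (this matters for two-slice problems, where half
the nodes are exogenous).

Each chain is seeded as `SeedSequence([random_state, chain_index])`;
identical inputs and seed reproduce the draw list bit-identically, and an
unset seed is refused.  Defaults are 2 chains × 100 000 iterations, 20%
burn-in, thinning 100; the maximum cross-chain edge-probability gap is
reported as a convergence diagnostic.  The tests and the acceptance
script use shorter explicit settings (3 000–50 000 iterations depending
on problem size), which the oracle-agreement checks show are sufficient
at those sizes.  Known limitation: for large single-slice networks with
many near-equivalent orientations, mixing across orientation modes still
relies on valley crossings; longer chains and more chains are advised
there.  Two-slice problems are unaffected because the temporal blacklist
fixes all orientations.

Two exact oracles validate the sampler: full enumeration of all allowed
DAGs (guarded to ≤ 5 nodes), and — for the temporal-only transition
regime, where every graph is bipartite and acyclicity is automatic — the
closed-form factorised posterior over each @t1 node's parent sets.

## CPDAG summaries

Sampled DAGs are converted to CPDAGs with Chickering's compelled-edge
labelling (topological edge ordering plus propagation), verified in the
tests against brute-force orientation invariance over all equivalence
classes on ≤ 4 nodes.  For two-slice graphs the temporal blacklist is
background knowledge: cross-slice edges are re-directed after conversion
and Meek rules R1–R3 are closed over to propagate orientations into
contemporaneous edges.  R4 is omitted; the propagation is sound but may
leave an occasional edge undirected that full background-knowledge
reasoning would compel.

Directional edge probabilities count an undirected CPDAG edge at full
weight toward *both* directions — so a pair's two directed probabilities
can sum above 1; this is deliberate and documented, as it makes a
reversible high-confidence edge visibly strong in both directions rather
than split 50/50.  The MAP summary graph is the modal CPDAG among the
sampled CPDAGs (ties broken by lexicographically smallest serialisation,
with a logged warning); edges above the probability threshold (default
0.1) are drawn solid when present in the MAP and dashed otherwise, with
probability doubling as a transparency weight in the DOT/GraphML exports.

## Effect estimation

The effect of A on B is the interventional relative risk under the
truncated factorisation: remove A's CPT, clamp A, marginalise exactly by
variable elimination (validated to < 1e−10 against full joint enumeration
up to 15 binary nodes; barren nodes outside the ancestral closure of the
target are pruned first).  An observational-conditioning mode is available
behind `mode="observational"` for sensitivity analysis; it differs from
the interventional answer exactly when confounding paths exist.

Three-level diagnosis factors are collapsed to binary (true = sub- or
full-threshold) for the ratio.  For a three-level *source*, `do(A = true)`
is not a single level; the package uses a soft intervention that sets A to
its model marginal restricted to the truthy (resp. falsy) levels.  Binary
sources reduce to ordinary point interventions.

Per sampled structure the CPTs are Dirichlet posterior means with
BDeu-consistent hyperparameters — strictly positive, so relative risks
are always finite without ad-hoc epsilons.  The default (plug-in means)
captures structure uncertainty only; `sample_cpts=True` draws CPTs from
their Dirichlet posterior per structure draw, propagating parameter
uncertainty as well.  Coverage checks use the sampling mode, since
plug-in HDIs collapse to near-points once the structure posterior
concentrates.  The posterior summary is the mean µ of the per-draw RRs
and the 95% highest-density interval, computed as the shortest window of
the sorted draws containing ⌈0.95·n⌉ points (no kernel smoothing;
deterministic given the draws).  If a pair is disconnected in a draw its
RR is exactly 1.  Matrix cells whose HDI contains 1 are flagged not
reportable and suppressed in exports unless `--all-cells` is passed.

## Synthetic cohorts

The default ground truth has 16 dynamic factors in five clinical domains
plus three static demographic factors; depression and anxiety are
three-level (none / subthreshold / full-threshold), the rest binary.
CPT rows are logistic in the truthy parents:
P(child truthy | parents) = σ(logit(base) + Σ β_i·[parent_i truthy]),
with per-factor base prevalences drawn once per seed from U(0.05, 0.35) —
the upper end kept below 0.5 so the planted multiplicative contrasts are
not flattened by saturation under the persistence term — persistence
weight β = 2.0 on every same-factor edge and β = 1.8 on each of the ten
planted cross-domain edges (functioning → ideation/self-harm,
ideation → attempt, the substance-use cascade, and so on).  Three-level
children split their truthy mass 60/40 between subthreshold and
full-threshold.  A test asserts that every planted cross edge has an
analytic interventional RR ≥ 1.5.

Simulation is ancestral: t = 0 from the initial network, later slices
from the transition network, static factors carried forward.  Attendance
is irregular: whole records are deleted missing-completely-at-random at
`missing_timepoint_rate` (default 0.15), so subjects can reappear after a
gap, and each subject stops attending after a Geometric(dropout_rate)
number of visits (default 0.15).  The default scale (2 663 subjects,
4 visits) mirrors a mid-sized clinical cohort; tests simulate smaller
cohorts for speed.

The compact generator `make_small_truth` (binary factors, *empty* initial
network, persistence everywhere, one planted cross edge, one exactly-null
pair) exists for effect-recovery studies: with independent t = 0 factors
and two-visit cohorts, the transition model's product-of-marginals
treatment of slice t is exactly right, so the analytic ground-truth RR
(by brute-force joint summation over the generator's CPTs) is the correct
coverage target.  For the full generator, `analytic_transition_rr` treats
slice t as independent marginals — the transition model's own assumption —
which is approximate whenever the initial network induces dependence
among the slice-t factors; passing coverage tests on the compact generator
therefore validates the effect machinery, not the product approximation.

What the generator does not emulate: calendar-time visit spacing,
informative visit processes beyond the optional MNAR mode, measurement
error in the factors, and cohort-level selection effects.  Recovery
results on synthetic cohorts speak to the correctness of the inference
machinery under the model's assumptions, not to robustness against those
real-data features.

## Problem sizes and numerical choices

The test suite and acceptance script use: 200 observations for the 3–4
node oracle comparisons (20 000 / 50 000 iterations; max-abs agreement
bound 0.03), 700 subjects × 3 visits for the six-factor factorised-oracle
comparison (4 000 iterations), 2 000 subjects × 4 visits for end-to-end
structure recovery (3 000 iterations, 2 chains — the two-slice posterior
is factorised and concentrates quickly), and 20 replicates of 2 000
two-visit subjects for HDI coverage.  Exact enumeration is guarded to 5
nodes; the factorised transition oracle replaces it at larger sizes.
Log-domain arithmetic is used throughout scoring (`gammaln`,
log-sum-exp); CPT smoothing guarantees strictly positive probabilities;
HDI ties take the first (lowest) window; the modal-CPDAG tie-break is the
lexicographically smallest serialisation.  Pipeline stage seeds derive
from the run seed as `(seed·9973 + 101·stage + 7) mod (2³¹ − 1)` so any
stage can be re-run in isolation.
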