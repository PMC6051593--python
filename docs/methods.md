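# Methods

This note documents the models, estimators and design choices behind
`statseq`, in the spirit of a model-description appendix.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Stimulus models

Streams are order-k Markov chains over four items A–D.  The target at
time *i* depends only on the context, the preceding k-tuple.  The three
standard levels are matched in context-conditional uncertainty:

* **level-0** (k = 0): occurrence probabilities 0.18, 0.72, 0.05, 0.05
  for A, B, C, D — two dominant items, two rare ones, so all levels use
  the same number of items;
* **level-1** (k = 1): the cyclic design A→{B: .8, C: .2},
  B→{C: .8, D: .2}, C→{D: .8, A: .2}, D→{A: .8, B: .2};
* **level-2** (k = 2): the allowed successor *set* is the level-1 set of
  the most recent item, while the 0.80/0.20 assignment depends on the
  item two back.

Which glyph plays which structural role is a counterbalancing
permutation applied to the canonical design (`build_model(level,
permutation=...)`).

**Why eight level-2 contexts.**  In any ergodic order-2 chain in which
every context allows exactly two successors, each recurrent item *b*
must head at least the two contexts *(b, t₁)*, *(b, t₂)* reached from
any context ending in *b*.  With all four items recurrent this forces at
least 8 reachable two-item contexts; 8 is attained by the design above,
which is therefore the smallest ergodic two-successor design that is
genuinely order-2 (rows for the two contexts sharing a final item have
equal support but opposite high/low assignment).  Alternative topologies
can be supplied as explicit transition tables to `MarkovModel`.

**Stationary context weights** solve π = πT for the induced context
chain (least-squares on the stacked linear system, after verifying
strong connectivity of the positive-transition digraph).  For all three
canonical designs the weights are uniform by symmetry; the solver does
not rely on that.  Generated sequences start from a context drawn from
π, so 672-item candidates carry no burn-in bias.

## KL-based sequence selection

Candidates (default 10,000 per level, 672 items each) are scored by

KL = Σ_c Q(c) Σ_t Q(t|c) log( Q(t|c) / P(t|c) ),

Q the ideal model (with stationary context weights Q(c)), P the
empirical conditional table of the candidate.  The 50 lowest-KL
candidates are kept, ties broken by generation index (stable sort).

Numerical conventions, used consistently in every divergence in the
package:

* **logarithms** are natural (nats); every entry point accepts
  `log_base=2` for bits;
* **smoothing**: the denominator table is add-ε smoothed and
  renormalized, row-wise: p ← (p + ε)/(1 + 4ε) with ε = 1e-6 by
  default.  A context absent from the denominator table enters as an
  all-zero row, which smooths to uniform — the "smoothed floor";
* terms with a zero numerator contribute nothing (0·log 0 = 0).

Training blocks (56 trials) contain each stream length 8–14 equally
often (8 trials per length); streams are contiguous windows cut from the
selected sequences at random offsets, so every window context is
model-reachable by construction.  Test runs hold 10 structured and 10
random (uniform i.i.d.) trials of 10 items in counterbalanced block
order.

## Performance index

Responses are scored distributionally per block: the response histogram
per context (each trial contributes its final-k context) is overlapped
with the presented-target histogram,
PI(c) = Σ_s min(P_resp(s|c), P_pres(s|c)), and contexts are averaged
with their relative frequencies among scored trials.  Session values are
means of block values (the block is the estimation unit).

Choices that the defining formulas leave open:

* **Null responses** (no keypress within the deadline) are excluded from
  both distributions and reported separately; scored + null = total.
* **Presented-target distribution**: estimated from *all* within-stream
  context→next-item transitions pooled over the block's streams
  (~590 transitions per 56-trial block), not from a per-trial "true next
  symbol", which is undefined for a stochastic source.  `presented=
  'model'` substitutes the exact model rows instead.
* **Context mismatches**: a context with a response row but no presented
  row (or vice versa) is dropped and the remaining weights renormalized;
  the count of dropped contexts is reported.

**Random-guess baseline.**  Analytically, a uniform responder attains
PI_rand = Σ_c π(c) Σ_t min(0.25, P(t|c)): 0.53 for level-0 and 0.45 for
any level whose rows are 0.80/0.20, independent of the context count.
The simulated mode estimates the same quantity at finite block size: the
*exact* uniform response distribution is scored against each simulated
block's empirical presented table and averaged over blocks.  This
estimator converges to the analytic value for large blocks and sits
~0.005 below it at 56-trial blocks.  A stricter variant
(`sample_responses=True`) also samples the uniform responses and pushes
them through the per-context estimator; with only ~7–14 responses per
context per block its min-overlap is biased markedly downward (to ≈0.40
at 56 trials), which is why the distributional definition is the
default.

The training criterion (PI > 0.70, i.e. at least 0.25 above the
context-based chance level) is exposed as a predicate
(`meets_training_criterion`); multi-day scheduling is out of scope.

## Strategy analysis

Two baselines derive from the generating model M: *matching* (the model
rows) and *maximization* (all mass on the arg-max target per context;
ties split equally — impossible in the 0.80/0.20 designs but defined for
configurable ones).  For a response table R,

KL(M ‖ R) = Σ_c M(c) Σ_t M(t|c) log( M(t|c) / R(t|c) ),

with M(c) the model's stationary context weights and R smoothed as
above.  The model sits in the numerator; a `direction` flag offers the
reversed divergence for sensitivity analysis.

ΔKL = KL(M_match ‖ R) − KL(M_max ‖ R) is computed in consecutive
non-overlapping windows (default 56 trials, the PI estimation unit;
configurable) to give the strategy curve.  The **strategy index** is the
integral curve difference (ICD): the trapezoidal integral of
ΔKL − ΔKL_matcher over the normalized window axis, where ΔKL_matcher is
the curve of an exact matcher (R = M_match, passed through the identical
smoothing path so the zero point is exact to machine precision).  A
single-window curve degenerates to the plain difference.  The
orientation is fixed so that 0 = matching and positive values lean
toward maximization; the index for context-based statistics pools
(averages) the level-1 and level-2 indices.

Sampling note: with ~14 responses per context per 56-trial window, a
window in which the low-probability target drew no responses inflates
KL(M_match ‖ R) through the smoothed floor.  Finite-sample strategy
indices of even a perfect matcher are therefore slightly positive; the
zero point is exact only for distributional (noise-free) response
profiles.  This affects all ε choices; ΔKL varies by < 1% across
ε ∈ [1e-8, 1e-5] for full-support response tables.

## Synthetic observers

No real logs ship with the package; agents generate them with the
structure the analysis assumes.  An agent keeps per-(context, target)
evidence counts: each trial, counts are multiplied by a forgetting
factor (`decay`, default 1 = none), then incremented for every
transition in the stream just watched (observers are assumed to learn
from the stream itself, not only from prediction outcomes — a generator
choice, not a claim about participants).  The response to the trial's
final context uses the posterior-mean row given a uniform Dirichlet
prior (`prior_count`, default 1): with probability `lapse` a uniform
guess; otherwise with probability `lambda_max` the arg-max of the row
(maximization), else a sample from it (matching).  λ = 0 and λ = 1 are
the exact matcher and maximizer in the post-learning limit.

Cohorts follow the study curriculum: three phases (level-0, level-1,
then variable order alternating level-1/level-2 blocks), by default four
280-trial sessions per phase — 1120 trials, inside the 840–1400 range a
3–5-session regime implies — for 21 observers whose λ values span
[0, 1] evenly.  Per-agent and per-stage seeds derive from one master
seed via `numpy.random.SeedSequence` splitting (`agent_seed`), so
cohorts are reproducible piecewise.

The **recovery experiment** closes the loop: for each λ on a grid,
replicate agents are trained (default 1120 trials) and pushed through
the strategy pipeline; reported are mean/SD of the recovered index per λ
and the Spearman correlation between true λ and index.  Cohort
simulations reuse one selected sequence set per level built from a
200-candidate pool — selection quality only has to be representative
there, not at the 10,000-candidate presentation standard, which keeps
the end-to-end experiments fast; the full-scale selection path is
exercised separately.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the estimators
assume: Markov streams with the designed conditional tables, blockwise
trial composition, null responses (via lapses only if configured),
matching↔maximization variability and incremental learning.  It does
not emulate reaction times, attention drift, session-to-session
consolidation, stimulus-level confusability, or learning confined to
prediction outcomes.  Passing tests therefore validate the
computational chain — design, scoring, strategy indexing, recovery —
not any claim about human observers.

## Known limitations

* The level-2 topology is one (minimal) member of the family consistent
  with two 0.80/0.20 successors per context; other ergodic topologies
  must be supplied explicitly.
* Strategy indices from sampled responses carry the positive
  finite-sample bias described above; comparisons should hold window
  size and trial counts fixed, as the recovery experiment does.
* Group-level inference (ANOVAs, Bayes factors, correlations with
  neural measures) is out of scope; the package stops at per-observer
  indices.
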