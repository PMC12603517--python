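# Methods

## The prediction problem

Each observation is a *study arm* of a randomised smoking-cessation trial:
a binary/fuzzy vector of intervention-content, delivery, population,
setting and methodology features, with an outcome equal to the percentage
of participants abstinent at follow-up.  The task is regression: predict
the outcome percentage of a *novel* feature combination, with explanations
a practitioner can read.

## Model

The model is a set of **soft conjunction rules**.  Rule *r* has a
selection weight `s_{r,l} ∈ [0,1]` for every literal *l* (a feature
asserted or negated — "nurse", "not nurse", "mean age: older adult") and a
signed rule weight `w_r` in percentage points.  On an arm with literal
memberships `x ∈ [0,1]^L` the rule's fit is the weighted product t-norm

    fit_r(x) = Π_l (1 − s_{r,l}(1 − x_l)),

chosen because it exactly interpolates a crisp conjunction (`s = 1`
demands the literal, `s = 0` ignores it) and is smooth in both arguments.
The prediction is linear in the fits:

    ŷ(x) = intercept + Σ_r w_r · fit_r(x).

Raw predictions are unclipped; mapping into [0, 100] happens only at the
presentation layer so training gradients are unaffected.

Selections are stored as logits (`s = σ(θ)`), so unconstrained gradient
steps can never leave [0, 1].

### Penalties

Interpretability is enforced by three penalties added to the mean squared
error:

* **length** `λ_len · Σ s` — prefer short rules;
* **crispness** `λ_crisp · Σ s(1 − s)` — drive selections to 0 or 1 so
  rules read as boolean conjunctions;
* **semantic** `λ_sem · Σ_r Σ_{(a,b) penalised} s_{r,a} s_{r,b}` — forbid
  pairs that the ontology marks *contradictory* (disjoint literals,
  complements, inherited through the hierarchy) or *redundant* (one
  literal entails the other).

Defaults `λ_len = 1e-3`, `λ_crisp = 1e-2`, `λ_sem = 1e-1` are **relative**
coefficients: inside the loss each is multiplied by the training-outcome
variance (the grand-mean baseline MSE, floored at 1).  This normalisation
keeps the penalty-to-error balance independent of the outcome units; the
ordering — semantic violations dominate, crispness next, sparsity
gentlest — is the design intent.

### Ontology semantics

The ontology supplies subsumption (child → parent, acyclic) and pairwise
disjointness between literals.  Literal entailment is closed under both:

* asserted(f) ⟹ asserted(ancestor); negated(f) ⟹ negated(descendant);
* a literal entails the complement of anything it is disjoint with
  (bupropion, disjoint with "not pill", entails pill).

The disjointness-derived clause goes beyond plain class-hierarchy
reasoning and matters in practice: without it, a conjunction such as
`{A, B, ¬C}` with `A disjointWith C` is observationally identical to
`{A, B}` in any consistent dataset, so training happily keeps the longer
variant and the rule sets never converge.  Simplification
(`simplify_conjunction`) drops every literal entailed by another, keeping
the lexicographically smaller token when two literals entail each other.
Data completion propagates memberships up the hierarchy by `max`, so
graded memberships remain valid; it is idempotent.

## Featurization

Five binarization methods turn numeric features into literal columns, all
with the logistic membership `m(value < t) = 1/(1 + exp((value − t)/τ))`
and temperature `τ` defaulting to 10% of the bin width (τ → 0 gives crisp
thresholds):

1. **semantic** categories (mean age → child / young adult / older adult /
   elderly with breakpoints 18/40/65 years — the category names are
   domain-standard, the numeric boundaries are this package's defaults and
   configurable);
2. **fixed-width** `value < t` thresholds (cigarettes/day in steps of 5),
   which create an ordering: memberships are non-decreasing in t;
3. **quantile** thresholds (linear interpolation of order statistics,
   recorded in config since several quantile conventions exist);
4. **exact-value** crisp flags (100% female), relative tolerance 1e-9;
5. **cluster** ranges from exhaustive 1-D segmentation minimising
   within-segment variance.  The segment count is chosen by a *gap*
   criterion — boundaries must sit at gaps wider than 3× the median
   spacing of the sorted sample — rather than an SSE elbow, because any
   split of any sample cuts SSE by a large fraction, which would split
   tight unimodal data that has no meaningful ranges.

Missing numeric values get membership 0 in every range literal plus a
crisp `<feature> (reported)` flag, so "unreported" is itself learnable.
Presence features receive a negated complement column (`not f = 1 − f`);
range and flag literals do not.  Features present in fewer than 30 arms
are pruned, with pruned children folded into their ontology parents by
`max` so the information survives in aggregate.  Row exclusions
(pregnancy or relapse-prevention trials, data reuse, unreported outcomes)
are declarative study/arm-id lists, not content inference.

## Training

Full-batch gradient descent with analytic gradients and Adam-style
per-parameter step sizes (lr default 1e-2; the gradient of the product
t-norm uses forward/backward cumulative products, which handles zero
factors exactly).  Initialisation: one crisp singleton rule per
non-negated literal, its weight taken from an ordinary least-squares fit
(ridge fallback when singular) and the OLS intercept; the remaining rules
start with selection logits ~ N(−2.5, 1) (selections near 0, so they act
as tiny intercept perturbations) and weights ~ N(0, 0.01).  The table is
split 90/10 at study level for validation; training runs at least
`min_epochs` (default 400) and stops once the validation loss (MSE +
penalties) has not improved for `patience` epochs (default 20;
configurable down to 1 for stopping at the first non-improving epoch,
which is noise-fragile).  The parameters of the best validation epoch are
returned, with a per-epoch loss log.

**Crispification** thresholds selections at 0.5, simplifies each
conjunction under the ontology, drops contradictory rules (warned),
folds empty conjunctions into the intercept, merges duplicate left-hand
sides by weight summation, and finally drops rules whose merged |weight|
is below 0.5 percentage points — a reporting floor far below any
practically relevant effect, which removes the cloud of noise-level
singletons the OLS initialisation seeds.

## Consensus

Training is stochastic and the data under-constrain the rules, so R
independent runs (seeds seed+0 … seed+R−1) are aggregated.  For each
distinct crisp conjunction, support = number of models containing it; the
null expectation assumes rules draw literals at random, giving containment
probability `P = C(n−k, ⌊m⌋−k)/C(n, ⌊m⌋)` with k the conjunction length,
m the mean rule length over all models (floored for the combinatorial
formula) and n the schema size, scaled by R and the mean rules-per-model
ρ.  A conjunction is kept when support > 1.3 × expected **and** support
≥ 2: for k > ⌊m⌋ the expectation is ~0, so without the support floor any
single stochastic appearance would pass, which is the opposite of a
consensus.  Singleton conjunctions with any support are always eligible
(the per-feature baseline rules of the deployed model); this is
toggleable.  Weights start at the cross-model mean and are then
fine-tuned by closed-form least squares on the crisp fit matrix with the
conjunctions frozen (minimum-norm solution when rank-deficient, which
happens whenever a rule fires on every arm and aliases the intercept —
predictions, not the intercept split, are the contract).

Between-model agreement uses the Jaccard index of left-hand-side sets,
and per-conjunction weight statistics (mean and *population* standard
deviation; single-model conjunctions get sd 0 and a low-support flag, and
a large sd relative to |mean| signals sign disagreement).

## Evaluation

Five-fold cross-validation at **study** level (arms of one study never
straddle folds, so data reuse across arms cannot leak).  The metric is
mean absolute error over arms, each arm scored exactly once in its test
fold.  Comparators:

* grand mean of the training outcomes;
* mixed-effects linear regression (random study intercept, fixed effects
  for all literals; unseen studies predicted at population level; OLS
  fallback on convergence failure);
* random forest, 50 trees, depth ≤ 3, ≤ 5 leaves;
* feed-forward network with hidden widths (2d, d, d/2) for schema size d,
  100 Adam epochs (the outcome is standardised internally for stable
  optimisation).

Method comparison: one-tailed Mann-Whitney U on the absolute-error
vectors (rule-model errors stochastically smaller), with the "likelihood
of superior accuracy" operationalised as 1 − p.  For groups of ≤ 8 the p
is computed by exhaustive enumeration with a mid-p convention at ties
(P[U < u] + ½P[U = u]), which keeps the swap symmetry p ↦ 1 − p exact and
yields exactly ½ for identical samples; larger groups use the
tie-corrected normal approximation, where the continuity correction makes
the swap symmetry approximate.

## Synthetic data

The generator plants known structure: a random forest-shaped hierarchy
with disjoint sibling pairs, per-feature prevalences, independent feature
draws repaired for disjointness and completed up the hierarchy, and
outcomes = intercept + Σ planted-rule effects + N(0, σ) clipped to
[0, 100] (clip events recorded in the truth record).  Gaussian noise
stands in for the sampling error of trial outcomes — the irreducible
floor, E|N(0,σ)| = 0.8σ for MAE.  What it deliberately does not emulate:
annotation errors, missing-report mechanisms, correlated feature
co-occurrence beyond the ontology axioms, or heavy-tailed outcome noise —
so passing tests demonstrate correctness of the machinery and
recoverability under clean conditions, not performance on real corpora.

The `smoking-like` preset mirrors the released corpus's shape: ~400
studies of 1–4 arms (≈1000 arms), 50 presence features (≈100 literals
after complement expansion), intercept 9, mostly moderate rule weights so
outcome mass concentrates below 30%, noise sd 6 percentage points
(roughly the binomial sampling error of a small trial arm at low
abstinence rates).

### Benchmark problem sizes

The planted-rule recovery benchmark uses 2000 arms over 700 studies, 20
features (41 literals), three planted rules (a singleton, a pair, a pair
with a negated literal), noise sd 2, and an 80:20 study-level holdout.
Training there uses 40 rules and 250–400 epochs at learning rate 0.03 —
enough rules for singleton coverage plus interaction head-room, with the
epoch budget sized to the problem.  The acceptance script scales the
corpus-shaped runs to 150 studies with 120–180 epochs and a 10-run
consensus; all sizes are recorded in the script and chosen so a complete
run stays desk-scale.

## Known limitations

* The fuzzy conjunction and linear combination are one defensible
  instantiation of a "weights on features and rules" scheme; other
  t-norms would train differently.
* The hypergeometric null treats rules as uniform random draws of
  literals; real trained rules are far from uniform, so the 1.3×
  threshold is a heuristic bar, not a calibrated test.
* Mixed-effects and network baselines use standard library
  implementations with fixed architectures; no hyperparameter search is
  performed anywhere, by design.
* Scenario predictions inherit every bias of the training corpus;
  control/intervention asymmetry in the data (intervention arms reported
  more completely) shows up as a gap between the two predictions even
  with no intervention features selected.
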