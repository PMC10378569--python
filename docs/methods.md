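# Methods

## Estimators

All information quantities are plug-in estimates over empirical
contingency tables of integer-coded variables, with `0·log 0 := 0` and no
bias correction (no Miller–Madow or shrinkage): the selection criteria are
defined on raw plug-in values, and every comparison between candidates at
a fixed step shares the same sample, so the dominant bias terms cancel in
the ranking.  Internally MI and CMI are computed through entropy
identities (I(X;Y) = H(X)+H(Y)−H(X,Y); I(X;Y|Z) = H(X,Z)+H(Y,Z)−H(X,Y,Z)−H(Z)),
which are algebraically identical to the cell-wise sums; the test suite
cross-checks them against an independent cell-by-cell enumerator and
against scikit-learn's `mutual_info_score` to 1e−12.  MI and CMI are
clamped at 0 to absorb float cancellation; three-way interaction
information is left signed.  The log base defaults to 2 (bits).  The base
divides every quantity uniformly and ω is a ratio, so the greedy argmax
order is base-invariant; the parameter exists for presentation only.

## The weighted criterion

The candidate score is J(f_k) = Σ_{f_j∈S} ω(f_j,f_k)·I(f_k;C|f_j) with
ω = 1 + 2(I(f_j;C|f_k) − I(f_j;C)) / (H(f_j)+H(C)).  Both numerator terms
are bounded by min(H(f_j), H(C)) ≤ (H(f_j)+H(C))/2, so ω ∈ [0, 2]; the
closed upper bound is attained exactly by a noise-free XOR pair (where
I(f_j;C)=0 and I(f_j;C|f_k)=H(f_j)=H(C)=1 bit), and the implementation
treats 2 as admissible.  When H(f_j)+H(C)=0 (both variables constant) all
information terms vanish and ω is defined as the neutral value 1 rather
than 0/0.

The greedy loop scores all remaining candidates each step and appends the
single argmax; ties break to the lowest original column index at every
step, making runs fully deterministic.  Quantities are memoized per run
(pairwise MI, per-pair CMI, entropies), leaving one O(n) pass per new
(candidate, selected) pair — O(K·m·n) overall for K of m features on n
samples.

Baselines share the loop and differ only in the score: MIM, MIFS
(β, default 1.0 — the historical default, exposed as a parameter), mRMR,
CIFE, CONDRED (relevance plus conditional redundancy,
I(f_k;C) + Σ I(f_k;f_j|C)), and DISR (Σ I((f_k,f_j);C)/H(f_k,f_j,C), the
paired-code joint variable over the joint entropy of all three).  CONDRED
and DISR follow their canonical forms from the linear-criterion
literature.  At step one every criterion reduces to argmax I(f;C) (empty
sums), which the greedy loop applies uniformly.

## Preprocessing and discretization

Features missing in strictly more than a configurable fraction of samples
(default 0.5) are dropped; surviving missing cells are replaced by the
per-feature mean of observed values.  Both operations are idempotent and
the dropped-name report is returned to the caller.

Equal-width binning fits per-feature edges over the observed min..max:
5 bins by default for generic continuous tables, 3 for expression data
(low / normal / high).  The maximum value is inclusive in the last bin,
all other bins are half-open; a constant feature yields a single
degenerate bin.  When a model fitted on a training split is applied to
held-out data, out-of-range values clip to the extreme bins — on the
fitting table itself clipping never occurs.  Class labels are coded by
first appearance, so downstream tie-breaks are reproducible.  The median
feature arity feeds the difficulty ratio N/(m·c), rounded half away from
zero.

## Evaluation protocol

`evaluate` runs stratified k-fold cross-validation (default 10 folds,
K = 15 features, KNN with 5 neighbors; naive Bayes on discrete codes and a
default-kernel SVM are the other reference adapters).  Per fold the
training portion is discretized, the criterion ranks training data only,
and the classifier trains on the top-K columns; the classifier adapter
declares whether it consumes discrete codes or original values.  Two
policy switches reflect a genuine protocol ambiguity: `fit_bins_on` and
`select_on` may each run on `"train"` (leakage-safe default) or `"full"`
(replicating protocols that discretize/rank the whole dataset up front).
A `repeats` parameter covers the repeated-CV reading of "10-fold CV fed 10
times"; the default is a single 10-fold pass.  `accuracy_curve` ranks each
fold once to depth k_max and truncates per k, so the whole 1..k_max sweep
shares one partition.

Method pairs are compared by a **paired** two-sided t-test on matched fold
accuracies (the partitions are identical, so pairing is the correct and
more powerful choice; an unpaired variant is selectable): Win/Loss
requires p < α (default 0.1) and the corresponding mean ordering, anything
else is a Tie.  Identical accuracy vectors have an undefined t statistic
and are declared Tie directly; a constant nonzero difference vector is
treated as p = 0 (infinitely strong paired evidence).

## Synthetic generator

`generate` plants known structure on a uniform categorical class:
*relevant* features are class copies corrupted by symmetric flips
(default rate 0.1 — strong but imperfect markers, matching what
informative proteins look like after coarse discretization); *redundant*
features are re-corrupted duplicates of relevant ones (default 0.1);
*XOR parents* come in pairs whose XOR equals a binary class with per-parent
flip 0.05 (each parent is exactly independent of the class marginally —
pure interaction); *noise* features are independent uniform.  A bounded
jitter (default amplitude 0.4, strictly below half the unit code spacing)
can turn codes into continuous values such that equal-width binning with
`bins = arity` recovers the codes exactly, letting discretization be
tested end to end.  XOR pairs are restricted to binary classes; multiclass
interaction constructions are out of scope because their ground truth is
ambiguous.

The generator emulates the *statistical* structure of omics tables —
marginal relevance, duplication, synergy, noise — not their biology: no
batch effects, no correlated noise blocks, no heavy-tailed intensities,
no class imbalance.  Passing tests on it demonstrate that the criteria
rank planted structure as designed, not that any particular biomarker
panel is recoverable from real data.

### A note on cold-start interaction recovery

Once one XOR parent is in the selected set, the weighted criterion scores
its partner near the theoretical maximum (ω ≈ 2, CMI ≈ 1 bit) and far
above any noise feature, while mRMR assigns the partner a non-positive
score — this is the operational content of the interaction claim, and the
suite verifies it.  Recovery *from a cold start* is a different matter:
each parent alone is independent of the class given any set that excludes
its partner, so step 1 (argmax marginal MI, which every greedy forward
criterion here uses) can only seed a parent by chance.  With one planted
pair among 20 noise features that chance is about 2/22 per early step, and
the measured top-3 recovery rate (~0.15 over 200 seeds) matches that
arithmetic.  This is a structural property of single-candidate greedy
forward selection, not an estimator defect.

## Problem sizes

Test and acceptance runs use deliberately small instances chosen to make
the checked properties sharp rather than to stress throughput: the 8-row
worked fixture (exactly solvable by hand), 10⁴ random triples of 20–200
samples for the ω bound, 100 random tables of ≤8 features and ≤60 samples
for brute-force oracle equivalence, and 200 seeds of the n = 1000 XOR
benchmark for the recovery rates.

## Known limitations

- Plug-in estimates are biased upward on small strata; criteria that
  condition (WBFS, CIFE, CONDRED) inherit more of this bias than MIM.
- No continuous (non-discretized) estimators; no wrapper or embedded
  selection; K is user-chosen, not optimized.
- Equal-width binning is sensitive to outliers, which compress the
  occupied range into few bins; no equal-frequency alternative is
  provided.
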