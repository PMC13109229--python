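# Methods

This note documents the statistical model behind `microsyntax`, the
estimator conventions, the synthetic-data generators used for validation,
and the design choices taken where several defensible options existed.

## Model

A label sequence X_t over the alphabet {0, …, K−1} is treated as a
stationary stochastic process.  Its first-order structure is summarized by
the state distribution p, the conditional transition matrix
T_ij = Pr(X_{t+1}=j | X_t=i) and the joint matrix
P_ij = Pr(X_t=i, X_{t+1}=j) = p_i T_ij.  *Higher-order syntax* is any
property of the conditional law Pr(X_{t+1} | last k labels) that is not
predicted by (p, T).  Two families of scalar coefficients probe it:

* **ER(k)** = H(X_{t+1} | X_t^{(k)}), the conditional entropy of the next
  label given the length-k history ("word"), in bits;
* **SE(k)** = −log₂ Pr(X_{t+1}=X_{s+1} | X_t^{(k)}=X_s^{(k)}), the
  negative log conditional probability that a recurrence of a k-word at
  two times extends one step further.

For a first-order Markov chain, ER(k) = −E(log₂ T) for every k ≥ 1, and,
under the additional assumption that collisions at different recurrence
lags are independent, SE(k) ≈ −log₂ E(T) (expectations with respect to
P).  Concavity of the logarithm gives ER ≥ SE.  For an i.i.d. chain the
levels reduce to the Shannon entropy H(p) and the Rényi-2 (collision)
entropy −log₂ Σ p_i².  The independence approximation behind the SE level
has no analytic error bound; its adequacy is checked numerically against
surrogate ensembles (at study scale the discrepancy is well inside the
Monte-Carlo spread; see the flat-curve acceptance tests).

Two sequence representations are analyzed.  *Continuous* sequences carry
one label per sample and retain state durations; *jump* sequences collapse
runs and retain only the order of state changes.  A jump sequence cannot
have a zero-order model (adjacent labels must differ), which is why the
two normalized measures differ (below).  When converting continuous to
jump, the first and last run are removed by default (they are truncated
by the recording window and their durations are uninterpretable); the
flag `drop_edge_segments=False` disables this.

## Estimators

**Transition model.** p is defined as the row marginal of the empirical
pair-count matrix, not the label frequency over all n samples.  The two
differ by a single count (the last label), but only the row-marginal
choice makes P = diag(p) T hold exactly on finite data, which the
closed-form baselines require.  Rows of T for states never seen as a pair
origin are stored as zeros and flagged; with the 0·log 0 = 0 convention
they contribute nothing to any entropy.

**ER(k)** is the plug-in conditional entropy, computed as a difference of
block entropies over overlapping windows (the k-word histogram is taken
over the prefix positions of the (k+1)-windows, so the difference is
algebraically identical to the conditional form).  k = 0 returns the
Shannon entropy of the label histogram.  Within a `syntax_profile`, the
whole er vector is derived from a *single* empirical distribution over
(kmax+1)-windows (each ER(k) conditions the final symbol of those windows
on its k predecessors).  This makes the chain-rule monotonicity
ER(k+1) ≤ ER(k) an exact theorem of the estimator instead of an
asymptotic property: per-k estimates from staggered window populations
can violate it by O(1/n) on short inputs, which would turn a structural
invariant into a numerical accident.  The standalone `entropy_rate(seq, k)`
keeps the conventional per-k definition; the two agree to O(kmax/n).

**SE(k)** uses pair counting over all unordered position pairs t < s whose
k-word and successor both exist: B = matching k-word pairs, A = the subset
whose successors also match, SE = −log₂(A/B).  Both counts reduce to sums
of C(c, 2) over word histograms, so the estimator runs in O(n) per k while
remaining *exactly* equal to the O(n²) pair enumeration (this equality is
enforced in tests over random sequences).  Restricting template positions
to those with a successor keeps A and B on the same pair population;
counting B over all positions would bias A/B.  Conventions that average
template-wise rather than over pairs exist in the continuous-signal
literature; pair counting was chosen because it is the direct empirical
analogue of the collision probability, and the brute-force oracle pins the
choice down.  Two degenerate outcomes are kept distinct: A = 0 with B > 0
yields +∞ (recurrences never extend), while B = 0 (no k-word recurs) is an
undefined result, raised as an error by `sample_entropy` and stored as a
marked NaN slot by `syntax_profile`.  Downstream statistics drop marked
slots pairwise with a warning.

**SE(0)** is not a Richman–Moorman length-0 template count (the syntax
concept here starts at word length 1); profile slot 0 stores the Rényi-2
entropy of the label frequencies, the closed-form limit of single-label
collisions under temporal independence, and is labelled as such.

**Bias.** Plug-in entropy estimates are biased low once the number of
possible words K^(k+1) is not small against n.  `syntax_profile` emits a
reliability warning when n < 10·K^(k+1).  The bias is real and visible:
at K = 4, k = 6, jump sequences of ~8,500 labels underestimate the
first-order ER level by ~0.15 bits, and lengthening the surrogates to 10⁵
samples removes ≥ 90 % of the gap (reproduced in the acceptance suite).
Sample-size planning should use surrogates of matched length so that
estimator bias cancels in the comparison.

## Surrogates

Zero-order surrogates share p (equivalently T_ij = p_j); first-order
surrogates share p and T.  Sampling is inverse-CDF from a seeded NumPy
`Generator`: initial state from p (exact for a stationary chain; the
choice of initial law is otherwise immaterial at the lengths used),
subsequent states from the T row of the current state.  Identical (spec,
seed) reproduce the identical sequence; the contract is reproducibility
on a given NumPy stack, not cross-platform bit equality.  Surrogates have
the source's length unless overridden (the long-surrogate device above).
Jump-sequence surrogates are sampled directly from the jump sequence's
own zero-diagonal T — surrogating the continuous sequence and collapsing
would not fix the jump transition matrix.  Jump sequences admit no
zero-order surrogate (it would produce adjacent duplicates) and the
package refuses to build one.  Shuffle surrogates are deliberately not
provided: shuffling preserves p but alters T, confounding first- and
higher-order effects.  No conditioning on strictly positive transition
counts is applied to accepted surrogates.

## Normalized syntax

With h an empirical ER or SE coefficient and h0/h1 the closed-form
zero-/first-order levels computed from the sequence's own fitted (p, T):

* σ_C(h) = log(h/h0)/log(h1/h0) on (0, h0], for continuous sequences —
  a ratio of logs, hence log-base invariant; σ_C(h0) = 0, σ_C(h1) = 1;
* σ_J(h) = 1 + log₂(h1/h) on (0, h1], for jump sequences; σ_J(h1) = 1.
  σ_J is base-dependent; base 2 is fixed so that one unit above 1 equals
  one extra bit of predictability relative to the first-order level.

Both are strictly decreasing in h, i.e. increasing with syntactic
structure.  Baselines are theoretical rather than surrogate-estimated by
default (they are exact functionals of the fitted model and add no
Monte-Carlo noise); surrogate-derived baselines can be obtained by
profiling surrogate sequences when a bias-matched comparison is wanted.
The scalar functions enforce the stated domains; inside
`normalized_profile` the evaluation is permissive, because sampling noise
routinely places an empirical h a fraction of a percent above its
theoretical anchor — the formulas then return values marginally below 0
or 1, which is the honest reading.  h = 0 (a perfectly predictable slot)
maps to +∞ with a warning; a fully deterministic *baseline* (h1 = 0) is a
degenerate-anchor error, since no normalization exists.  σ_C additionally
requires h1 < h0, i.e. genuine first-order structure; for sequences whose
fitted T is indistinguishable from i.i.d. the continuous normalization is
intrinsically ill-posed and the error is propagated rather than patched.

## Group statistics

Within-group comparisons (each subject's sequence vs its matched
surrogate, one surrogate per subject by default, optionally the mean of
several) use the Wilcoxon signed-rank test; between-group comparisons
use the Mann-Whitney U-test (unequal group sizes allowed).  Tests are
two-sided; effects in both directions occur (ER below and SE above the
first-order level on the same data are typical).  Raw p-values are
BH-FDR-corrected *within* one family — the tested word lengths k = 1..6
for a fixed (metric, kind, comparison) triple — and never pooled across
metrics or kinds.  Significance is p_FDR < α = 0.05.  All-zero-difference
or too-small slots are marked degenerate, excluded from the FDR family
and reported with a warning.  Wilcoxon uses zero-difference exclusion and
SciPy's exact small-sample distribution where available.  The type-I
error of the full pipeline is verified by simulation: with both columns
drawn from the same first-order generator, per-k rejection rates over 500
replicates fall within three Monte-Carlo standard errors of α.

## Synthetic data

The generators define the study conditions for every quantitative test:

* K = 4 throughout; continuous sequences of 10⁵ samples at 500 Hz
  (200 s); jump sequences of ~8.5·10³ labels; 24 subjects per synthetic
  cohort; word lengths k = 1..6; α = 0.05.
* `generate_microstate_like` draws a zero-diagonal jump chain and
  geometric dwell times.  Geometric dwell is the maximum-entropy
  run-length law consistent with a first-order continuous chain — the
  composite chain equals (1−1/d)·I + (1/d)·T_jump.  The default mean
  dwell of 12 samples (24 ms) reproduces the ~11.7 : 1 continuous-to-jump
  length ratio of resting-state recordings.  A uniform dwell option
  injects non-Markovianity into the continuous sequence while leaving
  the jump skeleton first-order (a targeted negative control).
* `generate_chain` samples chains of order 0, 1 or 2 (order 2 from a
  K²×K conditional table).  `second_order_jump_table` is the positive
  control: the preferred successor is decided by the *second-last* label
  (probability 0.7), so the first-order collapse is substantially less
  predictable and σ_J rises well above 1 from k = 2 on.
* `generate_quasiperiodic` repeats a jump-valid cycle with substitution
  noise (noiseless case: cycle ACDB of length 9 gives ACDBACDBA).

What passing tests on these fixtures shows: the estimators, baselines,
surrogate machinery and statistics behave correctly on sequences whose
generating law is known exactly.  What they cannot show: robustness to
the non-stationarities of real EEG (drowsiness, drifting vigilance),
smoothing artefacts of microstate back-fitting, or topographic
mislabelling — real sequences are consumed as ordinary label files, and
those effects live upstream of this package.

## Numerical choices

* All logarithms base 2; all entropies in bits; 0·log 0 = 0.
* Word histograms use base-K integer coding of sliding windows (exact for
  K^k < 2⁶², i.e. any realistic k), falling back to row-wise uniquing.
* Monte-Carlo experiment sizes (24 surrogates per ensemble, 500
  calibration replicates at 800 samples, 10⁴ random models for the
  Jensen sweep) are chosen so each acceptance check resolves its
  tolerance comfortably; calibration under the null is
  length-invariant because both test columns come from the same
  generator, so short replicates suffice.
* Manifest truncation defaults to the cohort minimum length, mirroring
  the uniform-length policy used for real recordings.
* Ties in Mann-Whitney are handled by SciPy's default tie correction;
  Wilcoxon drops zero differences ("wilcox" rule).

## Known limitations

* The first-order SE level is an approximation; for chains whose
  autocorrelation time approaches the sequence length the independence
  assumption degrades, and only surrogate comparison (not the closed
  form) is reliable.
* Plug-in ER remains biased low for k near log_K(n); the warning
  threshold n ≥ 10·K^(k+1) is a heuristic, not a guarantee.
* SE on very long, non-stationary recordings mixes recurrence with slow
  drift; the package computes the statistic but cannot separate those
  sources.
* p is the empirical pair-origin marginal, not the stationary
  distribution of the fitted T; for strongly non-stationary inputs the
  closed-form baselines inherit that choice (documented above) and the
  two can differ.
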