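# Methods

## Model

A forced-choice paired comparison between items *i* and *j* is modeled as
Bernoulli with

    P(i preferred over j) = π_i / (π_i + π_j) = expit(β_i − β_j),

β = log π. Judgments are treated as independent — no subject-level random
effects — matching how such small sensory panels are conventionally
analyzed; with at most 7 judgments per subject and randomized pair
assignment, subject effects mostly cancel in contrasts. Ties are not
representable (the design forces a choice).

Worth has no natural zero, so the model is identified by pinning one
reference item at β = 0; the default reference is the first item in the
item set. All substantive output (contrasts, p-values, quasi-variances,
ranking, the global test) is invariant to that choice, which the test
suite verifies by refitting under all references.

When judgment-level data with presentation order are available, the linear
predictor gains an order term: logit p = β_first − β_second + δ, with
positive δ an advantage of the first-tasted sample. Aggregated count
matrices discard the per-order outcome split, so fits from counts alone
omit δ. For the bundled study this omission is benign — its order effect
was small and non-significant and its design near-balanced — and the
reproduction tests carry tolerances (±0.15 on β, ±0.05 on quasi-SE and
pairwise p) sized for that parametrization difference.

## Fitting and inference

Two independent maximizers of the same likelihood are implemented:

- **MM**: the classical minorize–maximize update
  π_i ← w_i / Σ_j n_ij/(π_i+π_j), renormalized to the reference. Because
  MM converges linearly, stopping on log-likelihood change alone can leave
  coefficients ~1e−4 from the optimum; the iteration therefore also
  requires the parameter vector to be stationary (max |Δ log π| ≤ 1e−9).
- **Newton–Raphson** on the free coefficients, with step-halving on any
  non-increase of the log-likelihood.

Both stop on relative log-likelihood change < 1e−10, cap at 1,000
iterations (raising a convergence error with the trace), and agree to
≤1e−6 per coefficient on random connected instances. The covariance is the
inverse observed information (equal to the expected information here);
per-coefficient and contrast tests are two-sided Wald against the standard
normal, with no multiplicity adjustment (none is standard for this design;
α = 0.05). Whether the original per-coefficient p-values were Wald or LRT
is ambiguous; Wald is assumed, the convention of the usual software for
this model.

A finite MLE exists iff the win digraph (edge i→j when i ever beat j) is
strongly connected. Separation — an item with no wins or no losses, or a
disconnected digraph — is detected up front via the connectivity check
plus a runtime guard (|β| > 15) and raises an error naming the offending
items; an optional pseudo-count regularization (ε wins added both ways per
compared pair, default off) is provided for exploratory use only and never
applied silently.

The global test compares the fitted model to the equal-worth null, under
which every judgment is a fair coin and the null log-likelihood is
N·log ½; the statistic 2(ℓ̂ − ℓ₀) is referred to χ² with m−1 degrees of
freedom.

## Quasi-variances

Reference-based reporting gives the reference a zero standard error and
makes other items' SEs reference-dependent. Quasi-variances q_i are
computed by unconstrained minimization over log q (guaranteeing q > 0) of
the log-scale least-squares criterion
Σ_{i<j} [log(q_i+q_j) − log Var(β̂_i−β̂_j)]², with analytic gradient,
BFGS, gradient tolerance 1e−10. The log scale makes errors relative and is
the standard variant of the method; the worst relative error
max |(q_i+q_j)/Var(β̂_i−β̂_j) − 1| is always reported alongside the result.
On the bundled study it is ≈0.32, driven by the strongly correlated
A4/A5 contrast — the per-item error bars are a good summary for most
pairs, and the diagnostic says exactly how good.

## Design generator and simulator

The generator mirrors the study protocol: per subject, `max_per_subject`
unordered combinations sampled without replacement (a swapped-order repeat
counts as the same combination), presentation order by fair coin flip, all
from one seeded stream with subjects drawn sequentially — the whole design
is a pure function of (items, n_subjects, max_per_subject, seed). No
cross-subject balancing is enforced by default, matching the near- but not
exactly balanced per-pair totals real randomization produces; an optional
flag down-weights already-used pairs.

The simulator's default scenario reproduces the study conditions: 8 items,
37 subjects, up to 7 judgments each, with the fitted worth spread
(β from 1.49 down to −2.52) as ground truth and δ = 0 unless set. A master
seed spawns independent sub-streams for the design and the outcomes, so
byte-identical record streams are reproducible and the two sources of
randomness can be varied independently. What the simulator does *not*
emulate: subject dropout (the real study recorded 224 of 259 planned
judgments by an unreported mechanism, so simulated studies have 259),
between-subject taste heterogeneity, and drift in sample consistency over
a session. Passing recovery tests therefore demonstrate estimator
correctness under the model, not robustness to those real-data features.

Recovery experiments refit each simulated replicate (with the order term
iff a nonzero δ is under test) and report per-item bias, RMSE and 95% Wald
interval coverage. Replicates with separation are counted and excluded,
never regularized away — at study size with a wide worth spread they
genuinely occur, and hiding them would bias the summaries.

## Problem sizes used in the checks

The fixture analyses are deterministic and run in well under a second.
Monte-Carlo checks use 50,000 judgments for point recovery of δ (±0.05
band), 500 study-sized replicates for coverage (accepted range 90–99%),
10,000 subjects for the design-uniformity chi-square, and 100 random
5-item instances for MM/Newton agreement; these sizes give comfortable
margins for the properties asserted while keeping the whole suite in a few
seconds.

## Known limitations

- Independence across a subject's judgments is assumed, as in the source
  analysis; panels with many judgments per subject would warrant random
  effects.
- Quasi-variance quality is data-dependent; always read the reported worst
  relative error before using per-item error bars for a specific contrast.
- The pseudo-count option changes the estimand; it exists for exploration,
  and no reported result uses it.
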