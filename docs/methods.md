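# Methods

This note documents the models, parameter choices and numerical
conventions behind `goaoa`, and what the synthetic benchmarks do and do
not demonstrate.

## The wrapper objective

Feature selection is posed as continuous box-constrained minimization
over `[0,1]^D`.  A position is thresholded at 0.5 (inclusive) into a
feature mask; the objective is

    Fit(x) = α · E(BX) + (1 − α) · |BX| / D

with `α = 0.99` fixed.  The blend weight is sometimes described as a
random balance in the wrapper-selection literature; we keep it a
configuration constant because re-randomizing the objective per call
would make fitness comparisons between candidates incoherent.  `E` is
the held-out error of a k-nearest-neighbour classifier (k = 5,
Euclidean distance, scikit-learn brute-force backend).  KNN is the
de-facto wrapper classifier in metaheuristic feature-selection
comparisons and keeps the objective a deterministic function of the
mask given a fixed split; k is configurable.  Features are min-max
scaled using training-partition statistics before any distance is
computed (constant columns scale to zero span and are left centred),
which matters for scale-mixed public tables.  The error is measured on
the held-out 20% partition of a stratified 80/20 split made before the
search starts; an honest generalization estimate for the *final* subset
therefore needs a further untouched partition, since the search itself
consumes the test labels.  A cross-validation-on-train error mode can
be obtained by passing a split whose "test" part is a held-in fold.

Degenerate inputs: an all-below-threshold position would select no
features.  The default policy switches on the largest coordinate
(lowest index on ties) so the classifier stays defined; a strict
alternative (`worst_fitness`) scores the empty mask as error 1.  The
objective memoizes the error per mask — the error is deterministic
given the split, so this changes no computed value, only the cost of
the ubiquitous repeat masks once the search concentrates.

## Growth Optimizer

Minimization over the box with population N.  Each iteration ranks the
population by ascending objective value ("growth resistance", GR) with
a stable sort (ties broken by member index, for reproducibility when
discrete masks tie) and runs two phases.

**Learning.** For individual i, five role players are drawn: the
leader (rank 1), an elite uniform on ranks 2..P1, a bottom individual
uniform on the last P1 ranks, and a distinct random pair L1 ≠ L2 ≠ i.
Four gaps (leader−elite, leader−bottom, elite−bottom, L1−L2) are
weighted by learning factors `LF_k = ‖Gap_k‖/Σ‖Gap_j‖` and the strength
factor `SF_i = GR_i/GR_max`, and added to the position.  Degenerate
cases: when every gap is zero (collapsed population) the learning
factors default to 0.25 each by symmetry; when `GR_max ≤ ε` the
strength factor is 1.  GR values for SF are snapshot at phase start;
positions update in place, so later individuals see earlier accepted
moves — the usual in-place convention for this family of algorithms.

**Acceptance.** An improving candidate always replaces its parent; a
non-improving one survives with probability P2 except when the parent
is the current rank-1 member.  The best-ever solution (gbest) is
updated at every single evaluation and can never worsen, which makes
the reported trace non-increasing by construction.

**Reflection.** One guide is drawn uniformly from the top-P1 block per
individual (drawing it per dimension would be an alternative; per
individual is the less noisy reading and the one implemented).  Per
dimension, with probability P3 the coordinate is either re-initialized
uniformly in the box (probability AF) or pulled a uniform fraction
toward the guide.  Standalone GO decays AF over the evaluation budget,
`AF = 0.01 + 0.99(1 − FEs/MaxFEs)` with `MaxFEs = N + 2N·T`.

Out-of-range handling is hard clipping after every update — the
simplest contract that keeps the 0.5 threshold meaningful on the unit
cube.

## Arithmetic Optimization Algorithm

The canonical formulation: per dimension, a gate draw against the
increasing MOA schedule (`0.2 → 1.0` linear by default) chooses
exploration (division or multiplication around the best-ever position)
or exploitation (subtraction or addition), with magnitude
`MOP(t) = 1 − (t/T)^(1/α)`; `α = 5`, `µ = 0.5`, `ε = 1e−12` guards the
division.  The standalone loop uses greedy acceptance (improvement
only), one candidate per individual per iteration.  All schedule bounds
and constants are configurable so other AOA dialects can be swapped in
without touching the hybrid.

## The GOAOA hybrid

Per individual per iteration, one gate draw against MOA selects either
the full-position AOA exploration branch (anchored on the best-ever
solution) or the GO learning pipeline; both candidates pass through
GO's acceptance rule (P2 = 0.004 here).  The reflection phase is GO's,
with an iteration-indexed, flatter attenuation factor
`AF = 0.02 + 0.33(1 − t/T)` — less random restarting than GO's
schedule, which suits the plateau-rich thresholded landscape.  The
gate placement is a design choice: the hybrid's published description
switches "the exploration phase" of GO for AOA's, without fixing the
within-iteration order; gating per individual on AOA's own schedule is
the minimal rule consistent with both parents, and it is configurable.

A deliberate implementation detail: GO's learning phase always consumes
the gate draw even when the gate is disabled, so GO and GOAOA share one
code path and the hybrid reduces *bit-exactly* to GO when the gate is
pinned open (`moa ≡ 1`).  This is tested as a trajectory identity.

Default parameters follow the published table for this family:
GOAOA `α=5, µ=0.5, P1=10, P2=0.004, P3=0.3`; plain GO
`P1=5, P2=0.001, P3=0.3`.  Population size and iteration budget are not
published values; the package defaults are N = 30 and T = 100, and the
benchmark studies in the test-suite and acceptance script use
N = 20, T = 60 — small enough for exhaustive-oracle comparison on
desk-scale instances, large enough that the hybrid's hit rate against
the oracle is stable.

Evaluation accounting: each individual is evaluated once per phase, so
a two-phase run costs exactly `N + 2N·T` objective evaluations (the
published complexity expression is asymptotic; this is the exact count
under the one-evaluation-per-phase design).  The per-run trace has
length T + 1.

## Randomness

One `numpy.random.Generator` per run, seeded from the configuration,
consumed in a fixed documented order (phase-major, individual-major;
per-dimension draws taken as whole vectors; branch-specific draws
consumed on demand).  A seed therefore fully determines a trajectory,
and every generator, splitter and optimizer is bit-reproducible under
its seed.

## Synthetic data: what it emulates, and what it does not

`synthetic_classification` plants `k` informative columns whose
class-conditional means sit `class_separation` noise-standard-
deviations apart, among `D − k` standard-normal noise columns — a
ground-truthed stand-in for tables whose informative subset is known.
`synthetic_deep_features` emulates embeddings extracted from medical
images by a compact vision backbone: two balanced classes of isotropic
256-dimensional Gaussians whose means differ along one random
direction, so difficulty is a single scalar (the projected
separation).  Defaults mirror a 1400 + 1400 two-class cohort; the
benchmark runs in the acceptance script use 100 per class to keep the
study desk-sized.

Real extracted features are not isotropic Gaussians: they are
correlated, heteroscedastic, often heavy-tailed, and their informative
directions are distributed across many coordinates.  Passing the
synthetic suites therefore demonstrates the *mechanics* — that the
optimizer reaches the global optimum of the stated objective on small
instances, respects its invariants, and shrinks subsets without
degrading held-out error — not clinical performance on bone-scan
cohorts, which depends on a private image set and a trained feature
extractor outside this package's scope.

A consequence worth stating explicitly: with the error-dominant blend
(`α = 0.99`) and strongly separated planted features, the objective's
true optimum is a 1–2 feature subset, because one strong column already
drives the held-out error to zero and every extra feature costs
`(1−α)/D` with no error gain.  On such instances a *correct* optimizer
recovers only a fraction of the planted subset — full-recall recovery
of redundant planted features is not a property of this objective, and
the recovery study in the acceptance suite measures exactly this
trade-off (median selected-subset size, recall, and error versus the
all-features baseline).

## Friedman comparison

Algorithms are ranked within each dataset (midranks on ties), the
better metric value receiving the larger rank — the convention of the
benchmark tables this harness reproduces, and the opposite of many
textbook presentations; the direction is an explicit flag.  Mean ranks
are averaged over datasets; ranks per dataset always sum to
`m(m+1)/2`.  The chi-square statistic and p-value (standard
tie-corrected formula, via scipy) are attached for reference but the
published comparison prints only mean ranks; with fewer than three
algorithms they are NaN.  The shipped fixture matrices are verbatim
three-decimal transcriptions of the published accuracy (7×13),
sensitivity (7×13) and specificity (7×12 — one dataset is absent from
the published specificity table) matrices, and the recomputed mean
ranks match the published comparison to four decimals.

## Known limitations

* The wrapper error is measured on the same held-out partition the
  search optimizes — faithful to the benchmark protocol it mirrors, but
  optimistically biased; use a third partition for unbiased reporting.
* Binary masks arise only through the 0.5 threshold; no transfer
  functions (S/V-shaped) are provided.
* Comparator metaheuristics (BPSO, WOA, HHO, SSA) are not
  re-implemented; they plug in through the optimizer-callable
  interface.
* Categorical features are ordinally coded by the readers, which
  imposes an artificial metric on unordered categories under KNN;
  one-hot encoding is left to the caller.
* The exhaustive subset oracle is limited to D ≤ 12 by design.
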