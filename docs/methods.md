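# Methods

This note records the models behind `foragekit`, the defaults and why
they were chosen, the numerical choices that matter, and what the
simulator does and does not emulate.

## The decision problem

A foraging *trial* (patch, display) is one search screen. Every
collected target is treated as a recorded stay/leave decision: the last
pick before the patch is abandoned is a *leave*, every earlier pick a
*stay*. Decisions exist from the third collected target onward, because
the organization indicators are not meaningful on fewer than three
collection points (a correlation over two points is always ±1 and a
two-point path has no alternative orderings or crossings). A trial with
N ≥ 3 collected targets therefore contributes N − 2 decisions, exactly
one of them a leave. Distractor taps are excluded from the decision
series and from all organization coordinates; they enter only the
optional points-based intake rates. Fully depleted trials keep their
final pick labeled leave but carry a `depleted` flag so that analyses
which care about rule-triggered leaving (e.g. the MVT-recovery checks)
can exclude them.

Decisions are pooled across participants within an analysis stratum
(by default condition × age group) without random effects. The
non-independence of decisions from the same participant is acknowledged
and deliberately not modeled: the target of inference is the operating
characteristic of a *predictor*, not a population parameter, and the
ROC machinery used here has no standard mixed-effects extension. Set
size is never a default stratification variable because it varies
within participants from patch to patch.

## Organization indicators

All four indicators operate on the ordered coordinates of the targets
collected so far, in pixels, origin top-left. For moving displays the
coordinate of each target is the one recorded at its collection
instant. The *trial-so-far* series recomputes each indicator on the
first n picks only, n = 3 … N, so element n is exactly what an online
observer of the trial would have known at pick n (prefix property;
every prefix's optimal path is re-solved from scratch).

- **best-r**: the larger of |corr(order, x)| and |corr(order, y)|,
  Pearson. A zero-variance coordinate contributes 0 rather than NaN;
  if both coordinates are constant the indicator is 0 and the
  evaluation is flagged degenerate. This keeps collinear toy data and
  pathological trials in the series instead of poisoning downstream
  tables.
- **mean ITD**: arithmetic mean of consecutive Euclidean distances.
- **PAO**: `(actual / optimal − 1) × 100` with *optimal* the shortest
  **open** Hamiltonian path with **free endpoints** through the same
  points. Free endpoints give the canonical lower bound on travel; an
  `anchor_first` option constrains the path to start where collection
  started, for the alternative reading in which the observer's entry
  point is taken as given. All points coincident (optimal length 0)
  makes PAO undefined; the evaluation returns NaN and is flagged.
- **intersection rate**: number of segment pairs (i, j), j ≥ i + 2,
  that share at least one point — proper crossing, endpoint touch, or
  collinear overlap each count once per pair (segment predicates via
  shapely) — divided by the number of segments n − 1. Adjacent
  segments always share a pick point and are excluded by construction.
  A `per_target` option divides by n instead, matching conventions
  that report intersections per target; the per-segment denominator is
  the default because the quantity is a property of segment pairs.

### Shortest-path solver

Exact solutions use Held–Karp subset dynamic programming over (subset,
endpoint) states, O(n² 2ⁿ); the default `auto` method uses it up to
n = 12 (configurable, capped at 15) and a heuristic beyond. The
heuristic runs nearest-neighbor construction from every start point,
refines each tour by 2-opt interleaved with Or-opt (relocation of 1–3
node segments, optionally reversed), and keeps the best; for n > 15 the
multi-start sweep is capped at 8 evenly spaced starts. On random
7-point instances the heuristic matches the exact optimum on ≥ 99% of
cases and, being a minimizer run short of optimality, can only
*overestimate* the optimal length — hence heuristic PAO can only
*underestimate* exact PAO, never exceed it. Plain best-start
nearest-neighbor + 2-opt was measurably worse (≈ 90% agreement at
n = 7), which is why the Or-opt pass exists.

## Intake rates and RIAIR

For the i-th collected target at trial-relative time tᵢ (t₀ = 0):
instantaneous rate vᵢ/(tᵢ − tᵢ₋₁), average rate (Σⱼ≤ᵢ vⱼ)/tᵢ, and
RIAIR their ratio. Default `value_mode="items"` sets vᵢ = 1, making
RIAIR a pure function of pick times, which is the Marginal Value
Theorem read on intake counts; `points` mode uses the score deltas
(+2 target / −1 distractor) instead, as a sensitivity analysis. The
2-s inter-patch travel cost is session metadata and excluded from the
average-rate denominator by default (`include_travel` adds it): the
within-trial rate is the literal MVT quantity, and the choice only
rescales RIAIR monotonically, which leaves every ROC result unchanged.
The rate record at pick 1 uses trial onset as its reference event; it
exists for completeness but decision sets start at n = 3, so this
convention cannot affect any headline number.

## Composites

Standardization statistics (mean, sd per indicator) are computed over
*all* trial-so-far instances within the stratum, excluding flagged
degenerate evaluations; the population identity is recorded in the
provenance output. Dimensionality is assessed on **end-of-trial**
values only — one row per trial — because repeated instances from the
same trial are strongly dependent and would overstate the sample.

Parallel analysis follows Horn's original scheme: eigenvalues of the
observed 4 × 4 correlation matrix, minus the over-chance inflation
(mean random-data eigenvalue − 1) estimated from `reps` standard-normal
datasets of identical shape (default 500, seeded, deterministic).
Retention is sequential — leading components are kept while their
adjusted eigenvalue exceeds 1, stopping at the first failure — because
for later components the adjusted value hovers around 1 by construction
and a non-sequential count would flip coins on pure noise.

PCA loadings are the first eigenvector scaled by √λ₁, oriented so the
best-r loading is positive (the component's sign is otherwise
arbitrary). Composite weights are the loadings' *absolute values*; the
sign structure (+ best-r, − mean ITD, − PAO, − intersection rate) is
imposed explicitly by the composite formula, so signed loadings would
double-apply direction. Using raw eigenvector coefficients instead of
loadings would rescale the composite by the common positive factor √λ₁,
a strictly monotone change that cannot alter any ROC curve, threshold
ordering, or Youden point — the choice is cosmetic and loadings were
chosen.

## ROC analysis

Positive class is *leave* throughout: sensitivity is the proportion of
leaving decisions predicted, specificity the proportion of staying
decisions predicted. Thresholds are the midpoints between adjacent
distinct predictor values plus ±∞ sentinels, so each achievable
confusion table appears exactly once and reported thresholds fall
between observed values rather than on them. Default polarities encode
the directional hypotheses — leave is signalled by *low* composite,
best-r and RIAIR and by *high* mean ITD, PAO and intersection rate —
with `auto` available. The trapezoid AUC over these points equals the
Mann–Whitney concordance probability exactly, ties counted half, which
the test suite verifies by brute-force pair counting. Youden's J picks
the optimal point; ties are broken toward the more sensitive point
(catching leaves is the scarcer ability) and the rule is stable under
input order. No smoothing is applied anywhere in computation.

Single-predictor AUC CIs use DeLong's placement-value variance.
Combined curves have no per-decision scores, so their CIs use the
Hanley–McNeil standard error, which needs only the AUC and the two
class counts.

### Combining two ROC curves

Under class-conditional independence, a pair of operating points — one
per predictor — induces four joint outcomes (both tests positive, only
A, only B, neither) with known class-conditional probabilities.
Sweeping a likelihood-ratio threshold over the outcomes generates the
achievable (sensitivity, specificity) points of that pair; the combined
curve is the upper-left Pareto envelope over all pairs and sweeps.
Envelope points whose outcome set is expressible as a deterministic
rule are annotated with it — AND, OR, or a single test, possibly with a
flipped direction; XOR-type outcome sets are achievable by the LR sweep
but quoted rules are restricted to deterministic threshold logic, and
reports pick the Youden-best *annotated* point so that the printed
compound rule always reproduces the printed sensitivity and
specificity. Before pairing, each curve is thinned to at most 201
evenly spaced operating points to bound the O(P·Q) sweep;
full-resolution mode is available. An `empirical` mode instead
evaluates AND/OR rules directly on the raw values over the thinned
threshold grids and envelopes the result; it drops the independence
assumption and is the appropriate check when the two predictors share
within-trial structure. Note that pairing an informative curve with a
chance-level one realizes randomized mixtures of the informative
curve's own operating points, i.e. its convex hull — so a combined AUC
can legitimately exceed a non-concave partner's trapezoid AUC even when
the second predictor carries no information.

## The simulator

The generator emulates the statistical structure the analysis assumes,
at the study conditions the pipeline is meant for: a 1400 × 1500-px
arena; set sizes of 40–180 items with target proportion drawn uniformly
in [0.20, 0.30] per trial; item speed 0 (static), 44 or 88 px/s with
per-item direction redraws at intervals uniform in [0.5, 2.0] s
(defaults standing in for "semi-random" direction changes) and elastic
reflection at the walls. Items are points; capture records the item's
position at the collection instant, with no touch-error model.

Agents start at the arena center and repeatedly select the next target:
nearest-remaining with probability 1 − ε and uniformly at random with
probability ε (`nearest_neighbor`), by noisy reading order (`scanner`),
or fully at random. Pick time advances by
(0.3 s + distance / 1000 px·s⁻¹) × Lognormal(0, 0.2) — a simple
Fitts-like latency-plus-movement model, fully configurable, with no
claim of fitting human reaction times. Because targets deplete, the
nearest-target distance grows within a trial, producing the declining
instantaneous rates that patch-leaving theory presumes. Quitting rules:
`mvt(θ)` leaves at the first pick (≥ min_picks = 3) whose RIAIR,
computed by the same arithmetic as the analysis module, falls below θ;
`giving_up_time(G)` leaves when the anticipated time to the next target
exceeds G seconds; `fixed_count(k)` and `random(p)` as named. A rule
that never fires ends the trial at depletion, flagged. Identical seeds
and configurations give byte-identical event logs, and per-pick rule
evaluations are emitted as ground truth.

What the simulator does **not** emulate — and hence what passing tests
do and do not show: there is no memory load, no feature/conjunction
difficulty, no development, no target-identification errors, no gaze or
anticipation model, and pick-time noise is i.i.d. lognormal rather than
human. Recovery results (e.g. that the pooled RIAIR ROC recovers a
strict-MVT agent's θ, or that composite scores rank agents by their
disorder parameter) validate the *pipeline's* correctness and
sensitivity, not any claim about human foragers; conversely, failures
of a predictor on simulated cohorts whose leaving rule ignores that
predictor (e.g. RIAIR on fixed-count leavers) are by design.

Test and validation problem sizes were chosen to keep the full suite
fast while leaving no estimate starved: cohorts of 30 agents × 40
trials for rule recovery, 5 disorder levels × 30 trials for the
organization gradient, 500 random 7-point instances for the
path-solver audit, and n = 2000–5000 decisions for ROC calibration
checks.

## Known limitations

- The independence-mode combined curve assumes class-conditional
  independence of the two predictors; the composite and RIAIR are
  computed from the same trials and violate this to some degree. The
  empirical mode exists precisely to quantify that gap on real data.
- DeLong CIs ignore the clustering of decisions within participants
  and trials; intervals are anti-conservative to an unquantified
  degree on pooled decision sets.
- The heuristic path solver is not exact for n > 12; PAO values on
  very long trials are lower bounds on disorganization in the sense
  described above.
- Standardization, PCA and thresholds are stratum-specific; values are
  not comparable across strata without re-standardization.
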