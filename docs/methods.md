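# Methods

This note documents the model assumptions, estimation choices, numerical
conventions and known limitations behind `ctmi`.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Setting and assumptions

The object of inference is the summary causal graph over a panel of
discrete-time, real-valued series.  Assumptions: the causal Markov
condition and faithfulness; consistency of causal relations through time
(so a single graph over series is meaningful); acyclicity of the summary
graph between distinct series; and first-order Markov self-causation —
every series instant is caused by its own previous instant, modeled as an
implicit lag-1 self-loop that is neither tested nor scored.  `pctmi`
additionally assumes causal sufficiency; `fcitmi` drops it and returns a
partial ancestral graph.  Selection bias is out of scope (the
corresponding orientation rules are deliberately omitted).

## Window representation and alignment

Windows of λ consecutive observations represent each series; a pair of
windows is joined at a constant lag γ between start times (positive γ:
the first series leads).  Internally all lags are expressed in sub-unit
ticks: one time unit is divided into lcm(rates) ticks so that series with
different integer sampling rates share a grid, and joint rows recur every
lcm of the per-series tick spacings.  When window time-spans differ
between series, windows are matched on start time only; the per-series
window size in points is a caller choice, not auto-scaled to equal
duration.  Rows touching a NaN observation are dropped with a logged
count.  Lags are 0-based array offsets internally; the one-step "past"
column of each block is the single observation immediately preceding it
in that series' own sampling.

Search space: |γ| ≤ γ_max, 1 ≤ λ ≤ λ_max with λ_max = γ_max + 1 by
default.  A `SearchSpace(extended=True)` switch sets λ_max = 2·γ_max + 1,
which makes a maximal window centered on any instant cover every
admissible lagged sub-window — the regime in which the skeleton
identifiability argument is airtight — at a substantial cost in estimator
dimension; the default follows the measure's definition and benchmark
practice.

## Estimation

Conditional mutual information is estimated with the k-nearest-neighbor
digamma estimator under the supremum distance (default k = 10).
Neighbor counts are taken strictly inside the k-th-neighbor radius and
include the query point, which is the standard ψ(n+1) convention of the
conditional (Frenzel–Pompe) form; with an empty conditioning block the
construction reduces to the plain Kraskov MI estimator.  Zero counts
(possible only with exactly duplicated points) are clamped to one before
the digamma, with a warning.  Each series is standardized to zero mean
and unit variance before estimation — the sup-distance is scale
sensitive — and a seeded uniform jitter of amplitude 1e−10 is added once
per series to break distance ties.

Significance: a local permutation test with B permutations (default 100;
the acceptance script and the benchmark tests use 50 for runtime, at
p-value resolution 0.02).  Rows of the cause block are reassigned only
among their 5 nearest rows in the conditioning space (drawing without
replacement as far as possible, falling back to a random neighbor), so
the permuted data preserve the cause's dependence on the conditioning
variables; with no conditioning block the permutation is unrestricted.
P-values are multiples of 1/B; dependence is declared when p ≤ α
(default α = 0.05).

## Tie-breaking at the estimator's resolution

The measure's tie-break rules (largest lag, then smallest windows for the
maximization; largest conditioning lag, then smallest window for the
minimization) are stated for exact ties, which sampled estimates never
produce.  The package therefore treats estimates within one *resolution*
(default 0.01 nats) of the grid optimum as tied and applies the
deterministic tie-break within that band.  The value matches the measured
across-sample standard deviation of the estimator at n = 1000, k = 10
(about 0.005–0.015 nats, shrinking with n).  This matters for two
reasons.  First, the population CMI is monotonically non-decreasing under
window growth — the chain rule guarantees it — so the *noisy argmax*
otherwise drifts to the largest windows on every pair, inflating the
estimation dimension and defeating both conditional blocking and lag
orientation.  Second, the minimization over conditioning configurations
otherwise returns a value about two standard deviations below its true
minimum (selection bias over ~60 grid points), which the single-point
permutation null cannot see.  The greedy window search grows a window
only when the estimate improves by more than the resolution.

Search strategies: `exhaustive` scans the full (λ_pq, λ_qp, γ) grid
(O(γ_max · λ_max²) estimates per pair) and is the default of the `ctmi`
function; `greedy` hill-climbs windows from (1, 1) at every lag and is
the default of the benchmark driver, where the full grid is not
affordable at 10 replicates × 3–4 nodes.  With several conditioning
series the conditional minimization uses coordinate descent — one
conditioner at a time, the others held at (Γ = 0, λ = 1), two sweeps —
since a joint search is combinatorial; with a single conditioner one
sweep is an exhaustive scan.

## Discovery

The skeleton phase follows the PC-stable pattern: for growing
conditioning-set cardinality, all candidate (pair, set) tests are
gathered, their measure values computed, the list sorted ascending, and
tests executed in that order with adjacency re-checked at pop time;
removals record the separating set.  Candidate conditioners must not lie
strictly in the future of both endpoints, judged from the cached pairwise
optimal lags.  The permutation test is applied once per (pair, set)
triple, at the optimizing configuration.

`pctmi` applies the lag-based entropy-reduction rule to lagged edges
*before* the collider rule (at realistic sample sizes the optimal-lag
sign is the more reliable collider detector; a flag restores the textbook
order), then the collider rule once, the propagation rules to a fixed
point, and the entropy-reduction rules on whatever remains.  Both
entropy-reduction rules require that the endpoints admit *no possible
spurious correlation* — no alternative collider-free path; undetermined
(circle) marks count as non-colliders, which is the conservative reading
(more paths block, fewer orientations).  Orientation conflicts are
handled first-writer-wins within a pass; a rule demanding the opposite
arrowhead reverts the edge to undetermined, logs it, and freezes the edge
(which also bounds rule firings and guarantees termination).  Undirected
leftovers are kept and marked, not dropped.

`fcitmi` re-marks the skeleton with circles, applies the circle-collider
rule, removes further edges by conditioning on subsets of Possible-Dsep
sets (cardinality capped at 3 by default, same sort-then-pop strategy;
the conditional search re-optimizes only the conditioning lags/windows,
keeping the pair's cached optimum), resets all marks, and iterates FCI
rules 1–4 and 8–10 plus arrowhead-only entropy-reduction variants.

With the statistical test replaced by a perfect d-separation oracle, the
pipeline recovers the exact generating graph of the fork, v-structure and
diamond benchmarks, and the worst-case test count respects the
d²(d−1)^(k−1)(k−1)! bound; both are asserted in the test suite.

## Synthetic benchmark generator

Each series follows X_t^q = a_qq X_{t−1}^q + Σ_parents a_pq f(X_{t−γ}^p)
+ 0.1·ξ_t^q from the zero initial state, with coefficients drawn once per
edge (and per self-loop) uniformly on ±[0.1, 1], f drawn per edge from
{|·|, tanh, sin, cos}, and ξ ~ N(0, 15) read as *variance* 15, so the
innovation standard deviation is 0.1·√15 ≈ 0.39 (configurable).  No
burn-in by default (an option exists); series lengths default to
T = 1000; inter-series lags default to 1 where a published structure does
not print them.  Explosive trajectories (|X| > 1e12, possible with the
absolute-value nonlinearity) are regenerated with a fresh coefficient
draw, logged.  Hidden series are simulated then dropped; the returned
ground truth connects observed children of a dropped hidden cause with a
bidirected edge.  The latent 7-series/2-hidden template is a labeled
reconstruction in which each confounded child also has an observed
parent — the configuration in which bidirected edges are identifiable at
all — not a copy of any published figure.

What the generator does *not* emulate: non-stationarity, measurement
noise distinct from process noise, missing data patterns, non-integer
sampling-rate ratios, cyclic summary structures, time-varying causal
directions.  Passing benchmark tests therefore demonstrate recovery under
stationary nonlinear additive dynamics, not robustness to those
real-data complications.

About a quarter of generated inter-series edges are intrinsically hard at
T = 1000: a coefficient near 0.1 applied to a bounded nonlinearity is
buried under the 0.39 innovation noise, which is what keeps benchmark F1
means visibly below 1 and their dispersion high.

## Evaluation

Directed-edge F1 ignores self-loops.  A predicted edge claims p → q when
it carries an arrowhead at q and no arrowhead at p (a circle at the tail
end still counts as a directed claim); arrowheads at both ends claim a
hidden common cause and are matched against bidirected truth edges.
Undirected and circle–circle predictions never count as true positives.
Two graphs with no inter-series edges score 1.

## Worked-model discrepancies

The package's closed-form Gaussian oracle (exact innovation-coefficient
covariances of linear lagged models, log-determinant CMI) disagrees with
two printed claims about the standard worked example (a random walk
driving a second series at lags 1 and 2):

* at the lag-1, windows-(2, 2) grid point the closed form is
  (3/2)·ln 2 ≈ 1.0397 nats, not 3·log(3)/4;
* the population CMI keeps growing with window size (as the chain-rule
  identity requires), so the population argmax at λ_max = 3 is
  (γ = 2, λ = 3, 3) ≈ 1.94 nats rather than (γ = 1, λ = 2, 2); the kNN
  estimator at n = 4000, whose estimates saturate on this
  near-deterministic dependence, selects (γ = 2, λ = 1, 1) under the
  resolution-band tie-break.

The oracle, not the printed constants, is the reference the tests assert
against; the corresponding recovery test in the acceptance suite asserts
the printed claim and is expected to fail.

## Known limitations

* Edges whose endpoints retain a collider-free alternative path cannot be
  oriented by the entropy-reduction rules; dense skeletons may come out
  largely undirected.
* The permutation test is evaluated at the optimizing grid point only;
  the maximum over a grid of correlated estimates is mildly
  anti-conservative for adjacent near-unit-root series, which occasionally
  retains a spurious edge that no conditioning set can later remove.
* Conditioning on windows of a *descendant* of the cause can explain away
  a weak direct edge at finite n — a faithfulness-style power failure
  shared by all constraint-based methods, amplified here by windowed
  conditioning.
* Estimation cost is O(n²) per grid point (numba-compiled); panels beyond
  a few thousand points per series or beyond ~10 series call for the
  greedy search and reduced permutation counts.
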