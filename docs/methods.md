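# Methods

## Model

The simulated system is a probabilistic cellular automaton for cell
sorting by differential migration.  Cells live on a periodic `L x L`
square lattice (default `L = 25`, 625 sites), one cell per site, each
carrying one of `N` type labels; per-type counts are fixed at
construction and conserved exactly (no division, death or growth).  The
only move is the exchange of two adjacent heterotypic cells, which fires
at rate

    c(x, y, eta) = exp(-(S_x + S_y)),
    S_x = sum over z in N(x) of beta[eta(x), eta(z)],

with `N(x)` the von Neumann 4-neighborhood under periodic wrap.  Each
neighborhood sum includes the partner site, so the exponent carries eight
bond terms; this convention is what makes a global shift of all bond
strengths by `theta` rescale every rate by exactly `exp(-8 theta)`, and it
reproduces the two standard worked rates (straight-interface exchange
`exp(-(3 b00 + 3 b11 + 2 b01))`, lone-cell exchange `exp(-(3 b11 + 5
b01))`).  Homotypic exchanges would not change the configuration and are
excluded.  The bond matrix `beta` is symmetric and dimensionless; its flat
vector lists homotypic entries first, then heterotypic pairs `i < j` in
lexicographic order.

The model's time axis is the number of applied switches.  Exponential
waiting times (rate = total event rate) are drawn and can be recorded, but
every reported summary is switch-indexed: the scaling parameter `beta_s`
changes only the waiting-time scale, so switch-indexed observables are
invariant under it.

## Simulation engine

The engine is a Gillespie scheme over the adjacent heterotypic pairs.
Each unordered pair is one event (both orderings describe the same
physical exchange).  After a switch at `(x, y)`, exactly the events with a
member in `{x, y} U N(x) U N(y)` can have changed; only those are
recomputed.  Per switch the random stream is consumed in a fixed order —
one uniform for event selection, one for the waiting time — which makes
runs bit-reproducible given the seed.

Rates span many orders of magnitude (`exp` of sums of bond strengths up to
about +-80 when draws come from `U[-10, 10]`), so a running total
maintained by incremental `+= new - old` updates is destroyed by
floating-point cancellation; in early testing this produced spurious
frozen states.  The production kernel (numba-compiled) therefore keeps the
per-edge rate array grouped in blocks of 32; block partial sums are
re-summed exactly whenever a member edge changes, the total is the short
sum over block sums recomputed every step, and event selection walks
blocks first, then edges within the chosen block.  Selection and partial
sums accumulate in the same order, so an overshoot past the last live
event can only arise from last-bit rounding; it falls back to the last
live edge.  A pure-Python event table with the same semantics (dictionary
of pairs, incremental total with periodic exact re-summation every 10^4
steps) serves as the transparent reference implementation on small
lattices.

Correctness of the engine is established against an exactly solved oracle
rather than against any particular bookkeeping: on the 3x3 two-type
lattice with counts (4, 5) all 126 configurations are enumerated, the full
jump-chain transition matrix is built from the single-pair rate function
alone, its stationary distribution is solved by eigendecomposition, and
the stationary expectation of the order indicator is compared with the
switch-averaged value from long simulations (batch-means 3-sigma
Monte-Carlo error).  Both the fast kernel (10^6 switches) and the
reference table (6x10^4 switches) are checked this way.

## Order indicator

`d(eta)` counts undirected homotypic nearest-neighbor contacts (each of
the `2 L^2` lattice edges at most once).  The order indicator normalizes
it between constructed extremes: `d_max` is attained by the row-major
stripe fill of the requested counts (full phase separation), `d_min` by
the alternating pattern `(row + col) mod N` — the chessboard for `N = 2`,
diagonal stripes for `N = 3`.  When `L` is not divisible by the pattern
period the wrap leaves one defect row and one defect column (`2 L`
homotypic contacts); for two types this is provably the true minimum
(every row and every column is an odd cycle and contributes at least one
monochromatic edge), and for small lattices both extremes are verified by
exhaustive enumeration.  For `N >= 3` on incommensurate sides the
constructive minimum is an anchor, not a proven optimum; trajectory values
are clipped into [0, 1] and a warning is raised if a configuration beats
an anchor.  The anchors and the configurations attaining them travel with
the `OrderExtremes` object, together with notes recording any wrap
defects.

The asymptotic level `omega_bar` is the arithmetic mean of `omega` over
the recorded points in the last 10% of the switch index range.  The
default recording stride is `n_switches / 1000`, keeping about 100 points
in the averaging window; a trajectory must have at least 10 recorded
points for the estimate to be accepted.

## Derived system parameters

For the flat vector `beta` of length `N + N(N-1)/2`:

* `beta_s = <beta, 1>` (scaling);
* `beta_star = sum_i beta_ii - 2/(N-1) sum_{i<j} beta_ij` — the
  relabeling-invariant linear functional orthogonal to the all-ones
  direction, normalized so the homotypic coefficient is 1.  Its critical
  value 0 balances the heuristic mixing and unmixing limit rates: the
  ratio `c_unmix,0 c_unmix,1 / c_mix^2 = exp(3 beta_star)` identically;
* `beta_delta`: for two types `|beta_00 - beta_11|`, the convention used
  to label the first-passage experiments; for `N >= 3` the Euclidean
  distance of the flat vector to its type-symmetric projection (homotypic
  entries replaced by their mean, heterotypic by theirs).  For `N = 2` the
  two conventions differ by exactly `1/sqrt(2)`; both are exposed and the
  `N`-dependent default matches the labeling above.  In the distance form
  each heterotypic entry is counted once, consistent with the flat-vector
  ordering.

A 2x2 symmetric relative contact-tension matrix `T` from experiments or
Potts-type simulations maps onto the same scale via `beta_ij = -T_ij`
(high tension = low effective adhesion), giving
`beta_star = -T00 - T11 + 2 T01`.

## Sweeps, classification and estimation

A sweep draws flat vectors from `U[-10, 10]^d`, optionally
rejection-sampled until a constraint holds (the three-type experiments use
`beta_delta < 3`, which keeps the sample dominated by runs that converge
within the simulation horizon); each accepted draw is simulated once from
a fresh seeded uniform random start.  Per-run seeds derive from a single
master generator, so a run table is a pure function of
`(master_seed, conditions)`.  Rejection aborts with an error if 10^5
consecutive draws fail (acceptance below 0.001%).

Runs are labeled +1 when `omega_bar` strictly exceeds the random-mixture
level `1/N` (0.5 for two types, 1/3 for three), else -1; runs are *not*
filtered by convergence, so slowly converging draws contribute label noise
near the critical plane — this is what degrades the fitted intercept
relative to its ideal value 0.  By relabeling invariance a linear decision
boundary can depend on the bond strengths only through the homotypic and
heterotypic sums, so the features are compressed to those two numbers and
the boundary `0 = a (sum hom) + b (sum het) + i` is fitted with either a
soft-margin linear SVM (`C = 1`) or logistic regression with negligible
penalty (`C = 10^6`).  On near-separable data the recovered direction is
insensitive to these regularization choices (verified by the estimator
recovery test).  Coefficients are reported relative to `a`; the
theoretical values are `b/a = -2/(N-1)` and `i/a = 0`.  Accuracy is the
mean over a seeded stratified 5-fold cross-validation.

The estimator-only oracle separates fit correctness from simulation noise:
labels are generated analytically as `sign(beta_star)` on uniform draws
with `|beta_star| >= 1`.  The margin matters: with draws dense at the
critical plane, held-out points arbitrarily close to the boundary make an
exact cross-validated accuracy of 1 unattainable for any estimator, and
the label itself is physically meaningless at `beta_star ~ 0` (the system
stays mixed there).  With the margin both methods recover `b/a` to well
under 2% and classify perfectly.

## Study conditions and problem sizes

Defaults mirror the published setup: lattice side 25 (625 cells; the
stopping rule `312,499 = 500 * 625 - 1` switches is consistent with that
choice, and side is a parameter in any case), near-equal type counts with the
remainder assigned to the lowest type indices, termination after 312,499
switches, recording stride `n/1000`, draws from `U[-10, 10]^d`.

The package's own experiment sizes: sweeps run 3x10^5 switches per
simulation; the two-type sweep uses 2000 runs (the intercept of the fitted
boundary is the one quantity that needs the full sample) and the
three-type sweep 500 runs, which already pins the rank correlations and
relative coefficients to well inside their tolerances.  The acceptance
script uses 1000 two-type runs because it reports only the correlation and
`b/a`.  The zero-adhesion mixing-point check uses 3 replicates of 3x10^5
switches; the random-start anchors average 100 seeded draws.

## What the generator does and does not emulate

Synthetic inputs are exactly the model's own study conditions: uniform
bond-strength boxes, seeded uniform random starts with fixed counts.  Real
tissues violate several idealizations — cells are not single lattice
sites, neighborhoods are not 4-regular, counts change by proliferation and
death, and bond strengths are neither constant in time nor spatially
homogeneous.  Passing tests therefore certify the mathematical claims
about this model class (existence and form of the effective adhesion
parameter, its critical value, the convergence-speed ordering), not
quantitative predictions for any particular experiment.  The
contact-tension mapping shows how measured relative tensions enter the
framework, but no experimental tension values ship with the package.

## Known limitations

* `omega_bar` estimates the asymptote from a finite horizon; for large
  `beta_delta` or `|beta_star|` near 0 it is biased toward the starting
  level.  This is a property of the estimator shared with the published
  analysis, not a defect of the engine.
* The constructive `d_min` anchor for `N >= 3` on sides not divisible by
  `N` is not proven minimal (the two-type odd-side case is).
* Switch-indexed results say nothing about wall-clock sorting times;
  `beta_delta` orders switch counts only.
* The jump-chain oracle is exact but only feasible on lattices small
  enough to enumerate; engine correctness at production sizes rests on
  that oracle plus the local-update consistency checks.
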