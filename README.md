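# dmmsort

Stochastic lattice simulation and analysis of multi-type **cell sorting** by
differential migration.

During tissue development, mixed populations of cells segregate into
homotypic clusters.  Competing explanations — differential adhesion,
differential interfacial tension, heterotypic repulsion — all act by making
cell–cell contacts modulate cell motility in a type-specific way.  This
package implements a probabilistic cellular automaton that captures exactly
that common mechanism, for any number of cell types, together with the
analysis pipeline that extracts the single scalar which predicts the
outcome: the **effective adhesion parameter**.

## Model

Cells occupy the sites of a periodic `L x L` square lattice, one cell per
site, one of `N` types per cell; per-type counts are conserved.  Two
adjacent cells of *different* type exchange positions at rate

```
c(x, y, eta) = exp( - sum_{z in N(x)} beta[eta(x), eta(z)]
                    - sum_{z in N(y)} beta[eta(y), eta(z)] )
```

where `N(x)` is the von Neumann 4-neighborhood (each sum includes the
partner site, eight bond terms in total) and `beta_ij = beta_ji` are
dimensionless bond strengths: positive values (binding) hinder migration,
negative values (repulsion) enhance it.  Time is counted in applied
switches; waiting times between switches are exponential in the usual
Gillespie sense.

Segregation is measured by the **order indicator** `omega(eta) =
(d(eta) - d_min) / (d_max - d_min)`, where `d` counts homotypic
nearest-neighbor contacts; `omega` is 0 for a chessboard-like pattern, 1
for full phase separation, and about `1/N` for a random mixture.  The
asymptotic level `omega_bar` is the mean of `omega` over the last 10% of a
trajectory.

Three derived scalars of the flat bond-strength vector
`beta = (beta_00, ..., beta_{N-1,N-1}, beta_01, beta_02, ...)` organize the
dynamics:

* scaling parameter `beta_s = <beta, (1, ..., 1)>` — rescales all waiting
  times by `exp(-8 theta)` under a global shift by `theta`, nothing else;
* **effective adhesion parameter**
  `beta_star = sum_i beta_ii - 2/(N-1) * sum_{i<j} beta_ij` — the unique
  relabeling-invariant linear functional orthogonal to the scaling
  direction; it predicts `omega_bar`, with `beta_star = 0` the critical
  point at which the system stays mixed;
* convergence-speed parameter `beta_delta` (for two types
  `|beta_00 - beta_11|`, in general the distance to the type-symmetric
  vector) — larger values mean more switches to reach the asymptote.

The package simulates the model, sweeps bond-strength vectors drawn from
`U[-10, 10]^d`, classifies runs as sorted/mixed against the random level,
and recovers the direction of `beta_star` from the labels with a linear SVM
or logistic regression on symmetry-reduced features — reproducing the
theoretical coefficients `(1, -2/(N-1), 0)`.  A 2x2 relative
contact-tension matrix from experiments or Potts-type models maps onto the
same parameter via `beta_ij = -T_ij`.

## Worked example

One simulation with strong homotypic binding and heterotypic repulsion
(`beta_star = 3`):

```
$ dmmsort simulate --beta 1.2,-0.2,-1.0 --n-switches 312499 --seed 1
{
 "run": {
  "side": 25,
  "seed": 1,
  "n_switches": 312499
 },
 "beta_s": 0.0,
 "beta_star": 3.0,
 "beta_delta": 1.4,
 "omega_start": 0.5156794425087108,
 "omega_bar": 0.9767654465795013
}
```

The random start sits at the two-type mixture level `omega ≈ 0.5`; with a
positive effective adhesion parameter the population sorts and the
asymptotic order indicator ends near 1 (fully phase-separated).  With
`--beta 0,0,0` (`beta_star = 0`) the same command stays at
`omega_bar ≈ 0.5`.

The same machinery is scriptable:

```python
import dmmsort as dm

table = dm.sweep(2, 200, n_switches=100_000, master_seed=0)
print(dm.rank_correlations(table))        # (spearman, kendall)
fit = dm.fit_hyperplane(dm.classify_runs(table), "svm")
print(fit.b_rel)                          # ~ -2, the predicted coefficient
```

`dmmsort preset fig3|fig4a|fig4b|table1a|table1b|appD` regenerates the data
behind the published figures and tables at full or reduced scale.

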