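# Methods

This note documents the models implemented in `mobsig`, the numerical
and design choices behind them, what the synthetic data generator does
and does not emulate, and the package's known limitations.

## Data model and preprocessing

Inputs are a city table (id, name, centroid latitude/longitude,
resident population) and a long-format flow table (origin, destination,
period label, trip count). Flows are stored sparsely; an absent pair is
a zero flow. Margins (row sums `n_i+`, column sums `n_+j`) are always
recomputed from the stored flows, so they agree with a brute-force sum
by construction.

Preprocessing sets all within-city flows to zero and removes every flow
strictly below a censoring threshold (default 20 trips, the privacy
floor typical of operator-aggregated OD products). The comparison is
strict — a flow of exactly 20 survives — and the operation is
idempotent. The threshold is a plain parameter applied to whatever
matrix it is given: when daily censored feeds are aggregated to monthly
matrices, the caller decides whether to censor again, since the
appropriate order of aggregation and censoring depends on how the feed
was produced.

Distances are great-circle (haversine) between centroids with Earth
radius 6371.0088 km. At country scale the centroid approximation
dominates any geodesy refinement, so no ellipsoidal model is used.

## Mobility signatures

A city's signature is its outgoing-flow fraction vector sorted in
descending order; ties are broken by ascending destination id so output
is deterministic. A city with no outgoing flows has an empty signature
(length 0), distinct from an unknown city id, which is an error.

Signatures are compared with the Jensen–Shannon divergence using base-2
entropies, which bounds the divergence by 1. Two conventions matter and
are fixed here:

* **Rank alignment.** Signatures are compared as rank distributions —
  fraction vectors aligned by rank, the shorter zero-padded to the
  longer length — not matched by destination identity. Signatures of
  two different cities share no destination namespace, yet must be
  comparable; rank alignment is what makes the signature a *shape*
  descriptor. Truncation to the common length was considered and
  rejected: it discards exactly the tail behaviour the signature is
  meant to capture.
* **Probabilities, not counts.** Entropies are computed on the
  normalized fractions (0·log 0 := 0). Entropy of raw trip counts would
  be unbounded and scale-dependent.

The result is clipped to [0, 1] against round-off. The divergence of
two empty signatures is undefined (error); against a single empty
signature the padding convention applies.

## Doubly-constrained gravity model

Flows are `T_ij = A_i n_i+ B_j n_+j exp(-beta d_ij)` with `T_ii = 0`.
Balancing factors are found by Furness iteration (alternate row and
column scaling), initialized at 1, stopping when the maximum relative
margin error falls below 1e-8, with a 10,000-iteration default budget.
Non-convergence raises an error carrying the iteration count and the
achieved error; it is never silent. Zero-margin rows or columns are
fixed at zero flow and excluded from the error. The solution is unique
up to the usual `A_i·B_j` scaling gauge; the flows are
gauge-independent.

Two numerical guards matter at strong deterrence:

* The kernel is computed as `exp(-beta (d_ij - min_j d_ij))` per row.
  IPF is invariant under row scalings of the kernel (absorbed into
  `A_i`), and this keeps entire rows from underflowing to zero when
  `beta × distance` is large.
* Margins that are infeasible under a zero diagonal — a city whose
  production exceeds the attraction available elsewhere — are rejected
  up front with a clear error; under such margins IPF provably diverges
  (the balancing factors grow without bound until overflow, which is
  also caught and reported as non-convergence).

**Calibration of beta.** The deterrence rate is estimated by matching
the flow-weighted mean trip distance of the generated matrix to the
observed one (Hyman's classical criterion), by bisection over
beta ∈ [1e-6, 10] /km until the means agree to 1e-6 relative. The mean
is monotone decreasing in beta, so bisection is safe. A trial beta
whose IPF fails (overflow, or slow convergence beyond a 3,000-iteration
probe budget) is treated as over-strong deterrence and the bracket
moves down; the final fit is re-run with the full budget at the
accepted beta. Degenerate inputs — fewer than two distinct observed
trip distances, or margins that pin the flows regardless of beta (e.g.
a two-city system) — raise a calibration error rather than returning an
arbitrary rate. Maximum-likelihood estimation of beta is a valid
alternative the package deliberately does not implement: the mean-trip-
distance match is deterministic, assumption-light, and directly
interpretable.

## Radiation model

Flows follow the finite-size-corrected closed form with populations as
opportunities. The intervening opportunities `s_ij` sum the populations
of destinations *strictly* closer to the origin than `j`, excluding
both endpoint populations, under a total order by (distance,
destination id). This convention makes the row sum telescope exactly:
`sum_j T_ij = T_i` to machine precision, for any geometry, which the
tests verify at 1e-9 relative. Including the destination inside the
circle, or breaking distance ties arbitrarily, would destroy this
identity. The model is undefined when one city holds the entire
population (`m_i = M`). Per-origin totals `T_i` are taken from the
empirical production margins. The model has no free parameter, so its
`fit()` simply generates the matrix.

Model-generated flows are real-valued and are *not* rounded before
censoring; the same strict below-threshold rule used for empirical data
is applied when model signatures are built, so empirical and model
signatures face identical censoring.

## Model comparison

For each city with a non-empty empirical signature the divergence to
each model signature is computed and the smaller one wins; exact
equality is reported as a tie, never silently assigned. A model that
produces no surviving flows for a city after censoring yields no
divergence for that city; such cities are excluded from that model's
mean and from the share denominators and are counted separately in the
summary. Summaries report mean divergences per model, shares per
better-model group, within-group means, and the population lists per
group for population-versus-model plots.

## Temporal comparison

Relative differences between two periods are matched by destination
identity — `(f_a - f_b)/f_a` for destinations present in both periods —
with lost and gained destinations reported as sets. Matching by rank
instead was rejected: rank `r` may be a different destination in the
two periods, and the quantity of interest is how travel *to the same
place* changed.

Trip-distance samples weight each directed flow's distance by its trip
count (one observation per trip). The two-sample Kolmogorov–Smirnov
statistic is the supremum of the absolute difference of the two
flow-weighted empirical CDFs over the pooled support, computed without
materializing the per-trip expansion. The p-value is asymptotic — the
Kolmogorov distribution at `sqrt(n_eff) · D` with
`n_eff = n_a n_b/(n_a + n_b)` — which is appropriate for monthly OD
feeds whose trip counts run into the millions; an exact small-sample
p-value is out of scope and the D statistic itself is exact regardless.

## Synthetic data generator

The generator emulates the statistical structure of operator OD data so
that every stage is testable without proprietary inputs. Defaults are
fixed once as the reference conditions:

| parameter | default | rationale |
|---|---|---|
| cities | 310 | the municipal scale the method targets |
| extent | 1000 × 600 km | a Finland-like national rectangle |
| populations | log-normal, μ = 9, σ = 1.2 | heavy-tailed city sizes, mean ≈ 16.6k |
| kernel | gravity, β = 0.03 /km | ≈ 33 km decay, inter-municipal commuting scale |
| total trips | 3.4 M/day | national daily trip volume |
| censoring | 20 trips | operator privacy floor |
| lockdown | φ = 0.5 beyond 100 km | halves long-distance flows |

Production and attraction margins are proportional to population.
Poisson noise draws integer counts around the kernel means. All
randomness flows from one integer seed through numpy's PCG64 generator
(128-bit state) with fixed stream tags for the city system, the count
noise and the perturbation, so outputs are byte-stable across platforms
and regenerating one component does not disturb the others.

The lockdown perturbation is a sharp distance knee: flows over
distances beyond `d0` are scaled by φ, others untouched. A smooth
kernel change would also reduce long-distance travel, but the knee is
the simplest mechanism that reproduces the qualitative pattern
(shortened signatures, reduced mean trip distance, positive K-S
distance) and keeps the perturbation analytically transparent. One
consequence worth knowing: a city whose flows are *all* beyond the knee
is scaled uniformly, leaving its normalized signature and distance
distribution unchanged — the disruption is visible only where short and
long flows mix. Under censoring this is common for small remote cities;
on uncensored matrices every city mixes both and the pattern is strict.

What the generator does **not** emulate: road networks and travel-time
asymmetries, commuting schedules and weekday/weekend structure,
within-city mobility, operator market-share extrapolation, and
correlated (non-Poisson) count noise. Passing tests on synthetic data
therefore demonstrate the correctness and self-consistency of the
pipeline, not the empirical adequacy of either flow model for any real
country.

## Problem sizes used in tests

The test and acceptance runs use 310-city systems for end-to-end
classification and disruption checks, 50-city systems for
deterrence-rate recovery (≈ 400 trips per pair on average, comfortably
above the censoring floor), and 2–40-city systems for exact oracles and
property checks. These sizes match the reference scale where it matters
(one national system) and keep the exact-oracle comparisons small
enough to verify by independent brute force.

## Known limitations

* Gravity calibration assumes the exponential deterrence family; data
  generated under a different deterrence shape will calibrate to the
  best mean-distance match within the family, not a meaningful β.
* IPF convergence slows markedly for strong deterrence combined with
  highly heterogeneous margins; the budget is configurable, and
  non-convergence is always surfaced.
* The K-S p-value is asymptotic and unreliable for very small samples
  (tens of trips); the D statistic is exact.
* Period labels are opaque; calendar logic (e.g. month alignment across
  years) is the caller's responsibility.
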