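# Methods

## Model

The package forms a consensus over B base partitions of the same N
cytometry events. Each base cluster c (one cluster of one partition) is
summarised by its geometric median in the d-dimensional marker space,

    û(c) = argmin_x Σ_{x_i ∈ c} ‖x − x_i‖₂ ,

yielding an m × d median matrix, m = Σ_b k_b. Meta-clustering this matrix
partitions the pooled clusters into K consensus clusters; each consensus C
is a set of pooled clusters with similar expression profiles. Events are
then labelled by their base clusters' consensus memberships. When those
memberships conflict, the event t is scored against every candidate
consensus:

    p(C, t) = (Σ_{c ∈ C} ‖t − û(c)‖₁) / |C| ,   score(C, t) = |C| / p(C, t) ,

and takes the argmax. The score rises with the number of supporting
clusters (|C|) and falls with the mean Manhattan distance to their
medians, so a consensus wins by being both well supported and well
fitting. The candidate set of an event is the set of consensuses
containing at least one of its own base clusters, while p sums over *all*
member clusters of each candidate — including ones that did not contain
the event.

Assumptions: base partitions are meaningful views of the same events
(arbitrary cluster counts are fine; unassigned events carry the sentinel
label −1 and contribute to no pooled cluster); marker space is the
arcsinh-transformed scale on which Manhattan and Euclidean distances are
phenotypically meaningful; a consensus cluster is adequately summarised by
its member medians (cluster topology is deliberately discarded — the
method is a heuristic that trades shape information for tractability).

## Numerical choices

**Weiszfeld iteration** starts at the coordinate-wise mean (guaranteeing
the objective at the result never exceeds the mean's), stops when the
step norm falls below `tol` (default 1e−7) or after `max_iter` (500)
iterations. An iterate landing within 1e−12 of a data point switches to
the Vardi–Zhang modified update, which either certifies optimality at the
data point (subgradient condition r ≤ η) or steps off it; the plain
update is undefined there. n = 1 returns the point; n = 2 returns the
midpoint as the canonical representative of the optimal segment.
`oracle_geometric_median` (tests only) minimises the same objective with
L-BFGS-B from three starts and an explicit subgradient.

**Voting** is exactly linear algebra: for a chunk of ambiguous events,
cityblock distances to all m medians (chunk × m) are summed per consensus
via an m × K indicator, giving p and the score for every consensus at
once. p = 0 (the event coincides with every member median) scores +∞;
ties — finite or infinite — break to the smallest consensus label. Chunk
size is fixed at 4096 independent of the worker count, and chunks are
concatenated in order, so results are bit-identical for any `n_workers`.
Events unassigned by every base partition (possible with density-based
base clusterers, never produced by the built-in ensemble) fall back to
the consensus of the nearest pooled median in Manhattan distance.

**Meta-clustering** delegates to scikit-learn. Ward linkage requires the
Euclidean metric; other linkages receive a precomputed distance matrix so
manhattan/cosine/correlation metrics are available. Affinity propagation
and mean shift determine K themselves. The median matrix is clustered on
its raw (transformed-marker) scale by default; `scale="zscore"`
standardises columns first, off by default because markers on the arcsinh
scale are already commensurate and per-column scaling can inflate
uninformative markers.

**k selection** resamples `ceil(0.8·m)` median rows 100 times per
candidate k, reclusters each resample, and accumulates the co-clustering
proportion among co-sampled pairs. PAC — the fraction of off-diagonal
consensus entries strictly inside (0.1, 0.9) — is minimised, ties to the
smaller k. The resample reclusterer is k-means with a *single* fresh
k-means++ initialisation per resample: at the wrong k the forced merges
or splits vary between initialisations, which is precisely the
instability PAC measures. A deterministic reclusterer (agglomerative is
available as an option) draws instability only from row subsampling and
yields PAC = 0 for every k ≤ the true group count on separated medians,
making the minimum uninformative. Note the median matrix can carry real
sub-cluster structure: base runs that over-split contribute stable
within-cloud median groups, and PAC will legitimately report the finer
resolution. The k-selection experiments therefore use base runs at the
cloud resolution.

## Preprocessing

arcsinh(x / cofactor) with cofactor 5 (mass cytometry) or 150
(fluorescence flow) as conventional defaults; the transform is applied
only when requested, since public benchmark tables are often already
transformed. Down-sampling to a cap (default 300 000 events, the
conventional working-set ceiling) is uniform without replacement with an
explicit seed; stratified sampling is deliberately not the default.
FCS reading supports 3.0/3.1 list-mode float/double/integer data;
compensation and gating are upstream concerns and never applied.

## Synthetic benchmark

`make_blobs` draws `n_clusters` (default 10) cloud centres uniformly in a
hypercube of side `center_spread` (default 10) in `n_dims` (default 15)
dimensions and places isotropic Gaussian events at them with standard
deviation `sd`; per-cloud counts follow the weight vector by
largest-remainder apportionment, so they always sum to `n_events`
exactly. With the default geometry the typical centre separation is
≈ 15 units: `sd = 1` gives essentially disjoint clouds, and the grid
{1, 2, 3, 4} sweeps from negligible to substantial overlap — the spread
values are a package convention for that sweep, not measured constants.
`add_rare_population` appends a small Gaussian population (≤ 5% of
events) at a chosen offset, emulating rare subsets (pDCs, MAIT cells)
that are the hard case for consensus methods. `builtin_base_partitions`
provides k-means runs at mixed k as a stand-in ensemble.

What the generator does *not* emulate: marker-specific cytometry
distributions (zero inflation, spillover, batch effects), non-convex or
branching population topology, and correlated noise. Passing tests on
these benchmarks therefore demonstrate the algebra and the pipeline
behave as specified — recovery of well-separated mixtures, graceful
degradation with overlap — not clustering performance on real cytometry
data.

## Problem sizes used in the shipped experiments

The test suite and `scripts/acceptance.py` run the spread-grid recovery
experiment at n = 50 000 events (10 clouds, d = 15, four k-means base
runs at k ∈ {8, 10, 12, 15}, meta-k = 10), k selection on 20 seeded
datasets of n = 2000 (5 clouds, four base runs at k = 5), co-association
agreement at n = 3000 (the exact consensus is quadratic in N and capped
at 5000), and the scaling grid at n ∈ {10 000, 50 000}; `scaling_suite`
itself accepts arbitrary sizes for larger runs.

## Known limitations

- A geometric median says nothing about cluster shape; consensus clusters
  can misrepresent non-convex populations.
- |C| counts member clusters, not distinct supporting algorithms: one
  base run contributing several clusters to a consensus raises its vote
  weight accordingly. This literal reading is implemented and documented
  because candidate sets and |C| interact; an algorithm-level count is a
  possible variant.
- Rare populations survive the consensus only if at least some base runs
  isolate them; the vote cannot recover a population no input resolved.
- PAC-based k selection inherits the resolution of the base ensemble (see
  above) and, like all consensus-resampling criteria, is a heuristic —
  inspect the per-k statistics and the median-matrix heatmap rather than
  trusting the argmin blindly.
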