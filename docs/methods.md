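# Methods

This note records the models, estimators, parameter choices and known
limitations of the package, in the spirit of a statistical software
methods appendix. Empirical claims below are limited to what the test
suite and `scripts/acceptance.py` themselves compute.

## Graph construction

Per subject, ROI time-series are pairwise Pearson-correlated. The unit
diagonal is zeroed (it would otherwise encode a self-loop on every node),
and zero-variance ROI columns must be removed first (`drop_dead_rois`):
Pearson correlation is undefined for any constant series, so the dead-ROI
criterion is zero variance, not merely an all-zero signal.

Thresholding keeps exactly `floor((1 − q/100) · E)` of the
`E = R(R−1)/2` upper-triangle entries at percentile `q` (default 95), by
**exact rank selection** rather than an interpolated quantile cut: the
edge count is then deterministic, and the two differ only at ties, which
are broken by stable `(i, j)` index order for reproducibility.
Correlations are ranked **signed** — an explicit negative-discard rule
applied *after* rank selection removes any retained negative entries, so
the rule's order of operations is: rank, cut, then drop negatives.
Thresholding is per subject (each matrix cut on its own distribution);
pooled thresholding across subjects is deliberately not offered.

## Network fractal dimension (Compact Box Burning)

A box at size `l_B` is a node set with all pairwise hop distances
`< l_B`; distances are unweighted BFS hop counts and cross-component
distance is infinite, so a box never spans components. CBB builds one box
at a time: candidates start as all uncovered nodes; a candidate is drawn
uniformly at random, added, and the candidate set is intersected with the
added node's `< l_B` ball; the box closes when candidates run out.

* **Restarts** — CBB is stochastic and only upper-bounds the covering
  number; we take the minimum over 10 restarts by default (box-covering
  practice), with per-`(l_B, restart)` RNG substreams derived by counter
  from one master seed, making results order-independent.
* **Monotonization** — true covering numbers are non-increasing in
  `l_B`; the estimated series is forced monotone by a running minimum.
* **Regression** — `d_B = −slope` of OLS of `ln N_B` on `ln l_B` over
  the full integer range 1..10, *including* any trailing `N_B = 1`
  plateau. The plateau depresses the slope on small-diameter graphs; a
  `drop_plateau` flag exposes the sensitivity but the full range is the
  default and the convention used everywhere in this package. A warning
  is emitted when the graph diameter + 1 is below `l_max`.
* **Validation** — an exhaustive oracle (`exact_covering_number`,
  ≤ 12 nodes) computes the true minimum as the chromatic number of the
  distance-`≥ l_B` conflict graph; CBB with 50 restarts matches it on an
  enumerated family of small graphs. Analytic anchors: edgeless graphs
  give `d_B = 0`; the complete graph `K_1000` gives the closed-form OLS
  value ≈ 2.158; a `(2,2)`-flower at 6 generations (2 732 nodes) recovers
  its analytic dimension 2.0 within 25% (finite-size effects dominate the
  gap; box-counting dimensions converge very slowly in system size).

## Adjacency-matrix (2-D box-counting) dimension

The adjacency matrix is rendered one pixel per entry, unscaled, and
stored **losslessly** (PNG/PGM). Box sizes default to powers of 2 from 2
up to `floor(min(W,H)/4)`, scanned from 4 grid origins (the four
corners); partial boxes at the edges count. For each origin and each
consecutive size pair the instantaneous slope `−Δln N/Δln ε` is computed;
the minimum and maximum slopes over origins and pairs bound the
dimension and their mean is the reported scalar, with per-origin OLS
slopes kept for diagnostics. On exactly self-similar fixtures with
aligned grids (Sierpiński carpet at 243², sizes `3^k`) the bounds
coincide with the analytic dimension `ln 8 / ln 3`.

## Higuchi temporal fractal dimension

The estimator uses all integer intervals `k = 1..k_max` (not the original
log-spaced subsampling), matching the commonly used reference
implementations; `k_max = 64` by default, and results on fBm fixtures are
stable within ±0.05 between `k_max` 32 and 64. Curve lengths include the
`(N−1)/(⌊(N−m)/k⌋ k)` normalization and the final `1/k`; `k` values whose
worst offset has no complete step are dropped with a warning, and
constant signals raise a degenerate-signal error rather than returning a
number. The per-subject scalar is the **mean over ROIs** (the per-ROI
table is always available for other reductions). A Hilbert-envelope
preprocessing step (`analytic_signal_magnitude`) is provided but **off by
default**: envelope, phase and analytic-real-part readings are all
plausible for BOLD pipelines and the package does not privilege one. A
`truncate_series` control supports equalizing scan lengths across groups
before comparison.

## Null models

"Lattice" is implemented as the circulant k-nearest-neighbour ring with
`k = 2D` for embedding dimension `D` (a rectangular grid generator is
available as an alternative reading of a 2-D lattice). Random nulls are
uniform `G(n, m)` graphs with `m` matched to the mean empirical edge
count, 50 replicates by default, each analyzed with an independent seed
substream. Replicate dimensions at fixed `(n, m)` concentrate tightly
(IQR well under 10% of the median), so the random-null summary is stable.

## Group statistics

Kruskal–Wallis (tie-corrected, chi-squared approximation), pairwise
Mann–Whitney U reported as `min(U_ab, U_ba)` — the convention under which
a fully separated pair yields `U = 0` — with the exact distribution when
both groups have `n ≤ 20` and no ties, and the tie-corrected normal
approximation otherwise. Benjamini–Hochberg at `q = 0.05` is applied
across the family of all pairwise tests *within one measure*, the
narrowest defensible family. Quartiles use linear interpolation; medians
of odd-sized groups are exact order statistics regardless of convention.
Statistical kernels are delegated to scipy/statsmodels; the test suite
validates them against exhaustive permutation enumeration at small N
rather than against another library call.

## Synthetic cohort: what it does and does not emulate

The cohort generator samples multivariate-normal time points from a
hierarchical-modular correlation matrix: ROIs are leaves of a binary tree
(branching 2, 8 levels, 256 ROIs), and the correlation of two ROIs is
`w^(1 + depth · effect)` where `depth` is the number of levels to their
lowest common module, `w = 0.5` is the within-module correlation, and
`effect ∈ (0, 1]` is the per-group scalar. The construction is an
ultrametric nested-block matrix and is PSD by construction; a
clip-and-renormalize repair guards the general case. An AR(1) filter
(coefficient 0.3) adds mild temporal autocorrelation. All subject draws
descend from one seed by counter-derived substreams.

The group effect scales how sharply correlation decays with modular
depth — how *differentiated* the hierarchy is. At `effect = 1` signals
are strongly differentiated across modules and the top-5% graph mixes
modular structure with long-range edges; as the effect shrinks the
correlation profile flattens toward undifferentiated global synchrony,
whose thresholded graphs are hub-dominated and yield a lower `d_B` under
the 1..10 log–log fit. With the frozen defaults (effects 1.0/0.6/0.3,
groups of 15/10/8, 150 time points) the median network dimension follows
the effect ordering and the omnibus test rejects in 20/20 seeded
replicates of the acceptance check. These defaults were calibrated once
against the package's own pipeline and then frozen.

What the generator does **not** emulate, and what passing tests therefore
do not show about real data:

* No haemodynamics, scanner noise spectra, or motion; the signals are
  near-white after mild AR(1) smoothing, so their Higuchi dimension sits
  close to 2 in all groups with negligible group separation. Group
  effects on temporal roughness are exercised through fBm fixtures
  instead, where the `D = 2 − H` law provides the oracle.
* The network and adjacency-image dimensions **anticorrelate** on this
  synthetic family (hub-dominated degraded graphs concentrate pixels into
  full rows/columns, which raises the 2-D box count at large scales).
  On real cortical data the two measures have been reported to correlate
  positively; that behaviour depends on properties of real connectivity
  this generator does not reproduce, and no test asserts the sign on
  synthetic cohorts.
* No atlas geometry: ROI order is tree order, so adjacency images are
  block-diagonal rather than anatomically interleaved.

## Numerical and degenerate-input conventions

* Threshold ties: stable index order. CBB draws: counter-derived
  substreams below 2³¹. OLS: `scipy.stats.linregress` throughout; a
  constant `ln N_B` series short-circuits to slope 0 (edgeless graphs).
* PSD repair tolerance 0.1 on any single correlation entry; exceeding it
  is an error, not a silent fix.
* fBm: Davies–Harte circulant embedding; a non-PSD embedding (not
  observed for `H ∈ (0,1)` at the sizes used) clips eigenvalues with a
  warning rather than failing.
* Empty-edge graphs after thresholding warn and return an empty edge set;
  an empty *input* (no ROIs alive, empty file) is an error.
* `exact_covering_number` refuses graphs above 12 nodes; the backtracking
  colouring is exponential and is a test oracle, not a production path.

## Problem sizes

The validation suite uses 256-ROI cohorts (33 subjects), 2 732-node
flower graphs, 1000-node complete/null graphs, 243² images, and 2¹⁴-point
signals; these sizes keep the full suite and the acceptance script in the
minutes range on a single core while leaving every estimator in its
asymptotic regime (the flower's 25% tolerance is the one place finite
size visibly bites).
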