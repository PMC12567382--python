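# Methods

This note records the models, conventions and numerical choices behind
each stage, what the synthetic generator does and does not emulate, and
the known limitations.

## Climate predictors

Monthly climatologies (means over years; any month without observations is
an error naming the month) are summarised per cell and variable by the
first-order harmonic y_m = a0 + a1·cos(2πm/12) + b1·sin(2πm/12) at integer
month positions m = 1..12. Over a full cycle this basis is orthogonal, so
the least-squares solution is the closed-form projection a0 = mean(y),
a1 = (1/6)Σ y_m cos, b1 = (1/6)Σ y_m sin; no iterative solver is involved.
"Three coefficients" means intercept plus the annual cosine and sine
terms — the minimal harmonic model yielding exactly three coefficients per
variable, hence nine predictors for tmax (°C), tmin (°C) and vpd (kPa).
Fitting once on the multi-year climatology and averaging per-year fits are
identical under this orthogonality with balanced data; we fit on the
climatology. Cells with any missing month are masked in all nine layers.
Two exact consequences are used as test invariants: adding a constant to
all months shifts only a0, and advancing the series by k months rotates
(a1, b1) clockwise by 2πk/12 while preserving the amplitude.

## Ensemble distribution models

Pseudo-absences are drawn uniformly, without replacement, from valid cells
holding no presence record of the taxon, one per presence record (so
presence and pseudo-absence counts match and no cell carries both labels).
Records are split 70/30 into train/test, stratified by label, with
round(0.7·n) training rows per label.

The three learners share one contract — a 9-vector of predictors to a
probability-scale score in [0,1] — and deliberately differ in inductive
bias:

* **smooth_additive**: per-predictor cubic-spline basis (default 5 knots)
  with a logistic link; iterative fit capped at 500 iterations, tolerance
  1e-8.
* **adaptive_hinge**: logistic regression on a two-sided hinge basis
  max(x−t, 0), max(t−x, 0) at the 25th/50th/75th percentile knots of each
  standardized predictor.
* **kernel_margin**: RBF support-vector classifier whose decision values
  are calibrated to [0,1] by a logistic link fitted on 3-fold
  cross-validated decision values.

No equivalence with any particular GAM/MARS/SVM implementation is claimed;
the acceptance standard is virtual-species recovery, not coefficient
matching. Members with test-set Cohen's κ below 0.4 (the conventional
"moderate agreement" floor) are dropped; retained members are averaged
with weights proportional to κ. Both the floor and the weighting are
configurable. Binarization picks the threshold maximizing
TSS = sensitivity + specificity − 1 over midpoints of the sorted unique
test scores, ties resolved toward the lower threshold. κ is computed as
(p_o − p_e)/(1 − p_e) with p_e from the marginal products; a table with
p_e = 1 yields κ = NaN. Abiotic suitability of an ecosystem for a taxon is
100 × the mean continuous ensemble suitability over the ecosystem's cells.

## Niche space and overlap

A single PCA — centered, unit-variance, fitted on the predictor vectors of
*all* grid cells — defines the common climate space; taxa are projected
into it so cross-taxon overlap is meaningful. Axis signs are fixed by
making the largest-magnitude loading positive; zero-variance columns are
dropped with a warning. Hulls are built on the first two components (the
planar convex-polygon setting); overlap in more dimensions would require
hypervolume intersection and is out of scope.

A taxon's niche points in an ecosystem are, by default, the cells
predicted present by its binary map that lie in the ecosystem
(`taxon_niche_points`); `occurrence_niche_points` switches to the raw
record cells. Hull areas use the shoelace formula (scipy's Qhull supplies
the counter-clockwise vertices); intersections use exact convex polygon
clipping (shapely), and the Jaccard percentage 100·|∩|/|∪| is computed
with both areas from the same polygon backend so identical hulls score
exactly 100. Degenerate hulls (fewer than three points, or collinear)
score 0 overlap and are flagged; a cell of the overlap matrix is
*undefined* (excluded from every average) when either taxon's hull in that
ecosystem is degenerate. Biotic suitability of a tick is the mean of its
defined row entries. Optional outlier trimming is deliberately absent:
convex hulls are outlier-sensitive, and silently trimming would change the
estimand.

## Phylogenetic diversity and signal

Faith's PD of a host set is the branch-length sum of the minimal spanning
subtree rooted at the set's most recent common ancestor; the path from the
MRCA to the tree root is excluded and a single host has PD 0, making PD a
pure among-host diversity measure that is monotone under host addition.
An `include_root` switch serves the other convention. Host sets per tick ×
ecosystem are the hosts with defined overlap cells in that ecosystem's
matrix row.

Pagel's λ multiplies the off-diagonal entries of the Brownian-motion
covariance matrix (shared root-to-MRCA path lengths) while preserving the
diagonal. The trait mean and rate σ² are profiled out in closed form; λ is
found by bounded scalar minimization on [0,1] (tolerance 1e-6) with the
boundary values checked explicitly. Constant traits and star trees are
rejected as unidentifiable. In the pipeline λ is computed on the per-host
overlap trait when a tick has at least four defined hosts, and reported as
NaN otherwise.

## Network structure

Networks are directed tick→host graphs with an edge wherever the defined
overlap exceeds a threshold (default 0); isolated nodes are retained.
NODF follows the paired-overlap definition: for each ordered pair of rows
(and of columns) with *strictly* decreasing marginal totals, the paired
term is the percentage of the sparser line's interactions present in the
denser line; equal totals contribute 0, and NODF is the mean over all row
and column pairs (equivalent to pre-sorting by decreasing totals and
invariant to input permutations). The weighted variant (WNODF) orders
lines by fill and additionally requires the sparser line's weights to be
strictly smaller cell-wise, so uniform weights score 0.

Barber's bipartite modularity Q = (1/m)Σ(A_ij − k_i d_j/m)δ(g_i, g_j) is
maximized by label propagation: random initial modules, nodes moved to the
module maximizing their modularity contribution in fixed order with
lowest-label tie-breaks, best of (default) 20 seeded restarts.
Reproducibility is preferred over global optimality; exhaustive search
verifies optimality on small networks in the tests.

Significance of a network metric comes from the proportional-fill null:
cell probabilities p_ij = (r_i/C + c_j/R)/2, p-values with the add-one
correction (1 + #{null ≥ obs})/(n_null + 1) so p ≥ 1/(n_null+1) always.
By default p_ij is estimated from the observed margins (plug-in). A known
limitation: margin-estimation noise inflates null nestedness, making the
plug-in test conservative; `null_significance` therefore also accepts
externally specified probabilities, under which the Monte-Carlo p-value is
exactly uniform — the calibration experiment uses that fully specified
form. For weighted metrics each null fills its cells by resampling the
observed positive weights with replacement. The Mantel test correlates
upper-triangle entries and permutes rows and columns of the second matrix
simultaneously (two-sided by default); an exact mode enumerates all n!
relabelings for small n. A "Mantel significance of nestedness" is not a
well-posed operation on a scalar, so the package provides the null-model
z/p for nestedness and the true Mantel test for matrix-vs-matrix
questions, as two separately named tools.

## Ordination

Each (tick, ecosystem) item carries its profile of Jaccard overlaps over
the union host set (undefined hosts as 0). The default distance is the
Euclidean profile distance divided by √n_hosts, a bounded complement of
similarity with antipodal profiles exactly 100 apart; a reciprocal
transform (100/(1+s)) is available but unbounded behaviour near zero
overlap makes the complement the default. Non-metric MDS is Kruskal-style
SMACOF: disparities by isotonic regression on the dissimilarity rank
order, configuration updates by the Guttman transform, a classical-MDS
first start plus random restarts (default 8), and a relative
stress-decrement stopping rule (1e-6, max 300 iterations) so exactly
embeddable inputs anneal toward zero stress. Reported misfit is Kruskal
stress-1; values below 0.05 are flagged reliable (strict inequality). The
companion grouping test is PERMANOVA on the distance matrix — a documented
stand-in diagnostic, not a reproduction of any published test.

## Synthetic study systems

The generator emulates: seasonal climate as per-variable annual harmonics
whose coefficients vary along a latitudinal gradient (anchor values
loosely follow a Mediterranean-to-boreal transect), with additive i.i.d.
Gaussian noise defaulting to 5% of the local seasonal amplitude — small
enough that harmonic recovery is testable; ecosystem zonation as
latitudinal bands or k-means climate clusters; virtual taxa with Gaussian
(bell-shaped) suitability in the 9-D predictor space — the virtual-species
standard, making true niches ellipsoidal and overlap controllable;
occurrence records drawn over cells with replacement, proportional to
suitability (repeat records at one locality occur in real tick data);
Yule host phylogenies; and tip traits under λ-transformed Brownian motion.
Ground truth for overlap takes each taxon's suitability level set at half
its maximum, projects it to the common 2-PC space and applies the same
hull/Jaccard machinery, so identical niches score exactly 100 and overlap
decays with niche separation.

It does **not** emulate: real geography or projections, spatial
autocorrelation in sampling effort, observation bias, temporal dynamics,
or dispersal limitation. Passing recovery tests therefore demonstrates
statistical correctness of the pipeline under idealized sampling, not
robustness to the biases of real occurrence data.

One global seed expands to per-stage seeds as the first four bytes of
SHA-256("{seed}:{stage}") modulo 2³¹, so stages are independently
reproducible and runs are deterministic end to end.

## Problem sizes

Default experiment sizes are chosen to be informative on one CPU in
seconds to a few minutes: SDM recovery on a 50×50 grid with 300 presences;
the overlap sweep on 40×40 with 500 records per taxon and six separations;
λ recovery with 100 tips × 20 replicates; calibration with 500 simulations
of 8×10 matrices (99 nulls each) and 7-object Mantel tests (99
permutations); the full pipeline demo on 30×30 with 3 ticks, 8 hosts and
3 ecosystems.

## Known limitations

* The plug-in proportional null is conservative for nestedness (see
  above); fully specified probabilities restore exact uniformity.
* Learners are calibrated to presence-versus-background probability, so
  ensemble scores are monotone in, but not equal to, true suitability;
  comparisons against truth use rank-preserving constructs (correlation,
  matched max-TSS thresholds) rather than raw values.
* Hull-based niches ignore density: a single outlying presence cell can
  enlarge a hull; no trimming is applied by default.
* Label propagation may miss the global modularity optimum on larger
  networks; restarts mitigate but do not eliminate this.
* NMDS convergence is to a local stress minimum; restarts (including a
  classical-MDS start) mitigate but do not guarantee globality.
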