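# Methods

This note documents the models, conventions and numerical choices behind
`traversal`, and what its synthetic tests do and do not establish about
real prediction trajectories.

## Inputs and conventions

Residues are indexed 0-based and contiguously by order of appearance in
the PDB file; author residue numbers are metadata only, so numbering gaps
never reach the math. Only Cα coordinates are used. Torsion angles are
degrees in (−180, 180]; ω is carried although it is near-constant,
because moves replace the full (φ, ψ, ω) triplet. The undefined φ of the
first residue and ψ of the last are an explicit `NA` sentinel and are
masked on *both* sides of any triplet comparison.

Two triplets are identical iff all unmasked components agree after
rounding to 0.001° - the precision of the fragment text format - which
prevents float noise from inflating "unique triplet" counts. The
trajectory-log schema (versioned TSV, one line per accepted move with the
affected residues' triplets, `S` lines for snapshot references) is defined
by this package; readers validate monotone move indices, window bounds
and angle ranges, and never drop data lines silently.

## Contact maps and dissimilarity

A pair (i, j), i < j, is a contact iff its Cα distance is ≤ the cutoff
(default 8 Å; the boundary convention is `≤` and configurable). No
minimum sequence separation is imposed: near-diagonal contacts are
essentially constant along a chain, so they cancel in Hamming differences
(the suite checks they contribute ≤ 5% of the distance between snapshots
of the same chain). Distances are exact integer bit counts throughout -
never floats - and satisfy the metric axioms, which the suite verifies
wholesale on synthetic sets.

## Classical MDS

Torgerson scaling: eigendecompose B = −½ J D² J, take the top-m
eigenvectors scaled by √λ. Hamming matrices need not be
Euclidean-embeddable, so negative eigenvalues occur; they are excluded
from the variance denominator and the most negative eigenvalue is
reported as a diagnostic, which is common Torgerson practice. Axes with
nonpositive eigenvalues among the top m become zero columns. Eigenvector
sign is fixed by making each axis's largest-magnitude entry positive, so
plots reproduce bit-for-bit. The captured-variance fraction is always
reported and tends to be small for contact-map data; embeddings are for
orientation, the entropy measure below works in the full-dimensional
dissimilarity space precisely to avoid relying on the projection.

## PAM, state assignment, MSM

PAM is used so every cluster center is an actual sampled structure
(averaging conformations can produce physically impossible ones). The
implementation is the classic BUILD (greedy cost-minimizing seeding) plus
best-improvement SWAP, with all ties broken toward the lowest index -
deterministic given the matrix and k. Swap local search reaches the
exhaustive optimum on cluster-structured data (verified against full
enumeration at small n), which is the geometry the pipeline feeds it; on
structureless clouds only swap-local optimality is guaranteed - a known
property of k-medoids local search, shared by the reference
implementations.

k is chosen by maximal mean silhouette width (default search range 5-25,
clipped to n−1); the full silhouette table is returned so the choice can
be audited. The clustering pool defaults to trajectories plus decoy
background; assigning trajectory snapshots post hoc to decoy-only
clusters is equally supported (nearest medoid by Hamming distance, ties
to the lowest medoid index).

MSM counts pool consecutive snapshot pairs within runs only - never
across run boundaries. Self-transitions are retained: confinement shows
up as a high-probability, zero-weight self-loop, which is exactly what
drives its entropy to 0.

## Weighted entropy and its normalization

The transition weight w_ij is the Hamming distance between medoids i and
j rescaled so the largest pair is 1 (zero diagonal by the metric
identity; an all-zero weight set, e.g. k = 1, is a degenerate-input
error). The raw score is the occupancy-averaged, pairwise-weighted row
entropy

    H_raw = Σᵢ πᵢ Σⱼ w_ij (−P_ij ln P_ij),   0·ln 0 = 0,

in nats (the base cancels in normalization), with probabilities below
1e−12 treated as exact zeros. This Guiaşu-style weighted form is adopted
as the one standard formulation consistent with three requirements at
once: weighting by the structural difference of each transition,
normalization "for the given number of clusters and set of weights", and
a score of 0 for deterministic or confined trajectories.

H_max is the true maximum of the weighted row entropy over the
probability simplex. On positive-weight entries the maximizer satisfies
p_j = exp(−1 − λ/w_j); surplus mass parks on zero-weight entries (where
it contributes nothing), and λ is solved by bracketed Brent root-finding
(xtol 1e−14). Closed-form checks: equal weights over m entries give
ln m; a single positive weight w with slack gives w/e. Because occupancy
is free at the maximum and the objective is linear in it, H_max is the
best single row's maximum. Normalizing by a true maximum guarantees
0 ≤ H_norm ≤ 1 for *every* model (property-tested over random MSMs and
weight matrices).

One consequence deserves emphasis: since the self-transition carries zero
weight, the maximal-uncertainty distribution is uniform over the k−1
structurally distinct successors, not over all k states. A walk that
spends 1/k of each row on itself scores (k−1)ln k / (k ln(k−1)) < 1
(≈ 0.929 at k = 5) - self-transitions genuinely dilute exploration. The
suite asserts both facts: the uniform distinct-successor walk (realized
exactly by an Eulerian tour of the complete digraph) scores 1, and the
uniform-including-self walk scores strictly less.

## Mack-Skillings block statistics

Entropy comparisons across protocols form a complete block design
(targets × protocols × c replicate runs). Observations are mid-ranked
within each block; the omnibus statistic is the quadratic form
(S − E)ᵀ V⁻ (S − E) on the treatment rank-sum vector, where V is the
exact within-block permutation covariance of rank sums given the
realized ranks. With no ties this reduces algebraically to the textbook
closed form (unit-tested); with ties the mid-rank variance enters V
automatically. The asymptotic reference is χ² with k−1 degrees of
freedom. An exact enumeration over within-block assignments is used
automatically when it needs at most 200 000 assignments, with a
Monte-Carlo permutation p-value (and standard error) available at any
size. The asymptotic tail is well calibrated at realistic sizes (null
rejection rate at α = 0.05 verified within [0.035, 0.065] over 2000
simulated 10-block tables) but should not be expected to match exact
p-values to Monte-Carlo precision at 2 blocks, where the permutation
distribution has only ~8100 atoms.

Post-hoc all-pairs comparisons use the large-sample Tukey-type rule
|S_u − S_v| ≥ q_{α,k,∞} √(Var(S_u − S_v)/2) with the same tie-corrected
covariance, controlling the experimentwise error at α (default 0.05);
for k = 2 the decision coincides exactly with the omnibus test.

## Synthetic data: what it emulates, what it does not

`gen_chain` produces self-avoiding random walks with 3.8 Å virtual bonds
and a compactness bias toward the centroid - protein-*plausible* distance
geometry, not physical energetics. Basin trajectories are hidden-Markov
emissions: a state sequence over b prototype contact patterns (built
from compact chains, so basin geometry is realistic) with i.i.d. pair
flips at a noise rate validated to stay well below basin separation
(prototype distances must exceed 5× the expected flips). Move logs draw
windows by region-biased target residues and either fresh archetype
triplets (helix/strand/coil φ/ψ distributions) or whole fragments from a
generated library; the generator records exact per-residue change counts
and used-triplet sets as oracles. None of this emulates Rosetta's actual
acceptance statistics, fragment quality profiles, or energy landscapes -
passing tests establish the *measures* behave correctly (metric axioms,
recovery of planted structure, ordering of planted regimes), not that
any particular predictor explores well on real targets.

Default study conditions used by the deeper tests, chosen once: 5 basins
over 40-residue chains, 40 background emissions per basin, flip noise
0.01, 400-snapshot trajectories, 10 seeds for ordering claims
(confined < noisy < explorative required in ≥ 9/10); MSM recovery uses
10 runs × 500 steps against a known transition matrix at 0.05 sup-norm;
null calibration uses 2000 tables of 10 blocks × 3 treatments × 8
replicates. These sizes keep the full suite around 15 seconds while
leaving estimator noise far from the asserted margins.

## Known limitations

* All-atom detail, mmCIF and multi-chain targets are out of scope; the
  structure reader is single-chain, first-model, CA-only.
* The fragment reader accepts one header-keyword dialect of the fragment
  text format and fails loudly on others.
* PAM guarantees global optimality only on cluster-structured inputs;
  on structureless data it guarantees a swap-local optimum.
* The entropy measure conditions on the cluster partition; a poor k or a
  background that misses visited regions will distort it. The silhouette
  table and the weight summary are exposed so this can be checked.
* Low MDS variance fractions are expected, not a defect; treat the plots
  as indicative.
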