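# traversal

Exploration metrics for fragment-assembly protein structure prediction.

Fragment-assembly predictors (Rosetta-style Monte-Carlo fragment
insertion, distribution-guided variants, ...) are usually judged by the
quality of their final models. That confounds three things - the energy
function, the fragment library and the *search* itself - and says nothing
about whether a run actually explored a range of plausible folds or
quietly stagnated while its score kept fluctuating. `traversal` implements
trajectory-level measures that isolate the search component, assessed
relative to the space the fragment library actually makes available:

* **Local (per-residue) measures** - how often accepted moves change each
  residue's backbone torsion triplet (φ, ψ, ω) per search stage, and what
  fraction of the unique triplets available at that position (from every
  fragment insertion that can touch it) was used at least once.
* **Global (fold-level) measures** - snapshots are reduced to binary Cα
  contact maps (8 Å cutoff); dissimilarity is the Hamming distance
  *d*(A, B) = #{pairs i<j in different contact states}, which is a metric.
  On top of that:
  * classical (Torgerson) MDS for visualizing a trajectory against a
    background of low-resolution decoys, with the captured-variance
    fraction always reported;
  * PAM (k-medoids) clustering of the pooled snapshot/decoy set, cluster
    assignment of each time-ordered trajectory, and a Markov state model
    of the visits;
  * a structurally weighted, normalized Shannon entropy of that MSM,

    H_raw = Σᵢ πᵢ Σⱼ w_ij (−P_ij ln P_ij),  H_norm = H_raw / H_max ∈ [0, 1],

    where w_ij is the Hamming distance between the medoids of clusters i
    and j (rescaled to max 1, zero diagonal) and H_max is the theoretical
    maximum of the weighted row entropy over the probability simplex for
    the given number of clusters and weight set. H_norm is 1 for a
    maximally uncertain walk over structurally distinct states and 0 for
    deterministic cycling or confinement.
* **Replicated-block statistics** - the Mack–Skillings rank test (with
  exact/permutation options and Tukey-type post-hoc pairs) for comparing
  protocols' entropy distributions across targets in a complete block
  design (targets × protocols × replicates).
* **Synthetic generators** - seeded, oracle-carrying generators for every
  input class (toy CA chains, basin-structured trajectories, move logs,
  fragment libraries, block tables), so the whole pipeline is testable
  offline.

## Worked example

Five contact-pattern basins over a 40-residue chain, a 200-decoy
background, and one 400-snapshot trajectory per exploration regime:

```python
import numpy as np
from traversal import synthgen
from traversal.cluster_msm import pam, assign_states, build_msm, choose_k
from traversal.contactspace import maps_distance_matrix
from traversal.mds_embed import classical_mds
from traversal.wentropy import medoid_weights, weighted_entropy

protos = synthgen.make_prototypes(L=40, b=5, seed=7)
background = synthgen.gen_background_maps(protos, per_basin=40, flip_noise=0.01, seed=7)
dm = maps_distance_matrix(background)
k, _ = choose_k(dm, 2, 8)
print("chosen k:", k)
clustering = pam(dm, k)
w = medoid_weights(clustering, dm)
print(f"variance captured by 2 axes: {classical_mds(dm, 2).variance_fraction:.4f}")
for regime in synthgen.REGIMES:
    spec = synthgen.BasinSpec(
        prototypes=protos,
        T=synthgen.regime_transition_matrix(regime, 5),
        flip_noise=0.01, steps=400, seed=7,
    )
    maps, _ = synthgen.gen_trajectory(spec)
    seq = assign_states(maps, clustering, background, run_id=regime)
    res = weighted_entropy(build_msm([seq], k), w)
    print(f"{regime:12s} H_norm = {res.H_norm:.3f}  "
          f"(H_raw {res.H_raw:.3f} / H_max {res.H_max:.3f})")
```

Output:

```
chosen k: 5
variance captured by 2 axes: 0.5866
confined     H_norm = 0.228  (H_raw 0.297 / H_max 1.298)
noisy        H_norm = 0.677  (H_raw 0.879 / H_max 1.298)
explorative  H_norm = 0.896  (H_raw 1.163 / H_max 1.298)
```

Silhouette-based selection recovers the five planted basins; the entropy
score then orders the three regimes exactly as their hidden transition
matrices dictate: a trajectory stuck in one basin (high self-transition
probability, zero-weight) scores low, a half-deterministic walk sits in
the middle, and a uniform walk over distinct basins approaches 1. The
2-axis variance fraction is printed because contact-map Hamming matrices
are generally not Euclidean-embeddable and the MDS picture is indicative
only.

A `traversal` command-line tool mirrors the library
(`synth`, `ingest`, `distmat`, `local`, `mds`, `msm`, `entropy`,
`compare`); run `traversal --help`.

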