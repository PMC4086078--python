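# Methods

## Problem setting

Given `n_d` drugs and `n_p` proteins, a partially known interaction
matrix `Y ∈ {0,1}^{n_d × n_p}`, and one or more similarity views per
side, the task is to score every drug–protein pair so that true but
unrecorded interactions rank high. Unknown pairs are treated as
negatives (label 0) during training, the standard convention in this
literature; no negative subsampling is performed. All algorithms consume
only the two side kernels, so any data that can be expressed as a
similarity is admissible.

## Kernels and integration

Profile views are converted by one of four kernel functions — linear
(the default), Gaussian RBF (`γ` defaulting to the median heuristic
`1/median(‖xᵢ−xⱼ‖²)`), Tanimoto for binary fingerprints, and Pearson
correlation. The default pipeline for a profile is
*kernel → cosine normalization → PSD repair*; user-supplied similarity
matrices get PSD repair only, since e.g. raw sequence-similarity scores
need not be positive semidefinite. PSD repair clips negative
eigenvalues at 0 and reconstructs, the Frobenius-nearest PSD matrix.

Integration forms `K* = Σᵢ wᵢ Kᵢ` per side. Weights are normalized to
sum to one before combining (equal weights therefore give the mean), so
the integrated kernel keeps the unit-diagonal scale of its normalized
members and the effective ridge penalty does not depend on the number
of views; the literal raw sum is available via `normalize_weights=False`
(`--raw-sum`). Views covering different object subsets are aligned to
their id intersection, with dropped ids reported — integration over
mismatched universes is refused rather than silently padded.

Tanimoto self-similarity of an all-zero fingerprint is defined as 1
(cross-similarity 0), avoiding 0/0 while keeping the matrix a valid
kernel; a warning is emitted because an empty fingerprint usually
signals an upstream data problem.

## Pairwise kernel regression (PKR)

Kernel ridge regression over pairs with the product pair kernel.
With eigendecompositions `Kd = U_d D_d U_dᵀ`, `Kp = U_p D_p U_pᵀ`, the
dual coefficients of `(Kd ⊗ Kp + λI) a = vec(Y)` (pairs ordered
drug-major) form the matrix

    C = U_d [ G ∘ (U_dᵀ Y U_p) ] U_pᵀ,   G_ij = 1/(D_d[i]·D_p[j] + λ),

with fitted scores `F = Kd C Kp` and out-of-sample scores
`Kd_cross · C · Kp_crossᵀ`. Cost is `O(n_d³ + n_p³ + n_d n_p (n_d+n_p))`;
the `n_d n_p × n_d n_p` Kronecker matrix is never materialized. The test
suite checks exact agreement (≤ 1e−8) with the explicitly assembled
Kronecker system on small instances.

`λ` defaults to 1.0 for all algorithms. As `λ → 0` on strictly PD
kernels the training scores interpolate `Y`; large `λ` shrinks all
scores toward 0. The rate of that damping depends on the kernel's
eigenvalue scale (per eigencomponent the shrinkage ratio between `λ=1`
and `λ=1000` is `(s+1)/(s+1000)` for pair-eigenvalue `s`), which is one
reason the default pipeline normalizes kernels to unit diagonal: it
keeps `λ` values comparable across data sets.

## Bipartite local model (BLM)

For each drug `d` with at least one known target, a kernel ridge model
on the protein kernel with labels `Y[d,·]` (dual vector
`(Kp + λI)⁻¹ Y[d,·]ᵀ`); symmetrically per protein. A pair's score
combines the two sides, mean by default (max optional — the original
formulation is ambiguous on this point, and mean is the smoother
choice). A node with no known edges contributes no model: such pairs
fall back to the other side alone, and to 0 when neither side is
modeled. BLM therefore cannot rank new-drug × new-protein pairs — an
inherent property of the method, visible as chance-level performance in
the both-axes cold-start scheme.

## Bipartite graph embedding (BGE)

Training nodes are embedded from a PSD kernel built on the bipartite
incidence `B`:

    M = [[B Bᵀ, B], [Bᵀ, Bᵀ B]] + 1e−6·I,  eigenvalues clipped at 0.

The off-diagonal `B` blocks are essential: with the SVD `B = UΣVᵀ` the
retained eigenvectors are `[u_k; v_k]/√2` with eigenvalues `σ_k(σ_k+1)`,
so interacting drugs and proteins share eigen-directions and land close
together. (A block-diagonal `B Bᵀ / Bᵀ B` construction would embed the
two sides into orthogonal subspaces and make every drug–protein inner
product zero.) The top `embed_dim` eigenvectors scaled by `√eigenvalue`
give node coordinates; per-coordinate kernel ridge regressions map
`Kd`/`Kp` rows onto them, and pairs are scored by inner products of
mapped coordinates. `embed_dim` defaults to `min(10, min(n_d,n_p)−1)`.
This construction is a faithful-in-spirit embedding, recorded in the
model provenance and swappable; it is validated structurally (block
networks separate, a hub drug dominates the first coordinate, and at
`λ → 0` the mapped inner products reproduce the rank-`embed_dim`
truncation of `M`).

## Scores, thresholding, categories

Raw regression outputs are clipped to [0, 1] **for reporting only**
(the displayed confidence scale); every ranking metric uses raw scores,
so clipping never alters an AUC or AUPR. Edges are emitted when the
score strictly exceeds the threshold (default 0.5) and categorized by
endpoint training status (new–new, training–new, new–training,
training–training); known training edges can be appended for the "all"
view, flagged separately. Output files sort by descending score with
lexicographic (drug, protein) tie-breaks, so runs are byte-reproducible.

## Cross-validation

*Pair-wise*: all `n_d·n_p` pairs are randomly partitioned into k folds
(sizes differing by ≤ 1); test-fold labels are masked to 0 during
training, keeping kernel dimensions fixed (the pair-label-masking
convention). *Block-wise*: entities of the chosen axis (drugs,
proteins, or both) are partitioned; test pairs involve the held-out
entities, whose kernel rows and labels are excluded from training
entirely, so test entities never overlap training entities. The
both-axes variant (test pairs = new drugs × new proteins) is the
default reported cold-start scheme, being the strictest. Defaults
k = 3, 3 repetitions; a repetition's value is the unweighted mean of
its fold values and the reported SD is the sample SD across repetition
values. Folds whose test labels are single-class are skipped with a
warning.

AUC uses the Mann–Whitney formulation (ties count one half), computed
via average ranks. AUPR is average precision — the mean of precision at
each positive's rank in descending-score order — with ties broken
deterministically by input position; this is stated in report headers
because interpolated PR variants give slightly different numbers.

## Synthetic benchmark

Drugs and proteins receive standard-normal latent coordinates in a
shared `latent_dim`-space; propensity(d,p) = `z_d·z_p`; the top
`⌈density·n_d·n_p⌉` propensities (ties broken by pair index) become
edges, so edge counts are exact and runs deterministic given the seed.
Each view is `Z W + σE`: when the view has at least `latent_dim`
features, `W` has orthonormal rows, making the projection an isometry —
at zero noise a view's Gram matrix equals the latent Gram matrix
exactly. Binary views threshold at the view median. The
`complementary_views` variant gives each of two views access to only
half the latent coordinates, the regime where integrating views must
beat either alone.

Default conditions — 60 drugs × 40 proteins, `latent_dim` 4, density
0.08, view noise 0.1, 32 features per view — are small enough for the
full test suite and acceptance script to run in seconds yet large
enough that pair-wise CV AUC, cold-start degradation, and the
integration advantage are all stably resolved. What this generator does
**not** emulate: the sparsity and heavy-tailed feature statistics of
real chemical fingerprints or side-effect profiles, hub-dominated
degree distributions, or biased negative labeling. Passing tests
demonstrate correctness of the machinery and the qualitative behavior
of the methods under the similarity assumption, not absolute accuracy
on any real interaction data — reproducing published benchmark numbers
would require the original database-derived similarity matrices.

## Numerical choices

Kernels are symmetrized as `(K+Kᵀ)/2` on load (asymmetry > 1e−6 warns);
construction enforces symmetry to 1e−8. Eigendecompositions use
`numpy.linalg.eigh`. Missing profile cells are a hard error by default
(zero-fill is opt-in) because silent imputation corrupts kernels.
Id matching is case-sensitive exact string match with surrounding
whitespace stripped. Table writers print 12 significant digits;
round-trips are lossless at that precision.

## Known limitations

- BLM cannot generalize to pairs where both endpoints are new.
- The BGE network kernel is one reasonable construction among several;
  its absolute scores are not comparable across training sets.
- Training treats all unknown pairs as negatives, which underestimates
  scores for true-but-unknown interactions in dense regions.
- The CLI's simple mode intentionally refuses overrides; use advanced
  mode for anything non-default.
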