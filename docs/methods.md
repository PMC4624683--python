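# Methods

`ensemblecmp` quantifies how similar two conformational ensembles of the
same molecule are, treating each ensemble as a sample from an underlying
probability distribution over conformations and scoring pairs of ensembles
with symmetrized divergences between estimates of those distributions.
Three estimators are provided, differing in how the distribution is
modelled; all scores are reported in nats.

## The three estimators

### Harmonic ensemble similarity (HES)

Each ensemble is modelled as a single multivariate Gaussian N(μ, Σ) over
the flattened 3N coordinates of the selected atoms. Two models are scored
with the symmetrized Kullback–Leibler divergence, taken as the **sum** of
the two directed divergences, for which the Gaussian log-determinant terms
cancel:

    D = ½ [ tr(Σ₁⁻¹Σ₂) + tr(Σ₂⁻¹Σ₁) − 2d + (μ₁−μ₂)ᵀ(Σ₁⁻¹+Σ₂⁻¹)(μ₁−μ₂) ],
    d = 3N.

D is symmetric, zero iff the models coincide, and unbounded above.

*Covariance estimation.* The frame count is usually far below 3N, so the
sample covariance is singular. Σ is estimated with Schäfer–Strimmer
analytic shrinkage toward its own diagonal: off-diagonal entries are
damped by the data-driven intensity λ* = Σᵢ≠ⱼ V̂ar(sᵢⱼ) / Σᵢ≠ⱼ sᵢⱼ²
(clipped to [0,1]), and the spectrum is lifted by a small floor
(max(10⁻¹⁰·max diag, 10⁻¹² Å²)) so the model is positive definite even for
a zero-variance ensemble. Inversion goes through a symmetric
eigendecomposition with the same relative eigenvalue floor.

*Frame of reference.* Divergences of coordinate distributions are
meaningless unless all ensembles share one rigid frame. All ensembles are
superposed (Kabsch least squares) onto the iteratively aligned mean of the
**pooled** frames of every ensemble in the comparison, and that reference
is rotated into a canonical principal-axes frame with a deterministic sign
convention. Pooling makes the score independent of the order in which
ensembles are passed; canonical orientation matters beyond cosmetics
because the diagonal shrinkage target is basis-dependent — without it the
score would change by ~0.3% under a rigid rotation of the input.

### Clustering ensemble similarity (CES)

All frames of all ensembles are clustered **together** by affinity
propagation on similarities s(i,k) = −RMSD(i,k), where RMSD is the
superposition-minimized pairwise value. Each ensemble is then summarized
by the fraction of its frames in each cluster, and pairs of ensembles are
scored by the discrete Jensen–Shannon divergence of those population
vectors (natural log; 0 ≤ D_JS ≤ ln 2 ≈ 0.693).

Affinity propagation follows the standard responsibility/availability
message passing with damping (default 0.9), max_iter 500, convergence
declared when the exemplar set is stable for 50 consecutive iterations.
The self-similarity ("preference", which controls the cluster count)
defaults to the median of the off-diagonal similarities. A fixed
infinitesimal jitter (~10⁻¹³ of the similarity scale, seeded) breaks exact
message ties so the partition is deterministic given (matrix, parameters,
seed); final label ties resolve toward the lowest exemplar index.
Non-convergence returns the current partition with a warning — the
downstream JS remains well defined.

*A known instability of the median preference.* When the distance
distribution is bimodal (within-state ≈ 1 Å vs between-state ≈ 20 Å) and
the same-state pair fraction of the concatenation is close to ½ — which
happens exactly for two-state mixtures with mirrored populations — the
median sits on a knife edge between the two modes. Resampling (e.g.
bootstrap replicates) can tip it into the within-state mode, where the
preference becomes comparatively high and the partition fragments into
hundreds of clusters, inflating the plug-in JS by its small-sample bias
(≈ (k−1)/4 · (1/n₁ + 1/n₂) for k clusters). Fixtures with three or more
states, or asymmetric state fractions, keep the median robustly in the
between-state mode. Users comparing exactly two mirrored two-state
ensembles should set the preference explicitly.

### Dimensionality-reduction ensemble similarity (DRES)

The RMSD matrix is embedded into a low-dimensional space (default 3D)
with stochastic proximity embedding: random frame pairs are drawn and both
points are moved along their difference vector to reduce
|d_embed − d_target| whenever the target distance is within the
neighborhood cutoff, or whenever the embedding underestimates a far pair.
The learning rate anneals linearly from 2.0 to 0.05 over 100 cycles of
10·n pair updates each (the per-cycle work is linear in the number of
frames). The cutoff defaults to 1.5× the median pairwise RMSD. The
reported stress is S = [Σ_scope (d_e − d_t)²/d_t] / Σ_scope d_t over the
pairs in scope (zero-target pairs carry no weight).

The annealing budget was chosen so that duplicated frames — whose target
distance to their twin is exactly zero — collapse onto identical embedded
points when the distance geometry is low-dimensional; with an order of
magnitude fewer updates the embedding retains ~1 Å of per-point residual
and an ensemble compared with an exact copy of itself scores ~0.08
instead of ~0.

Per-ensemble densities in the embedded space are Gaussian kernel
estimates with a per-dimension Silverman bandwidth
h_k = σ_k (4/((d+2)n))^(1/(d+4)), floored at 10⁻³ embedding units for
zero-variance dimensions. The JS divergence is estimated by
resubstitution Monte-Carlo, D̂ = ½⟨ln(p_a/p_m)⟩_a + ½⟨ln(p_b/p_m)⟩_b with
p_m = (p_a+p_b)/2, densities floored at 10⁻³⁰⁰ before logs, and the
result clipped to [0, ln 2]. Because the bandwidth is diagonal, the score
is exactly invariant under translations, reflections and axis
permutations of the embedding but only approximately under general
rotations.

## Pairwise RMSD matrix

CES and DRES consume one condensed (upper-triangular) matrix of
superposition-minimized RMSDs over the concatenation of all ensembles.
Entries use a quaternion characteristic-polynomial kernel: the optimal
Kabsch score equals the largest eigenvalue of the 4×4 quaternion key
matrix, found by Newton iteration from the upper bound (G_a+G_b)/2; the
kernel is numba-compiled. Row blocks can be distributed over forked
worker processes; blocks are fixed by the frame count alone and every
entry is computed independently, so the result is bit-identical for any
worker count. The matrix can be cached to an HDF5 container (datasets
`values` and `ensemble_offsets`, attributes `format` and `n`, float64
throughout — lossless round-trip).

Bootstrap replicates, prefix windows and sparsified subensembles are
index subsets (with repetition) of already-computed frames; their
matrices are gathered from the cached one (repeats get distance 0) and
only clustering/embedding is recomputed.

## Workflows

- **compare_all** — all-vs-all divergence table; one matrix for CES/DRES,
  HES bypasses it.
- **bootstrap_uncertainty** — each replicate resamples the frames of both
  ensembles independently with replacement to their original sizes and
  recomputes the divergence end-to-end (re-clustering / re-embedding /
  re-fitting); reports the sample standard deviation over replicates
  (default 100).
- **convergence_profile** — divergence of time-ordered prefixes [0, w)
  against the full ensemble; default 10 evenly spaced prefix lengths. The
  full-length entry is 0 by construction (the prefix *is* the full
  ensemble) and is short-circuited rather than re-clustered.
- **sparsification_curve** — divergence of uniformly decimated
  subensembles (keep every k-th frame) against the full ensemble.
- **project_similarity_2d** — classical metric scaling of the divergence
  matrix seeded into a stress-majorization (SMACOF-style) refinement with
  two extra random restarts; output centered at the origin, defined up to
  rotation/translation/inversion.

## Synthetic fixtures

The generator emulates ensembles drawn from one or more harmonic wells:
each state is a reference conformation plus Gaussian displacements, and
multi-state ensembles draw each frame's state from stated population
fractions. Reference conformations are self-avoiding random chains with
3.8 Å spacing (Cα-like scale), so RMSDs are on realistic scales without
external structures; a companion helper produces a second center at an
exact requested minimized RMSD by bisection. State choice and
displacement noise use separate random streams, so changing populations
does not perturb within-state geometry for a given seed.

Displacements are isotropic over all 3N coordinates by default. An
optional `n_modes` confines them to a few random orthonormal collective
modes (total variance preserved). This matters for DRES: an isotropic
high-dimensional well makes *all* pairwise RMSDs nearly equal (a
near-simplex), a geometry no 3D embedding can represent, whereas real MD
basins — the regime the projection method targets — are effectively
low-dimensional. Low-rank fixtures are therefore used wherever a test
probes embedding fidelity (identity, sparsification, convergence);
isotropic fixtures are used everywhere a plain harmonic well is stated.

What the fixtures do **not** emulate: physical force-field detail,
anharmonicity, time correlation between frames (frames are i.i.d., so
"well-mixed" is true by construction), and solvent/periodicity artifacts.
Passing tests therefore demonstrate correctness of the estimators on
known ground truth, not performance on any particular real system.

## Problem sizes and numerical choices

Default test problem sizes are chosen to exercise each property at
desk scale: 200–1000 frames per ensemble for planted-population recovery
(1000 matches the frame count used in routine force-field comparisons and
keeps the binomial noise of the empirical populations near 0.01 nats),
2048 frames decimated to 128 for the sparsification check, 400-frame
bootstrap fixtures with 100 re-clustering replicates. The bootstrap
fixture uses a three-state mixture for the median-preference reason
above, sized by the delta method so the intrinsic resampling noise sits
well inside the 20% relative-error contract.

Degenerate inputs are handled explicitly: an all-zero distance matrix
embeds (or clusters) everything at one point with a warning; a
zero-variance ensemble still yields a positive-definite Gaussian model
(pure regularizer); collinear or coincident reference structures raise a
numerical-degeneracy error rather than returning an arbitrary rotation.

## Known limitations

- Absolute HES values depend on the shrinkage estimator and on the sum
  (rather than mean) symmetrization convention; CES values depend on the
  preference; DRES values depend on the embedding dimension, schedule and
  bandwidth rule. Scores are best interpreted relatively, comparing pairs
  under identical settings.
- Affinity propagation is O(n²) per iteration in memory and time; tens of
  thousands of frames are the practical ceiling.
- The bounded [0, ln 2] scores saturate for fully disjoint ensembles:
  everything "far" looks equally far.
- The 2D projection is a metric embedding of a divergence matrix that
  need not be Euclidean; only the relative layout is meaningful.
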