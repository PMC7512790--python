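# Methods

## Model and assumptions

The package treats image segmentation as clustering of pixel intensities
(one feature per pixel; color features are out of scope). Three fitted
models are provided.

**Fuzzy c-means (FCM).** Minimizes J = Σₖ Σᵢ u_ik^m ‖x_k − v_i‖² over
row-stochastic memberships u and centers v by exact alternating updates.
Each iteration recomputes memberships from the current centers, then
centers from the memberships, then J; the trace is therefore non-increasing
and the fit stops when |J(t) − J(t−1)| < tol or at the iteration cap.
Centers are initialized by drawing c distinct intensity *values* from the
data with the given seed. Sampling values rather than indices has two
consequences we rely on: initial centers can never coincide, and the draw
is invariant to pixel order, so permuting the data permutes membership rows
exactly. A pixel lying exactly on one or more centers receives membership
split equally among the coincident centers (the zero-distance limit of the
update). Constant images, or images with fewer distinct values than
clusters, are rejected as degenerate.

**Spatial FCM (SFCM).** Identical to FCM except that after every
membership update each pixel's membership is averaged with the mean over a
centered square window: û = (window-mean + u)/2. The window always contains
the center pixel, and at the image border it is truncated to the pixels
actually present, with the divisor equal to the true neighbor count — the
operator stays an exact average everywhere and preserves row sums
exactly. With window 1 the operator is the identity and SFCM reproduces FCM
bit for bit. Because the smoothing sits outside the alternating
minimization, monotone descent is not guaranteed (and not asserted) for
SFCM; termination is by |ΔJ| or the cap.

**KL consensus (plain and spatial).** The r member partitions are
concatenated and divided by r, making each pixel a probability profile
y_k· of length s = Σ c_f. The consensus minimizes
J = Σₖ Σᵢ u_ik^m D_KL(y_k·‖o_i·) with simplex-constrained centers, by the
closed-form updates obtained from the Lagrangian (centers: membership-
weighted convex combinations of profile rows; memberships: inverse-KL
weighting with exponent 1/(m−1)). The plain variant is an exact alternating
minimization and its objective trace is non-increasing; the property suite
asserts this. The spatial variant applies the same neighborhood operator as
SFCM to the memberships each iteration (default window 5×5), uses the
smoothed memberships in the center update, and reports J computed with the
smoothed memberships; descent is again not guaranteed. The returned
memberships are the smoothed ones.

An important structural consequence of the smoothing operator: it keeps
weight 1/2 on the pixel's own membership, so a pixel maximally confident in
the wrong cluster (membership exactly 1) can never be flipped by smoothing
alone — its smoothed wrong-cluster membership stays ≥ 0.5. Noise correction
therefore happens only for pixels whose own evidence is not extreme, which
is the typical case under additive noise.

## Numerical choices

- KL divergence uses the natural logarithm (the base cancels in the
  membership ratio; it only rescales J) with 0·log 0 = 0 and center entries
  floored at 1e-12 inside the log ratio, since member partitions routinely
  contain exact zeros.
- A profile whose divergence to some center is below 1e-12 is treated as
  lying on that center: its mass is split equally among all such centers.
- Defuzzification is per-pixel argmax with ties resolved to the lowest
  cluster index.
- Consensus centers are initialized by drawing c distinct rows from the
  *unique* rows of the profile matrix. Drawing unique rows (rather than
  row indices) avoids coincident initial centers, which would trap the fit
  in a symmetric fixed point where all clusters evolve identically; the
  unique-row pool also makes the draw independent of pixel order.
- Convergence defaults everywhere: tol 1e-5 on |ΔJ|, 100 iterations, m = 2.
- An empty consensus cluster (zero membership mass) raises an error naming
  the iteration; the caller may re-seed.

## Label alignment and accuracy

Cluster indices are arbitrary, so predicted label maps are aligned to the
reference by the permutation maximizing total pixel agreement (Hungarian
assignment on the confusion matrix; the test suite cross-checks it against
exhaustive permutation search for up to 4 classes). Overall segmentation
accuracy (SA) is the fraction of correctly labeled pixels after alignment;
per-class accuracy is the Jaccard index of the class's pixel sets, defined
as 1 when the class is absent from both maps.

## Synthetic data: what it emulates and what it does not

The two-value phantom is a 50×50 binary image split into two vertical
halves (intensities 0 and 1); the four-region phantom is a 64×64 image of
equal quadrants at levels 0, 1/3, 2/3, 1. Both come with exact ground-truth
label maps that noise never alters. "r% noise" means the Gaussian standard
deviation is r% of the clean intensity range; Rician corruption is
sqrt((I+e₁)² + e₂²) with independent Gaussian e₁, e₂ of that same standard
deviation, the standard magnitude-MRI model (Rayleigh-distributed where the
signal is zero). Noisy intensities are left unclipped so the noise
distribution is exactly as stated.

These phantoms exercise noise robustness with compact region boundaries,
but they lack the structure of real images: no intensity inhomogeneity, no
partial-volume effects, no textured or curved anatomy, and per-pixel
intensity is the only feature. Passing the benchmark grid therefore
demonstrates noise suppression and correct consensus behavior, not clinical
segmentation performance.

## Experiment grid

The experiment runner evaluates every method — each ensemble member, the
plain consensus and the spatial consensus — on the *same* noisy image
within each (noise kind, level, replicate) cell, with all cell seeds derived
from one master seed; tables are exactly reproducible from the
configuration. Default replicates: 5 with mean ± sd reporting. The ordering
checks in the test suite use both phantoms at 20% and 30% noise with 3
replicates, a grid small enough for interactive runs while large enough for
stable rank comparisons.

The default ensemble is two independently seeded FCM runs plus SFCM with
3×3 and 5×5 windows (r = 4). These members are fully specified by the
equations above, with diversity coming from initialization and spatial
scale. Ensembles built from members that use nonlocal weighting would give
the consensus substantially cleaner inputs at heavy noise (50% of range);
with the default members the spatial consensus still dominates every member
there, but absolute accuracy is bounded by what the members supply —
roughly SA 0.90 on the two-value phantom at 50% Gaussian noise, versus
perfect recovery at 20% and below.

## Known limitations

- Single intensity feature; no color or multichannel support.
- Cluster count c is prior knowledge; no model selection is attempted.
- Spatial variants can cycle in principle (no descent guarantee); in
  practice the |ΔJ| criterion terminates them within a few dozen
  iterations on all tested inputs.
- Member weighting is uniform; unreliable members degrade the consensus
  proportionally.
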