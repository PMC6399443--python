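# Methods

## Problem and model

Homotopic connectivity (HC) is the functional coupling between
mirror-symmetric regions of the two cerebral hemispheres. `homokappa`
estimates a *meta-analytic* form of HC (MHC) from coordinate-based
activation data: given a corpus of experiments, each reporting peak
activation foci (x, y, z) in stereotaxic space, it asks how often a region
and its contralateral mirror activate *together*, beyond what their
individual activation rates would predict. The resulting per-pair statistic
is Patel's κ. A second arm computes voxel-mirrored homotopic connectivity
(VMHC) from resting-state series — the Pearson correlation between each
voxel's time course and that of its x-mirror — so the two measures of HC
can be compared voxel-by-voxel.

### From foci to modeled activation

Each focus is blurred with an isotropic 3-D Gaussian kernel. With full width
at half maximum `FWHM`, the standard deviation is σ = FWHM/√(8 ln 2), and
the per-focus field at distance d is the Gaussian density scaled by the
voxel volume V:

    g(d) = V · exp(−d² / 2σ²) / ((2π)^{3/2} σ³)

An experiment's modeled-activation (MA) map combines its foci by
probabilistic union, MA = 1 − ∏(1 − g_f); the ALE map applies the same
union across experiments. Both therefore live in [0, 1), and the union is
exactly order-invariant. The kernel is truncated at 5σ (the value at the
truncation boundary is e^{−12.5} ≈ 3.7·10⁻⁶ of the peak, so the discarded
mass is negligible). A voxel-wise-max combination rule is *not* used; the
union is applied both within and across experiments.

**Default FWHM = 10 mm.** The radius containing ≈95 % of a 3-D Gaussian's
mass is 2.80σ; at FWHM 10 mm (σ = 4.25 mm) that radius is 11.9 mm, i.e. an
effective kernel extent of about 12 mm around each focus, which matches the
spatial uncertainty typical of coordinate-based meta-analytic data. A
per-experiment, subject-count-based FWHM can be substituted by passing a
different `KernelSpec` per experiment.

### Midline offset adjustment

A focus close to the midsagittal plane spills probability into the opposite
hemisphere and can fake homotopic co-activation. Inside a band of total
width 24 mm centered on the midline (half-width 12 mm), the contribution of
each focus to voxels in the *opposite* hemisphere is attenuated by a weight
w(|x|) that vanishes at the midline and equals 1 at the band edge;
same-hemisphere contributions and voxels with |x| ≥ 12 mm are untouched.
Two weight shapes are provided:

- `linear_ramp` (default): w = |x|/12;
- `inverse_distance`: interference is modeled as falling off like 1/|x|,
  giving w = (1 − c/max(|x|, c)) / (1 − c/12) with inner cutoff c = 1 mm
  (full suppression within 1 mm of the midline, exactly 1 at the band edge).

The attenuation is applied at the MA level, before any region aggregation —
that is where a spurious cross-hemisphere probability increase would
contaminate the co-activation counts. Foci lying exactly on x = 0 belong to
neither hemisphere and are not attenuated.

### Activation matrix and Patel's κ

On a symmetric parcellation (every left parcel has an exact mirror parcel on
the right), an N×M binary matrix records, for each experiment and region,
whether the region was *activated*: at least 20 % of its voxels (inclusive
boundary; configurable, with 0 % meaning "at least one voxel") are
MA-significant. The default significance predicate for a voxel is MA > 0,
i.e. the voxel lies within the truncated kernel of at least one focus; an
absolute MA cutoff is available instead.

For a homotopic pair (a, b) the joint activation states have probabilities
θ₁ = P(a=1,b=1), θ₂ = P(a=1,b=0), θ₃ = P(a=0,b=1), θ₄ = P(a=0,b=0),
estimated by the corresponding count fractions. With

    E       = (θ₁+θ₂)(θ₁+θ₃)              (independence expectation)
    max(θ₁) = min(θ₁+θ₂, θ₁+θ₃)           (largest attainable θ₁)
    min(θ₁) = max(0, 2θ₁+θ₂+θ₃−1)          (smallest attainable θ₁)
    D       = 1 if θ₁ ≥ E else 0

Patel's κ = (θ₁ − E) / [D·(max(θ₁) − E) + (1−D)·(E − min(θ₁))].

κ ∈ [−1, 1]; κ = 1 exactly when θ₁ attains its upper bound (which happens
whenever θ₂ = 0 or θ₃ = 0), κ = 0 at exact independence, κ = −1 at maximal
avoidance. The indicator D selects the attainable range on the relevant side
of E, which is what guarantees the ±1 bounds. When a region is never or
always active the denominator vanishes and κ is undefined: the package
returns NaN with a `degenerate` flag, never a numeric placeholder — 0 means
independence, not "unestimable".

**Significance** is Bayesian. Under a flat Dirichlet prior the posterior of
(θ₁…θ₄) given counts is Dirichlet(counts + 1); Monte-Carlo sampling
(default n = 10 000 draws) estimates P(κ > e | data) with e = 0, and a pair
is declared significant at posterior credibility ≥ 0.95. Samples with a
vanishing denominator are skipped and counted; if more than half are
skipped the result is flagged unreliable.

### Parcellations

- `symmetrize_atlas` makes an arbitrary labeled atlas exactly
  mirror-symmetric. Default policy `intersection`: a voxel keeps its label
  only if its mirror carries the same anatomical label (conservative — no
  tissue invented). `left_dominant` instead imposes the left hemisphere's
  labels on the right. Both are available because the right policy is a
  judgment call on real atlases; the choice is recorded in provenance.
- `homogeneous_parcellation` builds Fornito-style equal-size control
  parcellations: each left region is split into ⌊size/k⌋ 6-connected
  parcels of exactly k voxels by seeded random region growing (growth
  absorbs the frontier voxel with the fewest unassigned neighbours, with
  seed-randomized tie-breaks, which keeps the remaining tissue compact),
  then mirrored so pairs stay exact. Remainder voxels are merged into the
  nearest same-region parcel (making some parcels k + r, recorded in
  provenance) or dropped. Contiguity is enforced by default; a
  non-contiguous mode exists only for sensitivity checks.

### VMHC and map comparison

VMHC is computed per in-mask voxel as the Pearson correlation with the
x-mirror voxel's series, Fisher z-transformed with |r| clipped at 1 − 10⁻⁷
(atanh diverges at ±1; clipped voxels are flagged). The output is exactly
symmetric by construction. No spatial smoothing is applied anywhere in the
package. Subject maps are averaged voxel-wise with per-voxel mask counting.

Comparison of an MHC (κ) map with a VMHC (Fisher z) map over a shared brain
mask (non-brain voxels never enter any statistic):

- global Pearson r;
- VCC (voxels' contribution to correlation): for each voxel pair i, the
  change r_global − r_with_i_removed, computed by exact downdating of the
  sufficient statistics (n, Σx, Σy, Σx², Σy², Σxy) — algebraically
  identical to naive recomputation, at O(n) total cost — then normalized by
  z-scoring over the mask with sign preserved (positive = voxel drives
  convergence). z-scoring was chosen as the normalization because it
  preserves the sign convention and makes VCC values comparable across map
  pairs; this choice is recorded in the map's provenance.
- difference map z(MHC) − z(VMHC), both maps z-scored internally over the
  shared mask (mean 0, SD 1) so the two different statistics become
  comparable; positive values mark MHC-dominant voxels.
- `threshold_to_roi` keeps voxels strictly above a cutoff (default 1.0, on
  z-scaled maps), optionally intersected with a manual mask.
- `domain_enrichment` scores a behavioral domain d with n_d foci, k_d of
  them inside the ROI, against the all-domain base rate p₀ by the binomial
  z = (k_d − n_d p₀)/√(n_d p₀(1−p₀)). This is a self-contained enrichment
  statistic over a labeled foci table; it reproduces ranking logic testably
  without any external database service.

An external VMHC map is co-registered onto the MHC grid by nearest-neighbour
resampling by default (the values are statistics, not image intensities);
trilinear is available.

## Synthetic data: what it emulates and what it does not

- `gen_synthetic_atlas` produces exactly mirror-symmetric parcellations.
  `packed` partitions the hemisphere into contiguous blobs (for
  parcellation/symmetrization contracts); `spaced` places compact cubes
  separated — including across the midline — by more than the kernel
  truncation radius. The spaced design is used for estimator-recovery
  studies because the Bernoulli generative model and the activation-matrix
  estimator only correspond when the MA footprints of distinct regions
  cannot overlap; with overlap, spillover activations are a property of the
  geometry, not of the estimator.
- `gen_coactivation_experiments` draws, per experiment and pair, one of the
  four joint states from (θ₁…θ₄) and places foci uniformly over the active
  region's voxel centers. Experiments in which nothing activates report no
  foci and are omitted (an activation study with zero reported peaks does
  not enter a meta-analysis); the omission renormalizes θ₄ by the
  probability of an all-empty experiment, which at the defaults (8 pairs)
  is below 0.4 % and shifts κ by well under 0.01.
- `gen_rest_timeseries` plants an exact population mirror-correlation ρ per
  voxel pair via a shared Gaussian factor: left = √|ρ|·s + √(1−|ρ|)·e₁,
  right = sign(ρ)·√|ρ|·s + √(1−|ρ|)·e₂, unit marginal variance. An AR(1)
  option adds temporal smoothness without changing the contemporaneous
  correlation. It does **not** emulate hemodynamics, motion, physiological
  noise, or spatial autocorrelation — so passing recovery tests demonstrates
  the correctness of the estimators under their model assumptions, not
  robustness to real fMRI artifacts.

## Numerical choices

- All computation in float64; NIfTI storage in float32 (labels int32).
- Kernel truncation 5σ; MA/ALE algebra keeps values in [0, 1) exactly.
- Fisher z clip at |r| = 1 − 10⁻⁷, flagged.
- The 20 % activation rule uses an inclusive boundary with a 10⁻¹² guard
  against float rounding of fraction·size.
- Cluster-level ALE inference: permutations preserve per-experiment foci
  counts and redraw locations uniformly at in-mask voxel centers;
  cluster-forming threshold is the (1 − p) pooled-score quantile (default
  p = 0.001), cluster extent must exceed the (1 − α) quantile of the
  permutation max-cluster-size null (α = 0.05, n = 1000 by default; α ≥ 1
  keeps every suprathreshold cluster). Permuted score vectors are held in
  float32; this is designed for the package's grid sizes, not whole-brain
  2-mm nulls on small memory.
- Dirichlet prior counts + 1 (flat); defaults e = 0, n_mc = 10 000,
  credibility 0.95.
- Degenerate marginals: κ = NaN + flag, excluded from maps/tables (missing
  pairs render as background and are excluded from map masks).
- MNI↔TAL conversion uses the published pooled affines (SPM and FSL
  variants); the MNI→TAL direction is the matrix inverse. The constants are
  injected as named transform objects and fully pluggable; an identity
  transform supports tests and same-space data. Whether foci that leave the
  brain mask after conversion should be kept is undecidable in general; the
  package drops foci outside the *grid bounding box* at MA time with a
  logged count.

## Study sizes used by the test suite and acceptance script

Recovery studies use an 8-pair spaced atlas on a 4-mm grid, 2000
experiments per replicate (100 replicates per θ in the test suite, 25 in
the acceptance script), matching the package's intended operating scale for
synthetic validation. A replicate's estimate is the mean κ̂ over its 8
identically-parameterized pairs — the pairs are exchangeable draws under
one θ, and a single pair's κ̂ at N = 2000 has sampling SD up to ≈0.03, so
pooling is the appropriate per-collection summary. Calibration uses
N = 100 experiments per contingency (a typical per-domain corpus slice).
VMHC recovery uses T = 2000 to separate estimator bias from sampling noise;
the generator's default T = 225 reflects a standard 7.5-minute TR-2s
acquisition. Threshold-stability runs use FWHM 6 mm with 20-mm cube regions
so that a single focus covers a genuinely variable fraction of its region
(roughly 25–75 %), making the 0 %/20 %/40 % thresholds meaningfully
different rather than trivially identical.

## Known limitations

- The estimator-recovery guarantees hold under the spaced-atlas geometry;
  with adjacent regions (packed atlases, real anatomical atlases), kernel
  spillover between neighbouring regions biases co-activation counts — a
  property of region size and kernel width that users should assess with
  the spaced/packed generators before interpreting small-region κ values.
- κ's finite-sample distribution is skewed near |κ| = 1; the point estimate
  has a ratio bias of order +0.01 at N = 2000 for mid-range κ.
- Cluster-level inference stores all permuted in-mask scores; very large
  masks with many permutations need memory proportional to both.
- The behavioral enrichment z is a plain binomial approximation; domains
  with very few foci (n_d p₀ < 5) should be read with caution.
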