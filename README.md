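# homokappa

Meta-analytic homotopic connectivity (MHC) from coordinate-based activation
foci, with comparison against voxel-mirrored homotopic connectivity (VMHC)
from resting-state data.

Homotopic connectivity — the coupling between mirror-symmetric regions of
the two brain hemispheres — is usually measured from resting-state fMRI.
`homokappa` instead estimates it from the activation literature: given a
corpus of experiments, each reporting peak coordinates (x, y, z) in
Talairach or MNI space, it measures how often a region and its
contralateral mirror *co-activate* beyond chance. The package is for
neuroimaging researchers doing coordinate-based meta-analysis who want a
task-general, region-wise map of homotopic co-activation, and for comparing
that map against resting-state VMHC.

## Method in brief

1. **Modeled activation (ALE).** Every focus is blurred with an isotropic
   3-D Gaussian (σ = FWHM/√(8 ln 2), default FWHM 10 mm, truncated at 5σ);
   an experiment's MA map is the probabilistic union 1 − ∏(1 − g) over its
   foci. Near-midline foci have their cross-hemisphere contribution
   attenuated inside a 24 mm midline band so they cannot fake homotopic
   co-activation.
2. **Activation matrix.** On an exactly symmetric parcellation, experiment
   × region entries are 1 when ≥ 20 % of the region's voxels are
   MA-significant (thresholds 0 %–40 % supported).
3. **Patel's κ.** For each homotopic pair with joint activation
   probabilities θ₁…θ₄ (both, left-only, right-only, neither),

       κ = (θ₁ − E) / [D·(max(θ₁) − E) + (1 − D)·(E − min(θ₁))]

   with E = (θ₁+θ₂)(θ₁+θ₃), max(θ₁) = min(θ₁+θ₂, θ₁+θ₃),
   min(θ₁) = max(0, 2θ₁+θ₂+θ₃−1), D = 1{θ₁ ≥ E}; κ ∈ [−1, 1], 0 at
   independence. Significance is Bayesian: P(κ > 0 | data) by Monte-Carlo
   sampling from the Dirichlet(counts + 1) posterior.
4. **VMHC arm.** Per-voxel Pearson correlation with the x-mirror voxel's
   time series, Fisher z-transformed; group averaging; then map-level
   comparison: global Pearson r, leave-one-voxel-out contribution analysis
   (VCC, exact sufficient-statistic downdating), and the z-standardized
   difference map z(MHC) − z(VMHC).

Synthetic generators (mirrored atlases, foci drawn from the Bernoulli
co-activation model with known θ, rest series with planted mirror
correlation ρ) give every stage a ground-truth test surface. See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Estimate κ for 8 homotopic pairs from 2000 synthetic experiments drawn with
known co-activation θ = (0.30, 0.10, 0.10, 0.50):

```python
import numpy as np
import homokappa as hk

grid = hk.VolumeGrid.symmetric((36, 24, 24), voxel_size=4.0)
atlas = hk.gen_synthetic_atlas(8, grid, seed=3, style="spaced", min_gap_mm=24.0)

theta = np.array([0.30, 0.10, 0.10, 0.50])
spec = hk.CoactivationSpec(theta, n_experiments=2000, seed=7)
coll = hk.gen_coactivation_experiments(spec, atlas)

am = hk.activation_matrix_from_foci(coll, atlas, hk.KernelSpec(fwhm=10.0),
                                    fraction_threshold=0.20)
results = hk.compute_pair_kappas(am, atlas, n_mc=10_000, seed=1)
table = hk.region_kappa_table(results, atlas)
print(table[["left_name", "n11", "n10", "n01", "n00", "kappa",
             "posterior_prob_exceeds", "significant"]].head(4).to_string(index=False))
print(f"true kappa(theta) = {hk.kappa_from_theta(theta):.4f}")
print(f"mean kappa-hat    = {table['kappa'].mean():.4f}")
```

prints

```
left_name  n11  n10  n01  n00    kappa  posterior_prob_exceeds  significant
 pair01_L  584  200  170 1039 0.628329                     1.0         True
 pair03_L  633  196  182  982 0.617644                     1.0         True
 pair07_L  622  193  196  982 0.598330                     1.0         True
 pair02_L  603  206  190  994 0.596693                     1.0         True
true kappa(theta) = 0.5833
mean kappa-hat    = 0.6002
```

Each row is one homotopic pair: the four joint-activation counts over the
2000 experiments, the κ estimate, and the posterior probability that κ > 0.
The mean estimate recovers the generative κ to within its finite-sample
sampling error (a single pair's κ̂ at N = 2000 has SD ≈ 0.02 plus a small
positive ratio bias). `hk.mhc_map(results, atlas)` paints κ onto the
volume; `hk.vmhc`, `hk.vcc` and `hk.difference_map` drive the
resting-state comparison arm.

A CLI mirrors the library for shell use, e.g.
`homokappa simulate atlas --pairs 4 --out atlas.nii.gz`,
`homokappa kappa --foci foci.txt --atlas atlas.nii.gz --out-table mhc.tsv`,
`homokappa vmhc --rest rest.nii.gz --out vmhc.nii.gz`,
`homokappa compare --mhc mhc.nii.gz --vmhc vmhc.nii.gz`.

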