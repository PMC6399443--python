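"""Activation likelihood estimation: MA maps, midline offset, ALE, cluster null.

Each reported focus is blurred with an isotropic 3-D Gaussian kernel whose
standard deviation derives from a full-width-half-maximum, sigma = FWHM /
sqrt(8 ln 2).  The per-focus field at distance d is the Gaussian density
scaled by the voxel volume,

    g(d) = V_voxel * exp(-d^2 / (2 sigma^2)) / ((2 pi)^{3/2} sigma^3),

truncated at ``truncation_radius`` (default 5 sigma, mass loss < 1e-5 of the
peak).  A modeled-activation (MA) map combines an experiment's foci by
probabilistic union 1 - prod(1 - g), and the ALE map is the same union taken
across experiments' MA maps, so all values stay in [0, 1).

Foci near the midline spill probability into the opposite hemisphere, which
would fake homotopic co-activation; the midline offset adjustment attenuates
cross-hemisphere kernel contributions inside a band (default 24 mm wide,
i.e. half-width 12 mm) with a weight that vanishes at the midline and reaches
1 at the band edge.

Cluster-level significance follows the usual permutation recipe: foci counts
per experiment are preserved while locations are redrawn uniformly inside the
brain mask; the pooled permuted-score histogram gives a cluster-forming
threshold, and the permutation distribution of the maximum suprathreshold
cluster size gives the cluster-extent cutoff.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .foci import FociCollection, FociExperiment
from .grid import GridError, VolumeGrid, VoxelMap

logger = logging.getLogger("homokappa")

#: FWHM-to-sigma conversion constant, sqrt(8 ln 2)
FWHM_SIGMA_RATIO = math.sqrt(8.0 * math.log(2.0))

#: Default kernel width, mm.  The radius enclosing ~95% of the 3-D Gaussian
#: mass is 2.80 sigma = 11.9 mm at this FWHM, i.e. an effective kernel extent
#: of about 12 mm around each focus.
DEFAULT_FWHM = 10.0


def sigma_from_fwhm(fwhm: float) -> float:
    """Gaussian sigma for a given full width at half maximum (both mm)."""
    if not fwhm > 0:
        raise ValueError(f"fwhm must be positive, got {fwhm}")
    return fwhm / FWHM_SIGMA_RATIO


@dataclasses.dataclass(frozen=True)
class KernelSpec:
    """Isotropic Gaussian kernel: FWHM in mm; truncation in multiples of sigma."""

    fwhm: float = DEFAULT_FWHM
    truncation_sigmas: float = 5.0

    def __post_init__(self):
        sigma_from_fwhm(self.fwhm)  # validates fwhm > 0
        if not self.truncation_sigmas > 0:
            raise ValueError("truncation_sigmas must be positive")

    @property
    def sigma(self) -> float:
        return sigma_from_fwhm(self.fwhm)

    @property
    def truncation_radius(self) -> float:
        return self.truncation_sigmas * self.sigma

    def peak(self, voxel_volume: float) -> float:
        """Kernel value at d = 0, scaled by the voxel volume."""
        s = self.sigma
        return voxel_volume / ((2.0 * math.pi) ** 1.5 * s ** 3)


@dataclasses.dataclass(frozen=True)
class MidlineBand:
    """Midline compensation band: total width = 2 * half_width mm."""

    half_width: float = 12.0
    weight_mode: str = "linear_ramp"
    inner_cutoff: float = 1.0  # mm; inverse_distance mode: full suppression within

    def __post_init__(self):
        if not self.half_width > 0:
            raise ValueError("half_width must be positive")
        if not 0 < self.inner_cutoff < self.half_width:
            raise ValueError("inner_cutoff must lie in (0, half_width)")
        if self.weight_mode not in ("linear_ramp", "inverse_distance"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")

    def weight(self, abs_x: np.ndarray) -> np.ndarray:
        """Attenuation for cross-hemisphere contributions at |x| from midline.

        Monotone non-decreasing, ~0 at the midline, 1 at the band edge;
        identity (weight 1) outside the band.  linear_ramp: |x| / half_width.
        inverse_distance: interference assumed to fall off as 1/|x|, giving
        keep-weight (1 - c/max(|x|, c)) / (1 - c/half_width) with the inner
        cutoff c (fully suppressed within c of the midline, exactly 1 at the
        band edge).
        """
        abs_x = np.asarray(abs_x, dtype=float)
        if self.weight_mode == "linear_ramp":
            w = abs_x / self.half_width
        else:
            c = self.inner_cutoff
            w = (1.0 - c / np.maximum(abs_x, c)) / (1.0 - c / self.half_width)
        return np.where(abs_x >= self.half_width, 1.0, np.clip(w, 0.0, 1.0))


def _axis_coords(grid: VolumeGrid):
    """Per-axis world coordinates; requires a diagonal (axis-aligned) affine."""
    a = grid.affine
    if np.any(np.abs(a[:3, :3] - np.diag(np.diag(a[:3, :3]))) > 1e-9):
        return None
    return [np.diag(a[:3, :3])[k] * np.arange(grid.shape[k]) + a[k, 3]
            for k in range(3)]


def ma_map(e: FociExperiment, grid: VolumeGrid,
           kernel: Optional[KernelSpec] = None,
           band: Optional[MidlineBand] = None,
           out: Optional[np.ndarray] = None) -> VoxelMap:
    """Modeled-activation map: probabilistic union of per-focus Gaussians.

    Foci outside the grid bounding box are dropped with a warning.  With
    ``band`` set, each focus's contribution to voxels in the *opposite*
    hemisphere inside the midline band is attenuated by the band weight
    (foci exactly on the midline belong to neither hemisphere and are not
    attenuated).  ``out`` optionally supplies a preallocated work array of
    grid shape (contents overwritten) to avoid reallocation in tight loops.
    """
    kernel = kernel or KernelSpec()
    axes = _axis_coords(grid)
    if axes is None:
        raise GridError("ma_map requires an axis-aligned (diagonal) affine")
    xs, ys, zs = axes
    trunc = kernel.truncation_radius
    sigma = kernel.sigma
    peak = kernel.peak(grid.voxel_volume)
    steps = np.abs(np.diag(grid.affine[:3, :3]))

    lo = np.array([xs[0], ys[0], zs[0]]) - steps / 2
    hi = np.array([xs[-1], ys[-1], zs[-1]]) + steps / 2
    inside = np.all((e.foci >= lo) & (e.foci <= hi), axis=1)
    if not inside.all():
        logger.warning("experiment %s: dropped %d foci outside the grid",
                       e.experiment_id, int((~inside).sum()))
    foci = e.foci[inside]

    if out is None:
        one_minus = np.ones(grid.shape)
    else:
        one_minus = out
        one_minus.fill(1.0)
    if foci.shape[0] == 0:
        logger.warning("experiment %s: no foci inside the grid; MA map is zero",
                       e.experiment_id)
        return VoxelMap(grid, 1.0 - one_minus, "MA_probability")

    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    for fx, fy, fz in foci:
        i0, i1 = np.searchsorted(xs, [fx - trunc, fx + trunc])
        j0, j1 = np.searchsorted(ys, [fy - trunc, fy + trunc])
        k0, k1 = np.searchsorted(zs, [fz - trunc, fz + trunc])
        i1, j1, k1 = min(i1 + 1, len(xs)), min(j1 + 1, len(ys)), min(k1 + 1, len(zs))
        dx = xs[i0:i1] - fx
        dy = ys[j0:j1] - fy
        dz = zs[k0:k1] - fz
        d2 = (dx[:, None, None] ** 2 + dy[None, :, None] ** 2
              + dz[None, None, :] ** 2)
        g = np.where(d2 <= trunc * trunc,
                     peak * np.exp(-d2 * inv2s2), 0.0)
        if band is not None and fx != 0.0:
            vx = xs[i0:i1]
            cross = (np.sign(vx) * np.sign(fx) < 0) & (np.abs(vx) < band.half_width)
            if cross.any():
                w = np.ones_like(vx)
                w[cross] = band.weight(np.abs(vx[cross]))
                g *= w[:, None, None]
        one_minus[i0:i1, j0:j1, k0:k1] *= 1.0 - g
    return VoxelMap(grid, 1.0 - one_minus, "MA_probability")


def midline_adjust(ma: VoxelMap, band: MidlineBand, e: FociExperiment,
                   kernel: Optional[KernelSpec] = None) -> VoxelMap:
    """Apply the midline offset adjustment to an experiment's MA map.

    Cross-hemisphere per-focus contributions are attenuated inside the band;
    voxels with |x| >= band.half_width and all same-hemisphere contributions
    are untouched.  The per-focus structure of the probabilistic union is not
    recoverable from the finished map, so the map is rebuilt from the
    experiment's foci with the attenuation applied; ``kernel`` must be the
    kernel the input map was built with (default kernel otherwise).
    """
    return VoxelMap(ma.grid,
                    ma_map(e, ma.grid, kernel or KernelSpec(), band).values,
                    "MA_probability")


def ale_union(mas: Sequence[VoxelMap]) -> VoxelMap:
    """Voxel-wise probabilistic union 1 - prod(1 - MA_e) across experiments.

    Commutative and associative; a single map is returned unchanged and an
    all-zero map is the neutral element.
    """
    if not mas:
        raise ValueError("ale_union needs at least one MA map")
    grid = mas[0].grid
    one_minus = np.ones(grid.shape)
    for m in mas:
        if not m.grid.same_geometry(grid):
            raise GridError("MA maps do not share one grid")
        v = m.values
        if np.any(v < 0) or np.any(v >= 1):
            raise ValueError("MA values must lie in [0, 1)")
        one_minus *= 1.0 - v
    return VoxelMap(grid, 1.0 - one_minus, "ALE")


@dataclasses.dataclass(frozen=True)
class ClusterNull:
    """Permutation null for cluster-level ALE inference."""

    n_permutations: int
    cluster_forming_p: float
    alpha: float
    seed: int
    ale_threshold: float
    cluster_size_threshold: float
    max_cluster_sizes: np.ndarray

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        object.__setattr__(self, "max_cluster_sizes",
                           np.asarray(self.max_cluster_sizes))


def _max_cluster_size(binary: np.ndarray) -> int:
    labeled, n = ndimage.label(binary)
    if n == 0:
        return 0
    return int(np.bincount(labeled.ravel())[1:].max())


def ale_cluster_threshold(ale: VoxelMap, experiments: FociCollection,
                          kernel: Optional[KernelSpec] = None,
                          band: Optional[MidlineBand] = None,
                          cluster_forming_p: float = 0.001,
                          alpha: float = 0.05,
                          n_permutations: int = 1000,
                          seed: int = 0) -> Tuple[VoxelMap, ClusterNull]:
    """Cluster-level thresholding of an ALE map against a permutation null.

    Each permutation redraws every experiment's foci uniformly at in-mask
    voxel centers (foci counts preserved) and recomputes the ALE map.  The
    cluster-forming threshold is the (1 - cluster_forming_p) quantile of the
    pooled permuted in-mask scores; observed suprathreshold clusters are kept
    iff their size exceeds the (1 - alpha) quantile of the permutation
    maximum-cluster-size distribution (alpha >= 1 keeps every suprathreshold
    cluster).  Returns the binary significance mask and the null object.
    """
    kernel = kernel or KernelSpec()
    if n_permutations < 100:
        logger.warning("n_permutations=%d < 100: null quantiles are unstable",
                       n_permutations)
    mask = ale.grid.mask
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise GridError("empty mask: cannot build an ALE null")
    mask_idx = np.argwhere(mask)
    centers = ale.grid.voxel_to_world(mask_idx)

    foci_counts = [e.n_foci for e in experiments]
    perm_scores = np.empty((n_permutations, n_mask), dtype=np.float32)
    work = np.empty(ale.grid.shape)
    ss = np.random.SeedSequence(entropy=seed)
    child_seeds = ss.spawn(n_permutations)
    for p in range(n_permutations):
        rng = np.random.default_rng(child_seeds[p])
        one_minus = np.ones(ale.grid.shape)
        for exp, n_foci in zip(experiments, foci_counts):
            pick = rng.integers(0, n_mask, size=n_foci)
            fake = FociExperiment(exp.experiment_id, exp.space,
                                  centers[pick], exp.n_subjects)
            mam = ma_map(fake, ale.grid, kernel, band, out=work)
            one_minus *= 1.0 - mam.values
        perm_scores[p] = (1.0 - one_minus)[mask]

    ale_thr = float(np.quantile(perm_scores.ravel(), 1.0 - cluster_forming_p))
    max_sizes = np.empty(n_permutations, dtype=int)
    vol = np.zeros(ale.grid.shape, dtype=bool)
    for p in range(n_permutations):
        vol[:] = False
        vol[mask_idx[:, 0], mask_idx[:, 1], mask_idx[:, 2]] = \
            perm_scores[p] > ale_thr
        max_sizes[p] = _max_cluster_size(vol)

    observed = (ale.values > ale_thr) & mask
    labeled, n_clusters = ndimage.label(observed)
    if alpha >= 1.0:
        size_thr = 0.0
        keep_ids = np.arange(1, n_clusters + 1)
    else:
        size_thr = float(np.quantile(max_sizes, 1.0 - alpha))
        sizes = np.bincount(labeled.ravel())
        keep_ids = np.array([cid for cid in range(1, n_clusters + 1)
                             if sizes[cid] > size_thr], dtype=int)
    keep = np.isin(labeled, keep_ids) & (labeled > 0)
    null = ClusterNull(n_permutations, cluster_forming_p, alpha, seed,
                       ale_thr, size_thr, max_sizes)
    return VoxelMap(ale.grid, keep.astype(float), "binary"), null
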