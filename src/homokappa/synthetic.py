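"""Synthetic atlases, co-activation foci, and rest series with known truth.

These generators are the test surface for the whole pipeline: a symmetric
atlas with exactly mirrored left/right parcels, foci collections drawn from
the same Bernoulli co-activation model the kappa estimator assumes (per
homotopic pair, one of the four joint states with probabilities theta1..4),
and 4-D "resting-state" series with a planted mirror-voxel correlation rho.
All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import List, Tuple

import numpy as np
from scipy.signal import lfilter

from .foci import FociCollection, FociExperiment, TAL
from .grid import GridError, VolumeGrid
from .parcellation import Parcellation

logger = logging.getLogger("homokappa")


# ---------------------------------------------------------------------------
# atlases

def gen_synthetic_atlas(n_pairs: int, grid: VolumeGrid, seed: int = 0,
                        style: str = "packed",
                        midline_margin: float = 4.0,
                        region_size_vox: int = 3,
                        min_gap_mm: float = 24.0) -> Parcellation:
    """A symmetric parcellation with ``n_pairs`` exact mirror pairs.

    style="packed"
        The left hemisphere (world x <= -midline_margin, in-mask) is
        partitioned into ``n_pairs`` contiguous blobs by randomized
        multi-source region growing, then mirrored to the right.
    style="spaced"
        ``n_pairs`` compact cubes of side ``region_size_vox`` voxels are
        placed on a left-hemisphere lattice so that any two regions
        (including each region and every mirrored region) are separated by at
        least ``min_gap_mm`` of background.  Use this when region MA
        footprints must not overlap (e.g. estimator-recovery studies).

    Left labels are odd (2i+1), right labels even (2i+2).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    perm = grid.mirror_permutation()
    rng = np.random.default_rng(seed)
    xs = grid.world_x()

    if style == "packed":
        labels = _packed_left_partition(n_pairs, grid, xs, midline_margin, rng)
    elif style == "spaced":
        labels = _spaced_left_cubes(n_pairs, grid, xs, region_size_vox,
                                    min_gap_mm, rng)
    else:
        raise ValueError(f"unknown atlas style {style!r}")

    # mirror left parcels to the right: left label 2i+1 -> right label 2i+2
    mirrored = labels[perm, :, :]
    right = np.where(mirrored > 0, mirrored + 1, 0)
    labels = np.where(labels > 0, labels, right)

    names, pairs = {}, []
    for i in range(n_pairs):
        l, r = 2 * i + 1, 2 * i + 2
        names[l] = f"pair{i:02d}_L"
        names[r] = f"pair{i:02d}_R"
        pairs.append((l, r))
    return Parcellation(grid, labels, names, pairs,
                        provenance=f"synthetic {style} atlas n_pairs={n_pairs} "
                                   f"seed={seed}")


def _packed_left_partition(n_pairs, grid, xs, midline_margin, rng):
    left = grid.mask & (xs[:, None, None] <= -abs(midline_margin))
    coords = np.argwhere(left)
    if coords.shape[0] < n_pairs * 8:
        raise GridError(
            f"grid too small: {coords.shape[0]} left voxels for {n_pairs} "
            "parcels of minimum size 8")
    labels = np.zeros(grid.shape, dtype=np.int32)
    seeds = coords[rng.choice(coords.shape[0], size=n_pairs, replace=False)]
    frontiers: List[List[Tuple[int, int, int]]] = []
    for i, s in enumerate(seeds):
        labels[tuple(s)] = 2 * i + 1
        frontiers.append([tuple(s)])
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1),
               (0, 0, -1)]
    active = list(range(n_pairs))
    while active:
        for i in list(active):
            frontier = frontiers[i]
            grew = False
            while frontier and not grew:
                pick = int(rng.integers(len(frontier)))
                cx, cy, cz = frontier[pick]
                nbrs = []
                for dx, dy, dz in offsets:
                    p = (cx + dx, cy + dy, cz + dz)
                    if (0 <= p[0] < grid.shape[0] and 0 <= p[1] < grid.shape[1]
                            and 0 <= p[2] < grid.shape[2]
                            and left[p] and labels[p] == 0):
                        nbrs.append(p)
                if not nbrs:
                    frontier[pick] = frontier[-1]
                    frontier.pop()
                    continue
                q = nbrs[int(rng.integers(len(nbrs)))]
                labels[q] = 2 * i + 1
                frontier.append(q)
                grew = True
            if not frontier:
                active.remove(i)
    return labels


def _spaced_left_cubes(n_pairs, grid, xs, region_size_vox, min_gap_mm, rng):
    vs = grid.voxel_size
    half = (region_size_vox - 1) / 2.0
    step_vox = region_size_vox + np.ceil(min_gap_mm / vs).astype(int)
    # candidate cube-center indices per axis
    ny, nz = grid.shape[1], grid.shape[2]
    ys_c = np.arange(int(np.ceil(half)), ny - int(np.ceil(half)), step_vox[1])
    zs_c = np.arange(int(np.ceil(half)), nz - int(np.ceil(half)), step_vox[2])
    # x centers: cube's rightmost face must sit at world x <= -min_gap_mm/2
    xc = []
    i = int(np.ceil(half))
    while i + half < grid.shape[0]:
        face_x = xs[min(int(i + half), grid.shape[0] - 1)] + vs[0] / 2
        if face_x <= -min_gap_mm / 2.0:
            xc.append(i)
        i += step_vox[0]
    candidates = [(ix, iy, iz) for ix in xc for iy in ys_c for iz in zs_c]
    if len(candidates) < n_pairs:
        raise GridError(
            f"grid too small: only {len(candidates)} spaced cube positions "
            f"for {n_pairs} pairs (cube {region_size_vox} vox, gap "
            f"{min_gap_mm} mm)")
    order = rng.permutation(len(candidates))[:n_pairs]
    labels = np.zeros(grid.shape, dtype=np.int32)
    r = region_size_vox
    lo = int(np.floor(half))
    for i, ci in enumerate(order):
        cx, cy, cz = candidates[ci]
        labels[cx - lo:cx - lo + r, cy - lo:cy - lo + r, cz - lo:cz - lo + r] \
            = 2 * i + 1
    return labels


# ---------------------------------------------------------------------------
# co-activation foci

@dataclasses.dataclass(frozen=True)
class CoactivationSpec:
    """Bernoulli co-activation model parameters.

    ``pair_thetas`` is a probability 4-vector (theta1..theta4: both, left
    only, right only, neither) or one such vector per homotopic pair.
    """

    pair_thetas: np.ndarray
    n_experiments: int
    foci_per_active_region: int = 1
    seed: int = 0

    def __post_init__(self):
        t = np.atleast_2d(np.asarray(self.pair_thetas, dtype=float))
        if t.shape[1] != 4 or np.any(t < 0):
            raise ValueError("pair_thetas must be nonnegative 4-vectors")
        if np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each theta 4-vector must sum to 1 within 1e-9")
        if self.n_experiments < 1 or self.foci_per_active_region < 1:
            raise ValueError("n_experiments and foci_per_active_region "
                             "must be positive")
        object.__setattr__(self, "pair_thetas", t)


def gen_coactivation_experiments(spec: CoactivationSpec, atlas: Parcellation,
                                 return_states: bool = False):
    """Draw experiments from the Bernoulli co-activation model.

    Per experiment and homotopic pair, one of the four joint states is drawn
    with that pair's (theta1..theta4); each active region then receives
    ``foci_per_active_region`` foci uniformly over its voxel centers.
    Experiments in which no region activates report no foci and are omitted
    from the collection (their count is recorded in the provenance; at the
    default thetas this affects well under 1% of experiments).

    With ``return_states``, also returns the (n_experiments, n_pairs) state
    array (0 = both, 1 = left only, 2 = right only, 3 = neither) including
    the omitted experiments.
    """
    n_pairs = len(atlas.pairs)
    if n_pairs == 0:
        raise ValueError("atlas has no homotopic pairs")
    thetas = spec.pair_thetas
    if thetas.shape[0] == 1:
        thetas = np.repeat(thetas, n_pairs, axis=0)
    if thetas.shape[0] != n_pairs:
        raise ValueError(
            f"got {thetas.shape[0]} theta vectors for {n_pairs} pairs")

    rng = np.random.default_rng(spec.seed)
    n = spec.n_experiments
    states = np.empty((n, n_pairs), dtype=np.int8)
    u = rng.random((n, n_pairs))
    for p in range(n_pairs):
        states[:, p] = np.searchsorted(np.cumsum(thetas[p])[:3], u[:, p],
                                       side="right")

    region_centers = {}
    for (l, r) in atlas.pairs:
        for lab in (l, r):
            coords = np.argwhere(atlas.labels == lab)
            if coords.shape[0] == 0:
                raise ValueError(f"atlas pair region {lab} is empty")
            region_centers[lab] = atlas.grid.voxel_to_world(coords)

    k = spec.foci_per_active_region
    experiments = []
    n_empty = 0
    for i in range(n):
        pts = []
        for p, (l, r) in enumerate(atlas.pairs):
            s = states[i, p]
            if s in (0, 1):  # left active
                c = region_centers[l]
                pts.append(c[rng.integers(0, c.shape[0], size=k)])
            if s in (0, 2):  # right active
                c = region_centers[r]
                pts.append(c[rng.integers(0, c.shape[0], size=k)])
        if not pts:
            n_empty += 1
            continue
        experiments.append(FociExperiment(
            f"synthetic_{i + 1:05d}", TAL, np.vstack(pts)))

    coll = FociCollection(
        experiments,
        provenance=f"bernoulli co-activation seed={spec.seed} "
                   f"n={n} omitted_empty={n_empty}")
    if return_states:
        return coll, states
    return coll


# ---------------------------------------------------------------------------
# rest series

@dataclasses.dataclass(frozen=True)
class RestSpec:
    """Planted-correlation rest-series parameters.

    ``homotopic_rho`` is the target population Pearson correlation between
    every mirror voxel pair (scalar or per-voxel field, sign allowed);
    ``n_timepoints`` defaults to a 7.5-minute TR-2s acquisition (225 volumes).
    ``ar_coeff`` optionally adds AR(1) temporal smoothness (applied to both
    members of a pair, leaving the contemporaneous correlation unchanged).
    """

    n_timepoints: int = 225
    homotopic_rho: float | np.ndarray = 0.0
    noise_sd: float = 1.0
    ar_coeff: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        rho = np.asarray(self.homotopic_rho, dtype=float)
        if np.any(np.abs(rho) > 1.0):
            raise ValueError("|rho| must be <= 1 everywhere")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ValueError("ar_coeff must be in [0, 1)")


def gen_rest_timeseries(spec: RestSpec, grid: VolumeGrid) -> np.ndarray:
    """4-D series (nx, ny, nz, T) with mirror correlation = planted rho.

    Each mirror pair (v, v-bar) shares a latent signal mixed so that the
    population correlation between the pair equals rho at that voxel:
    left = sqrt(|rho|) s + sqrt(1-|rho|) e1, right = sign(rho) sqrt(|rho|) s
    + sqrt(1-|rho|) e2, all unit variance, scaled by noise_sd.  Midline
    voxels (their own mirror) receive plain noise.
    """
    perm = grid.mirror_permutation()
    rho = np.broadcast_to(np.asarray(spec.homotopic_rho, dtype=float),
                          grid.shape)
    rng = np.random.default_rng(spec.seed)
    T = spec.n_timepoints
    nx = grid.shape[0]

    out = np.empty(grid.shape + (T,))
    xs = grid.world_x()
    left_slabs = np.where(xs < 0)[0]
    mid_slabs = np.where(xs == 0)[0]

    for i in left_slabs:
        j = perm[i]
        shape2d = grid.shape[1:]
        nvox = int(np.prod(shape2d))
        s = rng.standard_normal((nvox, T))
        e1 = rng.standard_normal((nvox, T))
        e2 = rng.standard_normal((nvox, T))
        r = rho[i].reshape(nvox, 1)
        a = np.sqrt(np.abs(r))
        b = np.sqrt(1.0 - np.abs(r))
        left = a * s + b * e1
        right = np.sign(r) * a * s + b * e2
        out[i] = left.reshape(shape2d + (T,))
        out[j] = right.reshape(shape2d + (T,))
    for i in mid_slabs:
        nvox = int(np.prod(grid.shape[1:]))
        out[i] = rng.standard_normal((nvox, T)).reshape(grid.shape[1:] + (T,))

    if spec.ar_coeff > 0:
        phi = spec.ar_coeff
        flat = out.reshape(-1, T)
        flat = lfilter([1.0], [1.0, -phi], flat, axis=1) * np.sqrt(1 - phi * phi)
        out = flat.reshape(grid.shape + (T,))
    return out * spec.noise_sd
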