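"""Voxel-mirrored homotopic connectivity and map-comparison machinery.

VMHC is the Pearson correlation between each in-mask voxel's resting-state
time series and the series of its mirror voxel across the midline, Fisher
z-transformed (atanh, with |r| clipped at 1 - 1e-7).  No spatial smoothing is
applied anywhere.

The comparison arm quantifies agreement between an MHC (kappa) map and a VMHC
(Fisher-z) map: global Pearson correlation over a shared brain mask, the
leave-one-voxel-out contribution analysis (VCC: r_global minus r with voxel
pair i removed, computed by exact sufficient-statistic downdating, then
z-normalized over the mask), and the z-standardized difference map MHC - VMHC
whose positive values mark MHC-dominant voxels.  Non-brain voxels never enter
any statistic.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .grid import GridError, VolumeGrid, VoxelMap

logger = logging.getLogger("homokappa")

#: |r| clip before atanh, to keep Fisher z finite
R_CLIP = 1.0 - 1e-7


def fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def vmhc(series: np.ndarray, grid: VolumeGrid) -> VoxelMap:
    """Per-voxel mirror correlation of a 4-D series, Fisher z-transformed.

    ``series`` is (nx, ny, nz, T) on a mirror-closed grid; the correlation at
    voxel v uses only v and its x-mirror, and the output is exactly symmetric
    (v and its mirror carry the same value).  Voxels with a constant series
    at either end of the pair become missing (excluded from the output mask),
    as do voxels whose mirror falls outside the input mask.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 4 or series.shape[:3] != grid.shape:
        raise GridError("series must be (nx, ny, nz, T) matching the grid")
    if series.shape[3] < 3:
        raise ValueError("need at least 3 timepoints")
    perm = grid.mirror_permutation()
    mask = grid.mask & grid.mask[perm, :, :]

    x = series - series.mean(axis=3, keepdims=True)
    sd = np.sqrt((x ** 2).sum(axis=3))
    y = x[perm, :, :, :]
    sdm = sd[perm, :, :]
    num = (x * y).sum(axis=3)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / (sd * sdm)
    constant = (sd == 0) | (sdm == 0)
    valid = mask & ~constant
    if (mask & constant).any():
        logger.warning("vmhc: %d in-mask voxels have a constant series at "
                       "themselves or their mirror; set missing",
                       int((mask & constant).sum()))
    values = np.zeros(grid.shape)
    values[valid] = fisher_z(r[valid])
    return VoxelMap(grid.with_mask(valid), values, "fisher_z")


def group_average(z_maps: Sequence[VoxelMap]) -> VoxelMap:
    """Voxel-wise mean across subject maps, per-voxel mask-aware.

    A voxel's average uses only the maps in which it is in-mask; the output
    mask keeps voxels present in at least one input.
    """
    if not z_maps:
        raise ValueError("group_average needs at least one map")
    grid = z_maps[0].grid
    total = np.zeros(grid.shape)
    count = np.zeros(grid.shape)
    for m in z_maps:
        if not m.grid.same_geometry(grid):
            raise GridError("maps do not share one grid")
        total[m.grid.mask] += m.values[m.grid.mask]
        count[m.grid.mask] += 1
    mask = count > 0
    values = np.zeros(grid.shape)
    values[mask] = total[mask] / count[mask]
    return VoxelMap(grid.with_mask(mask), values, z_maps[0].value_kind)


def zscore_map(m: VoxelMap, mask: Optional[np.ndarray] = None) -> VoxelMap:
    """Standardize a map to mean 0, SD 1 over the (given or own) mask."""
    mask = m.grid.mask if mask is None else (np.asarray(mask, bool) & m.grid.mask)
    vals = m.values[mask]
    if vals.size < 2:
        raise ValueError("zscore_map needs at least 2 in-mask voxels")
    sd = vals.std()
    if sd == 0:
        raise ValueError("zscore_map: zero variance inside the mask")
    out = np.zeros(m.grid.shape)
    out[mask] = (vals - vals.mean()) / sd
    return VoxelMap(m.grid.with_mask(mask), out, "zscore")


@dataclasses.dataclass(frozen=True)
class ComparisonInput:
    """An MHC map, a VMHC map, and the shared brain mask they agree on."""

    map_a: VoxelMap  # MHC (kappa values)
    map_b: VoxelMap  # VMHC (Fisher z values)
    mask: np.ndarray

    def __post_init__(self):
        if not self.map_a.grid.same_geometry(self.map_b.grid):
            raise GridError("comparison maps must share one grid")
        mask = (np.asarray(self.mask, dtype=bool)
                & self.map_a.grid.mask & self.map_b.grid.mask)
        object.__setattr__(self, "mask", mask)

    @property
    def vectors(self) -> Tuple[np.ndarray, np.ndarray]:
        return self.map_a.values[self.mask], self.map_b.values[self.mask]


def map_correlation(ci: ComparisonInput) -> float:
    """Pearson r between the two maps over the shared mask."""
    x, y = ci.vectors
    if x.size < 3:
        raise ValueError("map_correlation needs at least 3 shared voxels")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("map_correlation: zero variance in a map")
    return float(np.corrcoef(x, y)[0, 1])


@dataclasses.dataclass(frozen=True)
class VCCMap:
    """Leave-one-voxel-out contribution to the global map correlation."""

    r_global: float
    map: VoxelMap                  # normalized contributions (z-scored)
    raw_delta: np.ndarray          # r_global - r_removed, in-mask vector
    normalization: str = "z-score over mask, sign preserved"


def vcc(ci: ComparisonInput) -> VCCMap:
    """Voxels' contribution to correlation, by exact one-pass downdating.

    For every in-mask voxel i the Pearson r is recomputed with observation i
    removed, via downdated sufficient statistics (n, sum x, sum y, sum x^2,
    sum y^2, sum xy) — algebraically identical to naive recomputation.  The
    per-voxel contribution r_global - r_removed is then z-scored over the
    mask (sign preserved: positive = convergence-driving voxel).  Removals
    that zero out the remaining variance yield missing values.
    """
    x, y = ci.vectors
    n = x.size
    if n < 4:
        raise ValueError("vcc needs at least 4 shared voxels")
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    cov_all = sxy - sx * sy / n
    vx_all = sxx - sx * sx / n
    vy_all = syy - sy * sy / n
    if vx_all <= 0 or vy_all <= 0:
        raise ValueError("vcc: zero variance in a map")
    r_global = cov_all / np.sqrt(vx_all * vy_all)

    m = n - 1
    cov_i = (sxy - x * y) - (sx - x) * (sy - y) / m
    vx_i = (sxx - x * x) - (sx - x) ** 2 / m
    vy_i = (syy - y * y) - (sy - y) ** 2 / m
    with np.errstate(invalid="ignore", divide="ignore"):
        r_i = cov_i / np.sqrt(vx_i * vy_i)
    bad = (vx_i <= 0) | (vy_i <= 0)
    delta = r_global - r_i
    delta[bad] = np.nan

    finite = np.isfinite(delta)
    if finite.sum() < 2 or np.nanstd(delta) == 0:
        norm = np.zeros_like(delta)
    else:
        norm = (delta - np.nanmean(delta)) / np.nanstd(delta)

    values = np.zeros(ci.map_a.grid.shape)
    out_mask = ci.mask.copy()
    idx = np.argwhere(ci.mask)
    values[tuple(idx[finite].T)] = norm[finite]
    if (~finite).any():
        out_mask[tuple(idx[~finite].T)] = False
    grid = ci.map_a.grid.with_mask(out_mask)
    return VCCMap(float(r_global), VoxelMap(grid, values, "vcc"), delta)


def difference_map(ci: ComparisonInput) -> VoxelMap:
    """z(MHC) - z(VMHC): positive where the meta-analytic map dominates.

    Both maps are z-scored over the shared mask internally, making the two
    statistics (kappa and Fisher z) comparable before subtraction.
    """
    za = zscore_map(ci.map_a, ci.mask)
    zb = zscore_map(ci.map_b, ci.mask)
    values = np.zeros(ci.map_a.grid.shape)
    values[ci.mask] = za.values[ci.mask] - zb.values[ci.mask]
    return VoxelMap(ci.map_a.grid.with_mask(ci.mask), values, "difference")


def threshold_to_roi(m: VoxelMap, cutoff: float = 1.0,
                     manual_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Binary ROI of voxels with value strictly greater than ``cutoff``.

    Restricted to the map's mask and, when given, intersected with a manually
    drawn mask.  An empty result is returned with a warning, not an error.
    """
    roi = (m.values > cutoff) & m.grid.mask
    if manual_mask is not None:
        roi &= np.asarray(manual_mask, dtype=bool)
    if not roi.any():
        logger.warning("threshold_to_roi: empty ROI at cutoff %g", cutoff)
    return roi


def domain_enrichment(roi: np.ndarray, foci_xyz: np.ndarray,
                      domains: Sequence[str], grid: VolumeGrid,
                      z_cutoff: float = 3.0) -> pd.DataFrame:
    """Behavioral-domain enrichment of an ROI by a binomial z statistic.

    Each focus carries a domain label.  With n_d foci in domain d, k_d of
    them inside the ROI, and base rate p0 = (all foci inside ROI)/(all foci),
    the enrichment is z_d = (k_d - n_d p0) / sqrt(n_d p0 (1 - p0)).  Rows are
    sorted by z descending; ``enriched`` flags z >= z_cutoff.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("domain_enrichment: empty ROI")
    foci_xyz = np.atleast_2d(np.asarray(foci_xyz, dtype=float))
    domains = np.asarray(domains)
    if foci_xyz.shape[0] != domains.shape[0]:
        raise ValueError("one domain label per focus required")
    ijk = np.rint(grid.world_to_voxel(foci_xyz)).astype(int)
    on_grid = np.all((ijk >= 0) & (ijk < np.asarray(grid.shape)), axis=1)
    inside = np.zeros(len(domains), dtype=bool)
    inside[on_grid] = roi[tuple(ijk[on_grid].T)]

    n_total = len(domains)
    p0 = inside.sum() / n_total
    if p0 in (0.0, 1.0):
        raise ValueError(
            f"domain_enrichment: base rate p0={p0}; z undefined "
            "(ROI covers none or all foci)")
    rows = []
    for d in pd.unique(domains):
        sel = domains == d
        n_d = int(sel.sum())
        if n_d == 0:
            continue
        k_d = int(inside[sel].sum())
        z = (k_d - n_d * p0) / np.sqrt(n_d * p0 * (1.0 - p0))
        rows.append({"domain": d, "n_foci": n_d, "n_in_roi": k_d,
                     "z": float(z), "enriched": bool(z >= z_cutoff)})
    df = pd.DataFrame(rows).sort_values("z", ascending=False,
                                        ignore_index=True)
    return df
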