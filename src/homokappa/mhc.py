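"""Meta-analytic homotopic connectivity: activation matrix and Patel's kappa.

The estimator works on a binary N x M activation matrix (rows = experiments,
columns = atlas regions): a region counts as activated in an experiment when
at least a given fraction (default 20%) of its voxels are significant in that
experiment's MA map.  For a homotopic pair (a, b) the four joint activation
states have probabilities

    theta1 = P(a=1, b=1),  theta2 = P(a=1, b=0),
    theta3 = P(a=0, b=1),  theta4 = P(a=0, b=0),

and Patel's kappa measures excess co-activation over independence, normalized
by the attainable range given the marginals:

    E         = (theta1 + theta2) * (theta1 + theta3)
    max_t1    = min(theta1 + theta2, theta1 + theta3)
    min_t1    = max(0, 2*theta1 + theta2 + theta3 - 1)
    D         = 1 if theta1 >= E else 0
    kappa     = (theta1 - E) / (D*(max_t1 - E) + (1 - D)*(E - min_t1))

so kappa lies in [-1, 1], equals 1 at the maximal attainable co-activation,
0 at exact independence and -1 at maximal avoidance.  Significance is
Bayesian: thetas are given a flat Dirichlet prior, the posterior is
Dirichlet(counts + 1), and Monte-Carlo sampling estimates P(kappa > e | data).

Degenerate marginals (a region never or always active) leave kappa undefined;
such pairs carry NaN and a flag, never a numeric placeholder.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ale import KernelSpec, MidlineBand, ma_map
from .foci import FociCollection
from .grid import VoxelMap
from .parcellation import Parcellation

logger = logging.getLogger("homokappa")


# ---------------------------------------------------------------------------
# activation matrix

@dataclasses.dataclass(frozen=True)
class ActivationMatrix:
    """Binary experiments x regions matrix under the fractional-activation rule."""

    values: np.ndarray  # (N, M) uint8
    experiment_ids: Sequence[str]
    region_labels: Sequence[int]
    fraction_threshold: float
    ma_significance_rule: str = "MA > 0 (within kernel truncation of a focus)"

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2 or not np.isin(v, (0, 1)).all():
            raise ValueError("activation matrix must be binary 2-D")
        object.__setattr__(self, "values", v.astype(np.uint8))
        object.__setattr__(self, "experiment_ids", tuple(self.experiment_ids))
        object.__setattr__(self, "region_labels",
                           tuple(int(l) for l in self.region_labels))
        if len(self.experiment_ids) != v.shape[0]:
            raise ValueError("experiment_ids length mismatch")
        if len(self.region_labels) != v.shape[1]:
            raise ValueError("region_labels length mismatch")

    def column(self, label: int) -> np.ndarray:
        return self.values[:, self.region_labels.index(int(label))]

    @property
    def n_experiments(self) -> int:
        return self.values.shape[0]


def _region_bookkeeping(atlas: Parcellation):
    labels_flat = atlas.labels.ravel()
    region_labels = [int(l) for l in atlas.label_ids]
    minlength = int(atlas.labels.max()) + 1
    sizes = np.bincount(labels_flat, minlength=minlength)
    return labels_flat, region_labels, sizes, minlength


def _active_row(active_flat: np.ndarray, labels_flat, sizes, minlength,
                region_labels, fraction_threshold: float) -> np.ndarray:
    counts = np.bincount(labels_flat[active_flat], minlength=minlength)
    counts = counts[region_labels]
    rsizes = sizes[region_labels]
    if fraction_threshold <= 0.0:
        return (counts >= 1).astype(np.uint8)
    return (counts >= fraction_threshold * rsizes - 1e-12).astype(np.uint8)


def activation_matrix(mas: Iterable[VoxelMap], atlas: Parcellation,
                      fraction_threshold: float = 0.20,
                      experiment_ids: Optional[Sequence[str]] = None,
                      abs_cutoff: float = 0.0) -> ActivationMatrix:
    """Build the N x M activation matrix from per-experiment MA maps.

    Entry (e, r) is 1 iff the fraction of region r's voxels that are
    MA-significant for experiment e is >= ``fraction_threshold`` (inclusive);
    a threshold of 0 means "at least one significant voxel".  The default
    significance predicate is MA value > 0, i.e. the voxel lies within the
    truncated kernel of some focus; ``abs_cutoff`` substitutes an absolute MA
    cutoff.
    """
    if not 0.0 <= fraction_threshold <= 1.0:
        raise ValueError("fraction_threshold must be in [0, 1]")
    labels_flat, region_labels, sizes, minlength = _region_bookkeeping(atlas)
    rows, ids = [], []
    for i, m in enumerate(mas):
        if not m.grid.same_geometry(atlas.grid):
            raise ValueError("MA map grid does not match atlas grid")
        active = (m.values.ravel() > abs_cutoff)
        rows.append(_active_row(active, labels_flat, sizes, minlength,
                                region_labels, fraction_threshold))
        ids.append(f"experiment_{i + 1:04d}")
    if experiment_ids is not None:
        ids = list(experiment_ids)
    rule = (f"MA > {abs_cutoff}" if abs_cutoff > 0
            else "MA > 0 (within kernel truncation of a focus)")
    return ActivationMatrix(np.asarray(rows, dtype=np.uint8), ids,
                            region_labels, fraction_threshold, rule)


def activation_matrix_from_foci(collection: FociCollection,
                                atlas: Parcellation,
                                kernel: Optional[KernelSpec] = None,
                                band: Optional[MidlineBand] = None,
                                fraction_threshold: float = 0.20,
                                abs_cutoff: float = 0.0) -> ActivationMatrix:
    """MA maps -> fractional-activation rule, streaming one experiment at a time.

    Identical to building every MA map and calling :func:`activation_matrix`,
    but MA maps are consumed as they are produced, so memory stays flat for
    large collections.
    """
    if not 0.0 <= fraction_threshold <= 1.0:
        raise ValueError("fraction_threshold must be in [0, 1]")
    kernel = kernel or KernelSpec()
    labels_flat, region_labels, sizes, minlength = _region_bookkeeping(atlas)
    work = np.empty(atlas.grid.shape)
    rows, ids = [], []
    for e in collection:
        m = ma_map(e, atlas.grid, kernel, band, out=work)
        active = (m.values.ravel() > abs_cutoff)
        rows.append(_active_row(active, labels_flat, sizes, minlength,
                                region_labels, fraction_threshold))
        ids.append(e.experiment_id)
    rule = (f"MA > {abs_cutoff}" if abs_cutoff > 0
            else "MA > 0 (within kernel truncation of a focus)")
    return ActivationMatrix(np.asarray(rows, dtype=np.uint8), ids,
                            region_labels, fraction_threshold, rule)


# ---------------------------------------------------------------------------
# contingency and kappa

@dataclasses.dataclass(frozen=True)
class ContingencyTheta:
    """Joint activation counts and probabilities for one region pair."""

    counts: Tuple[int, int, int, int]  # (n11, n10, n01, n00)

    def __post_init__(self):
        c = tuple(int(x) for x in self.counts)
        if len(c) != 4 or any(x < 0 for x in c):
            raise ValueError("counts must be 4 nonnegative integers")
        if sum(c) == 0:
            raise ValueError("contingency needs at least one experiment")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        return sum(self.counts)

    @property
    def thetas(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / self.n

    @property
    def E(self) -> float:
        t1, t2, t3, _ = self.thetas
        return (t1 + t2) * (t1 + t3)

    @property
    def theta1_max(self) -> float:
        t1, t2, t3, _ = self.thetas
        return min(t1 + t2, t1 + t3)

    @property
    def theta1_min(self) -> float:
        t1, t2, t3, _ = self.thetas
        return max(0.0, 2.0 * t1 + t2 + t3 - 1.0)

    @property
    def D(self) -> int:
        return 1 if self.thetas[0] >= self.E else 0

    @property
    def degenerate(self) -> bool:
        """True when either region is never or always active."""
        t1, t2, t3, t4 = self.thetas
        pa, pb = t1 + t2, t1 + t3
        return pa in (0.0, 1.0) or pb in (0.0, 1.0)


def contingency(m: ActivationMatrix, pair: Tuple[int, int]) -> ContingencyTheta:
    """Tally joint activation counts of a region pair over experiments."""
    a = m.column(pair[0]).astype(bool)
    b = m.column(pair[1]).astype(bool)
    if a.size == 0:
        raise ValueError("activation matrix has no experiments")
    n11 = int((a & b).sum())
    n10 = int((a & ~b).sum())
    n01 = int((~a & b).sum())
    n00 = int((~a & ~b).sum())
    return ContingencyTheta((n11, n10, n01, n00))


def kappa_from_theta(thetas) -> float:
    """Patel's kappa evaluated on a probability 4-vector (closed form).

    Returns NaN for degenerate marginals (zero attainable range).
    """
    return float(_kappa_vectorized(np.asarray(thetas, dtype=float)[None, :])[0])


def _kappa_vectorized(thetas: np.ndarray) -> np.ndarray:
    """kappa for (n, 4) theta arrays; NaN where the denominator vanishes."""
    t1, t2, t3 = thetas[:, 0], thetas[:, 1], thetas[:, 2]
    E = (t1 + t2) * (t1 + t3)
    tmax = np.minimum(t1 + t2, t1 + t3)
    tmin = np.maximum(0.0, 2.0 * t1 + t2 + t3 - 1.0)
    D = (t1 >= E)
    denom = np.where(D, tmax - E, E - tmin)
    out = np.full(thetas.shape[0], np.nan)
    ok = denom > 0
    out[ok] = (t1[ok] - E[ok]) / denom[ok]
    # exact independence with degenerate range still means kappa = 0 only
    # when the numerator is 0 and the range is 0 on the *other* side; leave
    # zero-denominator cases as NaN (undefined), per the degeneracy contract.
    return out


def patel_kappa(c: ContingencyTheta) -> float:
    """Patel's kappa for one contingency; NaN (flagged) when degenerate."""
    if c.degenerate:
        return float("nan")
    return kappa_from_theta(c.thetas)


# ---------------------------------------------------------------------------
# Monte-Carlo significance

@dataclasses.dataclass(frozen=True)
class KappaResult:
    """Point estimate plus Bayesian Monte-Carlo significance for one pair."""

    kappa: float
    posterior_prob_exceeds: float
    e: float
    n_mc: int
    seed: int
    significant: bool
    degenerate: bool = False
    unreliable: bool = False
    n_skipped: int = 0
    contingency: Optional[ContingencyTheta] = None

    @property
    def missing(self) -> bool:
        return self.degenerate or not np.isfinite(self.kappa)


def kappa_significance(c: ContingencyTheta, e: float = 0.0,
                       n_mc: int = 10_000, seed: int = 0,
                       credibility: float = 0.95) -> KappaResult:
    """Posterior probability that kappa exceeds ``e``, by Dirichlet sampling.

    The posterior over (theta1..theta4) under a flat prior is
    Dirichlet(counts + 1); ``n_mc`` draws give P(kappa > e | data), and the
    pair is declared significant when that probability reaches the
    credibility level.  Samples with a vanishing denominator are skipped and
    counted; if more than half are skipped the result is flagged unreliable.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    rng = np.random.default_rng(seed)
    alpha = np.asarray(c.counts, dtype=float) + 1.0
    draws = rng.dirichlet(alpha, size=n_mc)
    kappas = _kappa_vectorized(draws)
    valid = np.isfinite(kappas)
    n_skipped = int((~valid).sum())
    if valid.sum() == 0:
        posterior = float("nan")
    else:
        posterior = float((kappas[valid] > e).mean())
    point = patel_kappa(c)
    unreliable = n_skipped > n_mc // 2
    significant = bool(np.isfinite(posterior) and posterior >= credibility
                       and not unreliable)
    return KappaResult(point, posterior, e, n_mc, seed, significant,
                       degenerate=c.degenerate, unreliable=unreliable,
                       n_skipped=n_skipped, contingency=c)


def compute_pair_kappas(m: ActivationMatrix, atlas: Parcellation,
                        e: float = 0.0, n_mc: int = 10_000, seed: int = 0,
                        credibility: float = 0.95
                        ) -> Dict[Tuple[int, int], KappaResult]:
    """Patel's kappa with Monte-Carlo significance for every homotopic pair."""
    results: Dict[Tuple[int, int], KappaResult] = {}
    ss = np.random.SeedSequence(entropy=seed)
    children = ss.spawn(len(atlas.pairs))
    for child, pair in zip(children, atlas.pairs):
        c = contingency(m, pair)
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        results[pair] = kappa_significance(c, e=e, n_mc=n_mc, seed=sub_seed,
                                           credibility=credibility)
    return results


# ---------------------------------------------------------------------------
# rendering and export

def mhc_map(kappas: Dict[Tuple[int, int], KappaResult | float],
            atlas: Parcellation, significant_only: bool = False) -> VoxelMap:
    """Paint each pair's kappa onto both of its regions.

    Pairs with missing (degenerate) kappa render as background and are
    excluded from the output mask; with ``significant_only`` non-significant
    pairs are masked out as well.  The result is left/right symmetric by
    construction.
    """
    values = np.zeros(atlas.grid.shape)
    mask = np.zeros(atlas.grid.shape, dtype=bool)
    for pair, res in kappas.items():
        k = res.kappa if isinstance(res, KappaResult) else float(res)
        if not np.isfinite(k):
            continue
        if significant_only and isinstance(res, KappaResult) and not res.significant:
            continue
        region = np.isin(atlas.labels, pair)
        values[region] = k
        mask |= region
    return VoxelMap(atlas.grid.with_mask(mask), values, "kappa")


def region_kappa_table(kappas: Dict[Tuple[int, int], KappaResult],
                       atlas: Parcellation) -> pd.DataFrame:
    """One row per homotopic pair, sorted by kappa descending (missing last)."""
    rows: List[dict] = []
    for (l, r), res in kappas.items():
        c = res.contingency
        row = {
            "left_label": l, "right_label": r,
            "left_name": atlas.name_of(l), "right_name": atlas.name_of(r),
            "n11": c.counts[0] if c else np.nan,
            "n10": c.counts[1] if c else np.nan,
            "n01": c.counts[2] if c else np.nan,
            "n00": c.counts[3] if c else np.nan,
        }
        if c is not None:
            t = c.thetas
            row.update(theta1=t[0], theta2=t[1], theta3=t[2], theta4=t[3],
                       E=c.E)
        row.update(kappa=res.kappa,
                   posterior_prob_exceeds=res.posterior_prob_exceeds,
                   significant=res.significant, degenerate=res.degenerate)
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values("kappa", ascending=False, na_position="last",
                          ignore_index=True)


def write_kappa_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_kappa_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
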