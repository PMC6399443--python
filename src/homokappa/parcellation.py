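"""Symmetric brain parcellations and homotopic pair bookkeeping.

A :class:`Parcellation` is an integer label field on a :class:`~homokappa.grid.VolumeGrid`
(0 = background) with a name table and an explicit homotopic pair table
(left label <-> right label).  For a *symmetric* parcellation, the voxel set
of each left label maps exactly onto its right partner under mirroring about
the midline, which is what makes region-level homotopic statistics exact.

Also implemented here are the two control constructions: symmetrization of an
arbitrary (possibly asymmetric) anatomical atlas, and Fornito-style
homogeneous random parcellations in which every parcel has the same number of
voxels ``k`` (grown 6-connected inside each anatomical region, then mirrored).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .grid import GridError, VolumeGrid

logger = logging.getLogger("homokappa")


class ParcellationError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class Parcellation:
    """Labeled volume plus homotopic pair table.

    ``pairs`` lists (left_label, right_label); labels absent from any pair are
    treated as unpaired midline/background structures.
    """

    grid: VolumeGrid
    labels: np.ndarray  # int array, 0 = background
    names: Dict[int, str] = dataclasses.field(default_factory=dict)
    pairs: Sequence[Tuple[int, int]] = ()
    provenance: str = ""

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.shape != self.grid.shape:
            raise ParcellationError("labels shape does not match grid")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.allclose(labels, np.rint(labels)):
                raise ParcellationError("labels must be integers")
            labels = np.rint(labels).astype(np.int32)
        object.__setattr__(self, "labels", labels.astype(np.int32))
        object.__setattr__(self, "pairs", tuple((int(a), int(b))
                                                for a, b in self.pairs))

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids != 0]

    def region_size(self, label: int) -> int:
        return int((self.labels == label).sum())

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def name_of(self, label: int) -> str:
        return self.names.get(int(label), f"region_{int(label)}")


# ---------------------------------------------------------------------------
# homotopic pairing

def homotopic_pairs(p: Parcellation) -> List[Tuple[int, int]]:
    """Recover the left<->right pair table from geometry alone.

    Each label whose voxels lie in the left hemisphere (world x < 0) is
    matched to the label occupying exactly its mirrored voxel set.  Raises if
    any left region's mirror is not a single right label (the parcellation is
    then not truly symmetric).
    """
    perm = p.grid.mirror_permutation()
    mirrored = p.labels[perm, :, :]
    xs = p.grid.world_x()
    pairs: List[Tuple[int, int]] = []
    for lab in p.label_ids:
        mask = p.labels == lab
        region_x = xs[np.any(mask, axis=(1, 2))]
        if region_x.size == 0 or region_x.max() >= 0:
            continue  # not a purely left-hemisphere label
        partner = np.unique(mirrored[mask])
        if partner.size != 1 or partner[0] == 0:
            raise ParcellationError(
                f"label {lab}: mirrored voxel set is not a single right-"
                f"hemisphere label (found {partner.tolist()}); atlas is not "
                "mirror-symmetric")
        # verify exact set equality, not mere coverage
        rlab = int(partner[0])
        if p.region_size(rlab) != int(mask.sum()):
            raise ParcellationError(
                f"labels {lab}/{rlab}: mirrored voxel sets differ in size")
        pairs.append((int(lab), rlab))
    if not pairs:
        raise ParcellationError("no left-hemisphere labels found to pair")
    return pairs


def validate_symmetry(p: Parcellation) -> None:
    """Check that each recorded pair is an exact mirror pair."""
    perm = p.grid.mirror_permutation()
    mirrored = p.labels[perm, :, :]
    for left, right in p.pairs:
        if not np.array_equal(mirrored == right, p.labels == left):
            raise ParcellationError(
                f"pair ({left}, {right}) is not mirror-exact")


# ---------------------------------------------------------------------------
# symmetrization

def symmetrize_atlas(p: Parcellation, policy: str = "intersection") -> Parcellation:
    """Make an atlas exactly mirror-symmetric.

    policy="intersection"
        A voxel pair (v, v-mirror) keeps its label only when both voxels carry
        the same anatomical label (conservative: no tissue is invented).
    policy="left_dominant"
        Each voxel pair receives the left voxel's label, mirrored to the right.

    When the input carries a pair table, right labels are first canonicalized
    to their left partner so that an already-symmetric paired atlas is a fixed
    point.  Output labels: left hemisphere keeps the (canonical) label id,
    right hemisphere voxels get the paired id (reusing the input pair table's
    ids where available, fresh ids otherwise); unpaired voxels -> background.
    """
    if policy not in ("intersection", "left_dominant"):
        raise ParcellationError(f"unknown symmetrization policy {policy!r}")
    perm = p.grid.mirror_permutation()
    labels = p.labels
    right_to_left = {r: l for l, r in p.pairs}
    left_to_right = {l: r for l, r in p.pairs}

    canonical = labels.copy()
    if right_to_left:
        lut_max = int(labels.max()) + 1
        lut = np.arange(lut_max, dtype=np.int32)
        for r, l in right_to_left.items():
            if r < lut_max:
                lut[r] = l
        canonical = lut[labels]

    mirrored = canonical[perm, :, :]
    xs = p.grid.world_x()
    left_side = xs < 0
    right_side = xs > 0

    out = np.zeros_like(canonical)
    if policy == "intersection":
        agree = (canonical == mirrored) & (canonical != 0)
        kept = np.where(agree, canonical, 0)
    else:  # left_dominant: left voxel's label wins for the whole pair
        left_lab = np.where(left_side[:, None, None], canonical, mirrored)
        kept = np.where(left_lab != 0, left_lab, 0)
        # guarantee exact symmetry of the kept field
        kept = np.where(left_side[:, None, None] | right_side[:, None, None],
                        kept, np.where(canonical == mirrored, canonical, 0))

    # assign left/right ids per canonical label
    next_id = int(max([labels.max()] + [r for r in left_to_right.values()])) + 1
    names: Dict[int, str] = {}
    pairs: List[Tuple[int, int]] = []
    for lab in np.unique(kept):
        if lab == 0:
            continue
        lab = int(lab)
        rlab = left_to_right.get(lab)
        if rlab is None:
            rlab = next_id
            next_id += 1
        region = kept == lab
        out[region & left_side[:, None, None]] = lab
        out[region & right_side[:, None, None]] = rlab
        # midline voxels (x == 0) cannot belong to one hemisphere -> background
        base = p.name_of(lab)
        names[lab] = base if base.endswith("_L") else base + "_L"
        names[rlab] = (base[:-2] + "_R") if base.endswith("_L") else base + "_R"
        pairs.append((lab, rlab))

    return Parcellation(p.grid, out, names, pairs,
                        provenance=(p.provenance + "; " if p.provenance else "")
                        + f"symmetrized policy={policy}")


# ---------------------------------------------------------------------------
# homogeneous equal-size random parcellation

@dataclasses.dataclass(frozen=True)
class HomogeneousSpec:
    """Equal-size random parcellation parameters (k voxels per parcel)."""

    k: int
    seed: int = 0
    remainder_policy: str = "merge_to_nearest"

    def __post_init__(self):
        if self.k < 8:
            raise ParcellationError("k must be >= 8 voxels")
        if self.remainder_policy not in ("merge_to_nearest", "drop"):
            raise ParcellationError(
                f"unknown remainder_policy {self.remainder_policy!r}")


_NEIGH6 = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                    [0, -1, 0], [0, 0, 1], [0, 0, -1]])


def _grow_equal_parcels(coords: np.ndarray, k: int, rng: np.random.Generator,
                        max_restarts: int = 50):
    """Partition a voxel set into 6-connected parcels of exactly k voxels.

    Seeded random region growing.  Each parcel is seeded at an unassigned
    voxel with the fewest unassigned neighbours (a corner of the remaining
    tissue) and grown by repeatedly absorbing the frontier voxel with the
    fewest unassigned neighbours; ties are broken randomly by the seed.
    Eating concavities first keeps the remaining tissue compact, so parcels
    rarely strand.  A parcel stranded below k voxels is dissolved; several
    restarts are attempted and the attempt with the most complete parcels
    (then fewest leftovers) wins.

    Returns (list of index-arrays into coords, remainder index array).
    """
    n = coords.shape[0]
    n_parcels = n // k
    key = {tuple(c): i for i, c in enumerate(map(tuple, coords))}
    neigh = [[] for _ in range(n)]
    for i, c in enumerate(coords):
        for d in _NEIGH6:
            j = key.get((c[0] + d[0], c[1] + d[1], c[2] + d[2]))
            if j is not None:
                neigh[i].append(j)

    def free_degree(i, unassigned):
        return sum(unassigned[j] for j in neigh[i])

    best = None
    for _ in range(max_restarts):
        unassigned = np.ones(n, dtype=bool)
        parcels: List[np.ndarray] = []
        jitter = rng.random(n)  # random tie-break, fixed per attempt
        while len(parcels) < n_parcels and unassigned.sum() >= k:
            free = np.where(unassigned)[0]
            degs = np.array([free_degree(i, unassigned) for i in free])
            seed_idx = free[np.lexsort((jitter[free], degs))[0]]
            member = [seed_idx]
            unassigned[seed_idx] = False
            frontier = {j for j in neigh[seed_idx] if unassigned[j]}
            while len(member) < k and frontier:
                cand = min(frontier,
                           key=lambda i: (free_degree(i, unassigned),
                                          jitter[i]))
                frontier.discard(cand)
                member.append(cand)
                unassigned[cand] = False
                frontier.update(j for j in neigh[cand] if unassigned[j])
            if len(member) == k:
                parcels.append(np.asarray(member))
            else:  # stranded: dissolve back
                unassigned[np.asarray(member)] = True
                break
        leftover = np.where(unassigned)[0]
        if best is None or (len(parcels), -leftover.size) > (len(best[0]),
                                                             -best[1].size):
            best = (parcels, leftover)
        if len(parcels) == n_parcels:
            break
    return best


def homogeneous_parcellation(p: Parcellation,
                             spec: HomogeneousSpec) -> Parcellation:
    """Randomly repartition each region into equal-size connected parcels.

    Each *left* anatomical region of a symmetric input is partitioned into
    ``floor(size / k)`` 6-connected parcels of exactly ``k`` voxels; leftover
    voxels are merged into the nearest same-region parcel (making some parcels
    ``k + r``) or dropped, per ``spec.remainder_policy``.  The left partition
    is then mirrored so homotopic pairs stay exact.
    """
    rng = np.random.default_rng(spec.seed)
    perm = p.grid.mirror_permutation()
    xs = p.grid.world_x()
    out = np.zeros_like(p.labels)
    names: Dict[int, str] = {}
    pairs: List[Tuple[int, int]] = []
    next_id = 1
    log_lines: List[str] = []

    src_pairs = p.pairs if p.pairs else homotopic_pairs(p)
    for left_lab, _right_lab in src_pairs:
        mask = p.labels == left_lab
        coords = np.argwhere(mask)
        size = coords.shape[0]
        if size < spec.k:
            if spec.remainder_policy == "drop":
                logger.warning("region %d smaller than k=%d: dropped",
                               left_lab, spec.k)
                log_lines.append(f"region {left_lab}: dropped (size {size} < k)")
                continue
        n_parcels = max(size // spec.k, 0)
        if n_parcels == 0:
            log_lines.append(f"region {left_lab}: size {size} < k, dropped")
            continue
        parcels, leftover = _grow_equal_parcels(coords, spec.k, rng)
        if len(parcels) < n_parcels:
            logger.warning(
                "region %d: grew %d/%d parcels of k=%d; %d voxels left over",
                left_lab, len(parcels), n_parcels, spec.k, leftover.size)
        # remainder handling
        if leftover.size:
            if spec.remainder_policy == "merge_to_nearest" and parcels:
                centers = np.array([coords[m].mean(axis=0) for m in parcels])
                for idx in leftover:
                    d = ((centers - coords[idx]) ** 2).sum(axis=1)
                    tgt = int(np.argmin(d))
                    parcels[tgt] = np.append(parcels[tgt], idx)
                log_lines.append(
                    f"region {left_lab}: {leftover.size} remainder voxels "
                    "merged to nearest parcel")
            else:
                log_lines.append(
                    f"region {left_lab}: {leftover.size} remainder voxels dropped")
        for pi, member in enumerate(parcels):
            lid = next_id
            rid = next_id + 1
            next_id += 2
            sub = coords[member]
            out[sub[:, 0], sub[:, 1], sub[:, 2]] = lid
            base = p.name_of(left_lab)
            names[lid] = f"{base}_p{pi:03d}_L"
            names[rid] = f"{base}_p{pi:03d}_R"
            pairs.append((lid, rid))

    # mirror the left partition to the right hemisphere
    right_of = {l: r for l, r in pairs}
    mirrored = out[perm, :, :]
    right_side = (xs > 0)[:, None, None]
    lut = np.zeros(next_id, dtype=np.int32)
    for l, r in pairs:
        lut[l] = r
    out = np.where(right_side & (mirrored > 0), lut[mirrored], out)

    prov = ((p.provenance + "; " if p.provenance else "")
            + f"homogeneous k={spec.k} seed={spec.seed} "
            + f"policy={spec.remainder_policy}")
    if log_lines:
        prov += " | " + "; ".join(log_lines)
    return Parcellation(p.grid, out, names, pairs, provenance=prov)
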