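"""NIfTI-1 reading/writing for maps, parcellations and 4-D series.

Volumes are stored float32 on disk (standard neuroimaging practice); all
computation upstream is double precision.  The map's semantic ``value_kind``
travels in the NIfTI header description field.  Parcellations are integer
volumes with a TSV sidecar (label, name, pair_id, hemisphere, n_voxels).
"""

from __future__ import annotations

import os
from typing import Optional, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import GridError, VALUE_KINDS, VolumeGrid, VoxelMap
from .parcellation import Parcellation


def write_volume(m: VoxelMap, path) -> None:
    """Write a 3-D map as NIfTI-1, float32, value_kind in the descrip field."""
    img = nib.Nifti1Image(m.values.astype(np.float32), m.grid.affine)
    img.header["descrip"] = f"homokappa:{m.value_kind}".encode()[:79]
    nib.save(img, str(path))


def read_volume(path, value_kind: Optional[str] = None,
                mask: Optional[np.ndarray] = None) -> VoxelMap:
    """Read a 3-D NIfTI volume as a :class:`VoxelMap`.

    Raises on 4-D input (use :func:`read_series`).  ``value_kind`` defaults to
    the tag stored in the header description, else "generic".
    """
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise GridError(
            f"{path}: expected a 3-D volume, got shape {img.shape}; "
            "use read_series for 4-D data")
    data = np.asanyarray(img.dataobj).astype(float)
    if value_kind is None:
        descrip = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode(
            "utf-8", "replace")
        if descrip.startswith("homokappa:"):
            tag = descrip.split(":", 1)[1]
            value_kind = tag if tag in VALUE_KINDS else "generic"
        else:
            value_kind = "generic"
    grid = VolumeGrid(data.shape, img.affine, mask)
    return VoxelMap(grid, data, value_kind)


def write_series(data: np.ndarray, grid: VolumeGrid, path) -> None:
    """Write a (nx, ny, nz, T) 4-D series as float32 NIfTI-1."""
    data = np.asarray(data)
    if data.ndim != 4 or data.shape[:3] != grid.shape:
        raise GridError("series must be 4-D with spatial dims matching the grid")
    img = nib.Nifti1Image(data.astype(np.float32), grid.affine)
    nib.save(img, str(path))


def read_series(path, mask: Optional[np.ndarray] = None
                ) -> Tuple[VolumeGrid, np.ndarray]:
    """Read a 4-D NIfTI series; returns (grid, data[x, y, z, t])."""
    img = nib.load(str(path))
    if len(img.shape) != 4:
        raise GridError(f"{path}: expected 4-D data, got shape {img.shape}")
    data = np.asanyarray(img.dataobj).astype(float)
    grid = VolumeGrid(data.shape[:3], img.affine, mask)
    return grid, data


def write_parcellation(p: Parcellation, path) -> None:
    """Write labels as int32 NIfTI plus a ``<path minus .nii[.gz]>.tsv`` sidecar."""
    img = nib.Nifti1Image(p.labels.astype(np.int32), p.grid.affine)
    img.header["descrip"] = b"homokappa:parcellation"
    nib.save(img, str(path))
    pair_id = {}
    for i, (l, r) in enumerate(p.pairs):
        pair_id[l] = i
        pair_id[r] = i
    rows = []
    for lab in p.label_ids:
        lab = int(lab)
        hemi = "L" if any(lab == l for l, _ in p.pairs) else (
            "R" if any(lab == r for _, r in p.pairs) else "U")
        rows.append({"label": lab, "name": p.name_of(lab),
                     "pair_id": pair_id.get(lab, -1), "hemisphere": hemi,
                     "n_voxels": p.region_size(lab)})
    pd.DataFrame(rows).to_csv(_sidecar_path(path), sep="\t", index=False)


def read_parcellation(path) -> Parcellation:
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise GridError(f"{path}: parcellation must be 3-D")
    labels = np.asanyarray(img.dataobj)
    grid = VolumeGrid(labels.shape, img.affine)
    names, pairs = {}, []
    sidecar = _sidecar_path(path)
    if os.path.exists(sidecar):
        tab = pd.read_csv(sidecar, sep="\t")
        names = {int(r.label): str(r.name) for r in tab.itertuples()}
        by_pair = {}
        for r in tab.itertuples():
            if r.pair_id >= 0:
                by_pair.setdefault(int(r.pair_id), {})[r.hemisphere] = int(r.label)
        for pid in sorted(by_pair):
            d = by_pair[pid]
            if "L" in d and "R" in d:
                pairs.append((d["L"], d["R"]))
    return Parcellation(grid, np.rint(labels).astype(np.int32), names, pairs,
                        provenance=f"read from {path}")


def _sidecar_path(path) -> str:
    s = str(path)
    for suffix in (".nii.gz", ".nii"):
        if s.endswith(suffix):
            return s[: -len(suffix)] + ".tsv"
    return s + ".tsv"
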