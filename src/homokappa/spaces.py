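"""Stereotaxic space conversion through named affine constant sets.

MNI(ICBM)-to-Talairach conversion uses the published Lancaster "tal2icbm"
affines (pooled fits for SPM- and FSL-normalized data); the icbm2tal
direction is their matrix inverse.  The constants are injected as named
:class:`SpaceTransform` objects rather than inline magic numbers, and an
identity transform is provided for tests and for data already in the target
space.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .foci import FociCollection, FociExperiment, KNOWN_SPACES, MNI, TAL


@dataclasses.dataclass(frozen=True)
class SpaceTransform:
    """A named affine mapping ``source`` world mm to ``target`` world mm."""

    name: str
    source: str
    target: str
    matrix: np.ndarray  # (4, 4)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        object.__setattr__(self, "matrix", m)

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        return xyz @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self, name=None) -> "SpaceTransform":
        return SpaceTransform(name or f"{self.name}_inverse",
                              self.target, self.source,
                              np.linalg.inv(self.matrix))


def identity_transform(source: str, target: str) -> SpaceTransform:
    return SpaceTransform("identity", source, target, np.eye(4))


# Lancaster et al. (2007) pooled affines, as distributed with the tal2icbm
# conversion scripts; rows are the published coefficients.
_TAL2ICBM_SPM = np.array([
    [0.9254, 0.0024, -0.0118, -1.0207],
    [-0.0048, 0.9316, -0.0871, -1.7667],
    [0.0152, 0.0883, 0.8924, 4.0926],
    [0.0, 0.0, 0.0, 1.0],
])
_TAL2ICBM_FSL = np.array([
    [0.9464, 0.0034, -0.0026, -1.0680],
    [-0.0083, 0.9479, -0.0580, -1.0239],
    [0.0053, 0.0617, 0.9010, 3.1883],
    [0.0, 0.0, 0.0, 1.0],
])

TAL2ICBM_SPM = SpaceTransform("tal2icbm_spm", TAL, MNI, _TAL2ICBM_SPM)
ICBM2TAL_SPM = TAL2ICBM_SPM.inverse("icbm2tal_spm")
TAL2ICBM_FSL = SpaceTransform("tal2icbm_fsl", TAL, MNI, _TAL2ICBM_FSL)
ICBM2TAL_FSL = TAL2ICBM_FSL.inverse("icbm2tal_fsl")

#: default transform per (source, target) pair
DEFAULT_TRANSFORMS = {
    (TAL, MNI): TAL2ICBM_SPM,
    (MNI, TAL): ICBM2TAL_SPM,
}


def get_transform(source: str, target: str) -> SpaceTransform:
    if source == target:
        return identity_transform(source, target)
    try:
        return DEFAULT_TRANSFORMS[(source, target)]
    except KeyError:
        raise ValueError(f"no transform registered for {source} -> {target}")


def convert_space(collection: FociCollection, target: str,
                  transform: SpaceTransform | None = None) -> FociCollection:
    """Map every focus of a collection into ``target`` space.

    With ``source == target`` (and no explicit transform) the collection is
    returned unchanged.  An explicit ``transform`` overrides the registered
    constants but must match the requested source/target pair.
    """
    if target not in KNOWN_SPACES:
        raise ValueError(f"unknown target space {target!r}")
    source = collection.space
    if transform is None:
        if source == target:
            return collection
        transform = get_transform(source, target)
    if (transform.source, transform.target) != (source, target):
        raise ValueError(
            f"transform {transform.name!r} maps {transform.source}->"
            f"{transform.target}, not {source}->{target}")
    new_exps = [
        FociExperiment(e.experiment_id, target, transform.apply(e.foci),
                       e.n_subjects)
        for e in collection
    ]
    prov = (collection.provenance + "; " if collection.provenance else "")
    return FociCollection(
        new_exps, provenance=prov + f"converted {source}->{target} "
                                    f"via {transform.name}")
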