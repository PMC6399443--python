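"""Activation foci: domain types and the Sleuth plain-text dialect.

A *focus* is a reported peak activation coordinate (x, y, z) in stereotaxic
world mm (Talairach or MNI).  Experiments group foci; collections group
experiments, mirroring the structure of BrainMap/Sleuth exports.

Dialect accepted by :func:`read_sleuth_text`:

* lines starting with ``//`` are metadata;
* the first ``// Reference=<space>`` line fixes the coordinate space for the
  whole file (required);
* experiments are blocks separated by one or more blank lines;
* within a block, the first ``//`` line (other than the Reference line) names
  the experiment, an optional ``// Subjects=<n>`` records the sample size,
  and every non-comment line holds one whitespace-separated ``x y z`` focus.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from typing import List, Optional, Sequence

import numpy as np

logger = logging.getLogger("homokappa")

TAL = "TAL"
MNI = "MNI"
KNOWN_SPACES = (TAL, MNI)

_SPACE_ALIASES = {
    "talairach": TAL,
    "tal": TAL,
    "mni": MNI,
    "icbm": MNI,
    "icbm152": MNI,
}


class SleuthParseError(ValueError):
    """Raised on malformed Sleuth foci text."""


def normalize_space(name: str) -> str:
    key = str(name).strip().lower()
    if key in _SPACE_ALIASES:
        return _SPACE_ALIASES[key]
    raise SleuthParseError(f"unknown reference space {name!r}")


@dataclasses.dataclass(frozen=True)
class FociExperiment:
    """One experiment's activation peaks in world mm."""

    experiment_id: str
    space: str
    foci: np.ndarray  # (n, 3) float
    n_subjects: Optional[int] = None

    def __post_init__(self):
        foci = np.asarray(self.foci, dtype=float)
        if foci.ndim != 2 or foci.shape[1] != 3 or foci.shape[0] == 0:
            raise ValueError("foci must be a non-empty (n, 3) array")
        if not np.isfinite(foci).all():
            raise ValueError("foci coordinates must be finite")
        if self.space not in KNOWN_SPACES:
            raise ValueError(f"unknown space tag {self.space!r}")
        if self.n_subjects is not None and self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        object.__setattr__(self, "foci", foci)

    @property
    def n_foci(self) -> int:
        return self.foci.shape[0]


@dataclasses.dataclass(frozen=True)
class FociCollection:
    """An ordered set of experiments sharing one coordinate space."""

    experiments: Sequence[FociExperiment]
    provenance: str = ""

    def __post_init__(self):
        exps = tuple(self.experiments)
        ids = [e.experiment_id for e in exps]
        if len(set(ids)) != len(ids):
            raise ValueError("experiment_ids must be unique")
        spaces = {e.space for e in exps}
        if len(spaces) > 1:
            raise ValueError(f"mixed coordinate spaces in collection: {spaces}")
        object.__setattr__(self, "experiments", exps)

    def __len__(self) -> int:
        return len(self.experiments)

    def __iter__(self):
        return iter(self.experiments)

    @property
    def space(self) -> str:
        return self.experiments[0].space if self.experiments else TAL

    @property
    def n_foci(self) -> int:
        return sum(e.n_foci for e in self.experiments)


_REFERENCE_RE = re.compile(r"^//\s*Reference\s*=\s*(\S+)", re.IGNORECASE)
_SUBJECTS_RE = re.compile(r"^//\s*Subjects\s*=\s*(\d+)", re.IGNORECASE)


def read_sleuth_text(path) -> FociCollection:
    """Parse a Sleuth-style plain-text foci export.

    Raises
    ------
    SleuthParseError
        If no ``// Reference=`` header is present, or a coordinate line is
        non-numeric (the error names the offending line number).
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    space = None
    for line in lines:
        m = _REFERENCE_RE.match(line.strip())
        if m:
            space = normalize_space(m.group(1))
            break
    if space is None:
        raise SleuthParseError(f"{path}: missing '// Reference=' space header")

    experiments: List[FociExperiment] = []
    block_meta: List[str] = []
    block_foci: List[List[float]] = []
    block_subjects: Optional[int] = None
    n_auto = 0

    def flush():
        nonlocal block_meta, block_foci, block_subjects, n_auto
        if not block_foci:
            if block_meta:
                logger.warning("skipping block with metadata but no foci: %s",
                               block_meta[0])
            block_meta, block_subjects = [], None
            return
        n_auto += 1
        exp_id = block_meta[0] if block_meta else f"experiment_{n_auto:04d}"
        experiments.append(FociExperiment(
            experiment_id=exp_id, space=space,
            foci=np.asarray(block_foci, dtype=float),
            n_subjects=block_subjects))
        block_meta, block_foci, block_subjects = [], [], None

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            flush()
            continue
        if line.startswith("//"):
            if _REFERENCE_RE.match(line):
                continue
            m = _SUBJECTS_RE.match(line)
            if m:
                block_subjects = int(m.group(1))
                continue
            block_meta.append(line[2:].strip())
            continue
        parts = line.split()
        if len(parts) != 3:
            raise SleuthParseError(
                f"{path}:{lineno}: expected 'x y z', got {line!r}")
        try:
            block_foci.append([float(p) for p in parts])
        except ValueError as exc:
            raise SleuthParseError(
                f"{path}:{lineno}: non-numeric coordinate in {line!r}") from exc
    flush()

    return FociCollection(experiments, provenance=f"read from {path}")


def write_sleuth_text(collection: FociCollection, path) -> None:
    """Write a collection in the dialect :func:`read_sleuth_text` accepts.

    Coordinates are printed with six decimals, so a write/read round trip
    reproduces them to 1e-6 mm.
    """
    space_name = "Talairach" if collection.space == TAL else "MNI"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"// Reference={space_name}\n\n")
        for e in collection:
            fh.write(f"// {e.experiment_id}\n")
            if e.n_subjects is not None:
                fh.write(f"// Subjects={e.n_subjects}\n")
            for x, y, z in e.foci:
                fh.write(f"{x:.6f}\t{y:.6f}\t{z:.6f}\n")
            fh.write("\n")
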