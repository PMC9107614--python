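"""Shared containers for BOLD runs, spatial maps, node courses and selections.

Every stage of the pipeline moves data between a small set of plain
dataclasses.  A :class:`BoldRun` holds one subject's masked 4D time series as
a dense ``V x T`` matrix (V in-mask voxels, T frames) together with the grid
geometry; a :class:`SpatialMap` is a per-voxel statistic on the same grid; a
:class:`TimepointSelection` is an ordered set of frame indices with the rule
that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = [
    "BoldRun",
    "SpatialMap",
    "NodeTimecourse",
    "TimepointSelection",
    "ComponentSet",
    "NuisanceSet",
    "PcaReduction",
    "config_hash",
    "pearson",
    "zscore",
]


def config_hash(obj: Any) -> str:
    """Stable short hash of any JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def zscore(x: np.ndarray, axis: int = -1, ddof: int = 0) -> np.ndarray:
    """Mean 0 / sd 1 along ``axis``; raises on zero variance."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, ddof=ddof, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("cannot z-score a constant vector")
    return (x - mu) / sd


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two 1-D vectors (0.0 if either is constant)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        return 0.0
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


@dataclass
class BoldRun:
    """One subject's masked BOLD run.

    Parameters
    ----------
    data:
        ``V x T`` array of in-mask voxel time courses (BOLD a.u.).
    mask:
        3-D boolean grid; ``mask.sum() == V``.  Voxel *v* of ``data``
        corresponds to the *v*-th True voxel in C order.
    tr:
        Repetition time in seconds.
    subject_id:
        Free-form subject label.
    affine:
        Voxel-to-world (mm) affine; a diagonal voxel-size affine for
        synthetic grids.
    """

    data: np.ndarray
    mask: np.ndarray
    tr: float
    subject_id: str = "sub-00"
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("BoldRun.data must be V x T")
        if int(self.mask.sum()) != self.data.shape[0]:
            raise ValueError(
                f"mask has {int(self.mask.sum())} voxels but data has "
                f"{self.data.shape[0]} rows"
            )
        if self.affine is None:
            self.affine = np.eye(4)

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "BoldRun":
        return replace(self, data=np.asarray(data, dtype=float))

    def to_volume(self) -> np.ndarray:
        """Embed ``data`` back into the 4D grid (zeros outside the mask)."""
        vol = np.zeros(self.mask.shape + (self.n_frames,), dtype=float)
        vol[self.mask] = self.data
        return vol


@dataclass
class SpatialMap:
    """A per-voxel statistic vector on a run's grid."""

    values: np.ndarray
    kind: str = "stat"  # wASM | ASM | FCM | ICA | contribution-beta | stat
    zscored: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SpatialMap values must be finite")


@dataclass
class NodeTimecourse:
    """Average (or model-derived) time course representing a network node."""

    values: np.ndarray
    node_id: str = "node"
    subject_id: str = "sub-00"
    method: str = "mean"
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("NodeTimecourse must be finite")
        if self.values.std() == 0:
            self.degenerate = True

    @property
    def n_frames(self) -> int:
        return self.values.size


@dataclass
class TimepointSelection:
    """An ordered set of frame indices plus the selection rule that made it."""

    indices: np.ndarray
    mode: str  # top_amplitude | bottom_amplitude | top_absolute | all | ...
    n_requested: int = 20
    node_id: str = "node"
    complement: bool = False
    log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int).ravel()
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("selection indices must be strictly increasing")

    def __len__(self) -> int:
        return self.indices.size


@dataclass
class NuisanceSet:
    """Motion parameters and their first differences (T x 12)."""

    matrix: np.ndarray
    columns: list

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.columns):
            raise ValueError("nuisance matrix / column-name mismatch")

    @classmethod
    def from_motion(cls, motion: np.ndarray) -> "NuisanceSet":
        """Build the 12-column set from 6 motion parameters.

        Derivatives are backward first differences with the first row zero.
        """
        motion = np.asarray(motion, dtype=float)
        if motion.ndim != 2 or motion.shape[1] != 6:
            raise ValueError("motion must be T x 6")
        deriv = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
        names = [f"mot{i}" for i in range(6)] + [f"mot{i}_d" for i in range(6)]
        return cls(np.hstack([motion, deriv]), names)

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]


@dataclass
class PcaReduction:
    """A subject- or group-level spatial PCA reduction."""

    basis: np.ndarray           # original-dim x m projection vectors
    singular_values: np.ndarray
    variance_retained: float
    level: str                  # "subject" | "group"
    reduced: np.ndarray         # m x V reduced data

    @property
    def n_components(self) -> int:
        return self.reduced.shape[0]


@dataclass
class ComponentSet:
    """Matched spatial maps + time courses from an ICA run.

    ``maps`` is ``K x V`` with each component z-scored over voxels;
    ``timecourses`` (when present) is ``T x K``.  ``stability`` holds the
    per-component run-stability quality index Iq in [0, 1] for multi-run
    estimates and is ``None`` for a single run.
    """

    maps: np.ndarray
    timecourses: np.ndarray | None = None
    stability: np.ndarray | None = None
    model_order: int = 0
    converged: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise ValueError("ComponentSet.maps must be K x V")
        if self.model_order == 0:
            self.model_order = self.maps.shape[0]

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    def stable(self, iq_min: float = 0.8) -> "ComponentSet":
        """Subset of components whose stability index exceeds ``iq_min``."""
        if self.stability is None:
            raise ValueError("stability indices unavailable (single run)")
        keep = np.flatnonzero(self.stability > iq_min)
        return ComponentSet(
            maps=self.maps[keep],
            timecourses=None if self.timecourses is None else self.timecourses[:, keep],
            stability=self.stability[keep],
            model_order=len(keep),
            converged=self.converged,
            meta={**self.meta, "parent_indices": keep.tolist()},
        )
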