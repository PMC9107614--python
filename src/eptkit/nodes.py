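"""Network node definitions and node time-course extraction.

A *node* is the seed whose time course drives extreme-time-point selection.
Four kinds are supported, mirroring common practice:

- ``cube``: an axis-aligned box of given edge length (mm) around a centre;
- ``sphere``: voxels whose centres lie within a radius (mm) of a centre;
- ``mask``: the top-n voxels of a statistic map (e.g. a meta-analytic map);
- ``ica_reference``: a subject-specific network estimated by spatially
  constrained ICA against a reference map, whose time course (rather than a
  seed average) represents the network.

For the first three kinds the node course is the unweighted spatial mean of
the member voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import BoldRun, NodeTimecourse, SpatialMap, pearson

__all__ = ["NodeSpec", "resolve_node_mask", "node_timecourse", "ica_node_timecourse"]


@dataclass
class NodeSpec:
    """Definition of one node; exactly the fields of its kind are used."""

    kind: str                       # cube | sphere | mask | ica_reference
    center_mm: tuple | None = None  # world-mm centre for cube/sphere
    edge_mm: float | None = None    # cube edge length
    radius_mm: float | None = None  # sphere radius
    stat_map: np.ndarray | None = None  # flat V-vector for kind="mask"
    top_n: int = 27
    reference_map: SpatialMap | None = None
    node_id: str = "node"

    def __post_init__(self) -> None:
        required = {
            "cube": ("center_mm", "edge_mm"),
            "sphere": ("center_mm", "radius_mm"),
            "mask": ("stat_map",),
            "ica_reference": ("reference_map",),
        }
        if self.kind not in required:
            raise ValueError(f"unknown node kind {self.kind!r}")
        for f in required[self.kind]:
            if getattr(self, f) is None:
                raise ValueError(f"node kind {self.kind!r} requires {f}")


def _voxel_centers_mm(run: BoldRun) -> np.ndarray:
    """World-mm coordinates of in-mask voxel centres (V x 3)."""
    if run.affine is None:
        raise ValueError("run has no affine; mm-based node specs need one")
    ijk = np.argwhere(run.mask)
    hom = np.column_stack([ijk, np.ones(len(ijk))])
    return (hom @ run.affine.T)[:, :3]


def resolve_node_mask(spec: NodeSpec, run: BoldRun) -> np.ndarray:
    """Resolve a node spec to a sorted array of in-mask voxel indices.

    Cube/sphere membership is by voxel-centre position in world mm.  For
    ``mask`` nodes the top-n voxels by statistic value are taken; ties at
    the cutoff are broken by flat voxel index (earliest wins) and noted in
    a warning so the resolved set is deterministic.  A sphere smaller than
    half a voxel degenerates to the single nearest voxel.
    """
    if spec.kind == "mask":
        stat = np.asarray(spec.stat_map, dtype=float).ravel()
        if stat.size != run.n_voxels:
            raise ValueError(
                f"stat map has {stat.size} values, run has {run.n_voxels} voxels"
            )
        n = min(spec.top_n, stat.size)
        order = np.argsort(-stat, kind="stable")  # ties -> earliest flat index
        chosen = order[:n]
        if n < stat.size and stat[order[n - 1]] == stat[order[n]]:
            warnings.warn(
                f"tie at the top-{n} cutoff (value {stat[order[n]]:g}); "
                "broken by flat voxel index"
            )
        return np.sort(chosen)

    if spec.kind == "ica_reference":
        raise ValueError("ica_reference nodes have no voxel mask; use ica_node_timecourse")

    centers = _voxel_centers_mm(run)
    target = np.asarray(spec.center_mm, dtype=float)
    if spec.kind == "cube":
        half = spec.edge_mm / 2.0
        inside = np.all(np.abs(centers - target) <= half + 1e-9, axis=1)
    else:  # sphere
        d = np.linalg.norm(centers - target, axis=1)
        inside = d <= spec.radius_mm + 1e-9
        if not inside.any():
            vox_size = float(np.abs(np.diag(run.affine)[:3]).min())
            if spec.radius_mm < vox_size / 2.0:
                inside = np.zeros(len(centers), dtype=bool)
                inside[int(np.argmin(d))] = True
    idx = np.flatnonzero(inside)
    if idx.size == 0:
        raise ValueError(f"node {spec.node_id!r} resolves to no in-mask voxels")
    return idx


def node_timecourse(run: BoldRun, voxels: np.ndarray, node_id: str = "node") -> NodeTimecourse:
    """Unweighted spatial mean over the voxel set at each frame."""
    voxels = np.asarray(voxels, dtype=int)
    if voxels.size == 0:
        raise ValueError("empty voxel set")
    values = run.data[voxels].mean(axis=0)
    tc = NodeTimecourse(values, node_id=node_id, subject_id=run.subject_id, method="mean")
    if tc.degenerate:
        warnings.warn(f"node {node_id!r}: zero-variance (degenerate) course")
    return tc


def ica_node_timecourse(
    run: BoldRun, reference: SpatialMap, node_id: str = "node_ica"
) -> tuple[NodeTimecourse, SpatialMap]:
    """Subject-specific network time course via reference-guided ICA.

    Delegates to :func:`eptkit.group_ica.gig_ica`.  If the reference matches
    no data component (|r| < 0.2 at initialisation) the estimate falls back
    to dual regression and is flagged accordingly.
    """
    from .group_ica import gig_ica

    comp = gig_ica(run, [reference])
    tc = NodeTimecourse(
        comp.timecourses[:, 0],
        node_id=node_id,
        subject_id=run.subject_id,
        method="gig_ica" if not comp.meta.get("fallback", [False])[0] else "dual_regression",
    )
    smap = SpatialMap(
        comp.maps[0],
        kind="ICA",
        zscored=True,
        provenance={"node": node_id, "subject": run.subject_id, "method": tc.method},
    )
    return tc, smap
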