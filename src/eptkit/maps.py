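"""Activation spatial maps, seed connectivity maps and map comparison.

Two first-order statistics summarise what the brain looks like at a set of
selected frames, given the node course w(t) that drove the selection:

- the weighted activation spatial map,
  ``wASM(v) = (1/T) * sum_{t in sel} w(t) X(v, t)``,
- the sign-corrected activation spatial map,
  ``ASM(v)  = (1/T) * sum_{t in sel} sign(w(t)) X(v, t)``,

where T is the number of selected frames.  Sign correction prevents frames
of opposite node polarity from cancelling; when every selected w(t) is
positive the ASM reduces to a plain average of the selected frames.  The
second-order counterpart is the seed functional connectivity map (per-voxel
Pearson correlation with the node course over the selection).

Per-frame network contribution betas — the coefficient of a network map in
the regression of each frame on that map — describe how strongly a network
is expressed at every time point and, sorted, expose whether its engagement
is continuous or event-like.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import BoldRun, NodeTimecourse, SpatialMap, TimepointSelection, pearson

__all__ = [
    "wasm",
    "asm",
    "fcmap",
    "contribution_betas",
    "zscore_map",
    "threshold_map",
    "partial_spatial_similarity",
]


def _sel_arrays(run: BoldRun, w, sel: TimepointSelection):
    if len(sel) < 1:
        raise ValueError("empty time-point selection")
    wv = w.values if isinstance(w, NodeTimecourse) else np.asarray(w, dtype=float).ravel()
    if wv.size == run.n_frames:
        wv = wv[sel.indices]
    elif wv.size != len(sel):
        raise ValueError("weight vector matches neither run length nor selection size")
    return run.data[:, sel.indices], wv


def _provenance(w, sel: TimepointSelection) -> dict:
    return {
        "node": getattr(w, "node_id", sel.node_id),
        "mode": sel.mode,
        "n_frames": len(sel),
    }


def wasm(run: BoldRun, w, sel: TimepointSelection) -> SpatialMap:
    """Amplitude-weighted activation spatial map over the selection."""
    X, wv = _sel_arrays(run, w, sel)
    values = (X * wv[None, :]).sum(axis=1) / len(sel)
    return SpatialMap(values, kind="wASM", provenance=_provenance(w, sel))


def asm(run: BoldRun, w, sel: TimepointSelection) -> SpatialMap:
    """Sign-corrected activation spatial map over the selection.

    Frames where w(t) is exactly zero contribute nothing (sign 0) and are
    counted in the provenance.
    """
    X, wv = _sel_arrays(run, w, sel)
    signs = np.sign(wv)
    prov = _provenance(w, sel)
    n_zero = int((signs == 0).sum())
    if n_zero:
        prov["zero_weight_frames"] = n_zero
    values = (X * signs[None, :]).sum(axis=1) / len(sel)
    return SpatialMap(values, kind="ASM", provenance=prov)


def fcmap(run: BoldRun, tc, sel: TimepointSelection) -> SpatialMap:
    """Seed functional connectivity map restricted to the selection.

    Per-voxel Pearson correlation between the node course and the voxel
    course over the selected frames; constant voxels get r = 0 and are
    counted in the provenance.
    """
    if len(sel) < 3:
        raise ValueError("need at least 3 selected frames for a correlation map")
    X, wv = _sel_arrays(run, tc, sel)
    if wv.std() == 0:
        raise ValueError("node course constant over the selection")
    Xc = X - X.mean(axis=1, keepdims=True)
    wc = wv - wv.mean()
    denom = np.linalg.norm(Xc, axis=1) * np.linalg.norm(wc)
    prov = _provenance(tc, sel)
    constant = denom == 0
    if constant.any():
        prov["constant_voxels"] = int(constant.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(constant, 0.0, (Xc @ wc) / np.where(constant, 1.0, denom))
    return SpatialMap(np.clip(r, -1.0, 1.0), kind="FCM", provenance=prov)


def contribution_betas(run: BoldRun, network_map: SpatialMap) -> np.ndarray:
    """Per-frame OLS coefficient of a network map, frame ~ intercept + map.

    Returns a length-T vector; ``np.sort`` of it gives the ranked
    contribution curve used to inspect whether network engagement changes
    smoothly over time or in discrete jumps.
    """
    m = network_map.values
    mc = m - m.mean()
    denom = mc @ mc
    if denom == 0:
        raise ValueError("zero-variance network map")
    return (mc @ run.data) / denom


def zscore_map(smap: SpatialMap) -> SpatialMap:
    """Z-score a map across voxels (mean 0, sd 1)."""
    sd = smap.values.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant map")
    return SpatialMap(
        (smap.values - smap.values.mean()) / sd,
        kind=smap.kind,
        zscored=True,
        provenance=dict(smap.provenance),
    )


def threshold_map(smap: SpatialMap, z: float = 1.0) -> SpatialMap:
    """Keep values >= z, zero the rest (display convention for z-maps)."""
    values = np.where(smap.values >= z, smap.values, 0.0)
    return SpatialMap(values, kind=smap.kind, zscored=smap.zscored,
                      provenance={**smap.provenance, "threshold_z": z})


def partial_spatial_similarity(
    a: SpatialMap, b: SpatialMap, confounds: list | None = None
) -> float:
    """Spatial correlation of two maps after regressing out other networks.

    Both maps are residualised (across voxels) on the confound maps plus an
    intercept before the Pearson correlation, so shared variance carried by
    the confounds cannot drive the similarity.  Rank-deficient confound
    sets are reduced with a warning.
    """
    if a.values.size != b.values.size:
        raise ValueError("maps are on different grids")
    if not confounds:
        return pearson(a.values, b.values)
    C = np.column_stack([c.values for c in confounds])
    if C.shape[0] != a.values.size:
        raise ValueError("confound maps are on a different grid")
    D = np.column_stack([np.ones(C.shape[0]), C])
    q, r = np.linalg.qr(D)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} collinear confound column(s)"
        )
        D = D[:, keep]
    beta_a, *_ = np.linalg.lstsq(D, a.values, rcond=None)
    beta_b, *_ = np.linalg.lstsq(D, b.values, rcond=None)
    return pearson(a.values - D @ beta_a, b.values - D @ beta_b)
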