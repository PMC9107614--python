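"""Event-present / event-absent time-point (EPT/EAT) selection.

EPTs are the n frames (default 20, matching the ICA model order) with the
largest node amplitude; EATs the n frames with the smallest signed
amplitude — the frames least likely to contain an event of that network.
An absolute-value variant selects the n largest magnitudes, as some
event-detection studies use both extremes.  Two further detectors from the
event-detection literature (fixed threshold in SD units and local maxima)
are provided for comparison.

Ties are broken by the earlier frame index so selections are reproducible.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import BoldRun, NodeTimecourse, TimepointSelection

__all__ = ["select_timepoints", "remove_local_extrema", "subset_run", "MODES"]

MODES = (
    "top_amplitude",
    "bottom_amplitude",
    "top_absolute",
    "all",
    "threshold",
    "local_maxima",
)


def _as_values(tc) -> np.ndarray:
    if isinstance(tc, NodeTimecourse):
        if tc.degenerate:
            raise ValueError("degenerate (zero-variance) node course")
        return tc.values
    return np.asarray(tc, dtype=float).ravel()


def select_timepoints(
    tc, mode: str = "bottom_amplitude", n: int = 20, threshold_sd: float = 1.0
) -> TimepointSelection:
    """Select frames from a node course under the given mode.

    ``top_amplitude``/``bottom_amplitude`` take the n largest/smallest
    signed values, ``top_absolute`` the n largest magnitudes, ``all`` every
    frame.  ``threshold`` keeps frames above ``threshold_sd`` standard
    deviations and ``local_maxima`` keeps interior strict local maxima;
    for these two the count is data-driven rather than n.
    """
    values = _as_values(tc)
    T = values.size
    node_id = tc.node_id if isinstance(tc, NodeTimecourse) else "node"
    log: list = []
    if mode == "all":
        return TimepointSelection(np.arange(T), "all", n_requested=T, node_id=node_id)
    if mode == "threshold":
        idx = np.flatnonzero(values > values.mean() + threshold_sd * values.std())
        return TimepointSelection(idx, mode, n_requested=idx.size, node_id=node_id)
    if mode == "local_maxima":
        interior = np.arange(1, T - 1)
        is_max = (values[interior] > values[interior - 1]) & (
            values[interior] > values[interior + 1]
        )
        idx = interior[is_max]
        return TimepointSelection(idx, mode, n_requested=idx.size, node_id=node_id)
    if mode not in ("top_amplitude", "bottom_amplitude", "top_absolute"):
        raise ValueError(f"unknown selection mode {mode!r}")
    if n > T:
        raise ValueError(f"cannot select {n} frames from {T}")
    if values.std() == 0:
        raise ValueError("degenerate (zero-variance) node course")

    if mode == "top_amplitude":
        key = -values
    elif mode == "bottom_amplitude":
        key = values
    else:
        key = -np.abs(values)
    order = np.argsort(key, kind="stable")  # stable: ties -> earliest frame
    chosen = order[:n]
    if n < T and key[order[n - 1]] == key[order[n]]:
        log.append("tie at the selection cutoff; broken by earlier frame index")
    return TimepointSelection(
        np.sort(chosen), mode, n_requested=n, node_id=node_id, log=log
    )


def remove_local_extrema(sel: TimepointSelection, tc) -> TimepointSelection:
    """Drop selected frames that are strict local minima of the course.

    A control for EAT selections: even after removing the locally most
    extreme troughs (so fewer than n frames remain), the network should
    still be recoverable from what is left.
    """
    if sel.mode != "bottom_amplitude":
        raise ValueError("local-extrema removal applies to EAT (bottom_amplitude) selections")
    values = _as_values(tc)
    T = values.size
    keep = []
    removed = 0
    for i in sel.indices:
        if 0 < i < T - 1 and values[i] < values[i - 1] and values[i] < values[i + 1]:
            removed += 1
        else:
            keep.append(i)
    log = list(sel.log) + [f"removed {removed} strict local minima"]
    if not keep:
        warnings.warn("all selected frames were local minima; selection is empty")
    return TimepointSelection(
        np.asarray(keep, dtype=int),
        sel.mode,
        n_requested=sel.n_requested,
        node_id=sel.node_id,
        log=log,
    )


def subset_run(run: BoldRun, sel: TimepointSelection) -> BoldRun:
    """Restrict a run to the selected frames (in selection order).

    The TR is preserved for bookkeeping only — the subset frames are not
    temporally contiguous.
    """
    if len(sel) == 0:
        raise ValueError("empty time-point selection")
    if sel.indices.min() < 0 or sel.indices.max() >= run.n_frames:
        raise ValueError("selection indices outside run")
    return run.with_data(run.data[:, sel.indices])
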