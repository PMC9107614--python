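"""Recursive ICA: expose weak networks by re-running ICA on residuals.

When the frames analysed are chosen to *minimise* a target network's
amplitude (its event-absent time points), the target is weak and the
decomposition is dominated by other sources.  Recursive ICA runs group ICA,
checks whether any stable component matches the target reference, and if
not regresses the stable non-target components out of every subject's data
and repeats on the residual — each pass strips dominant variance so weaker
sources can surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import BoldRun, ComponentSet, SpatialMap, pearson
from .group_ica import run_group_ica

__all__ = ["regress_out_components", "recursive_ica", "RecursiveResult"]


def regress_out_components(run: BoldRun, comp: ComponentSet) -> BoldRun:
    """OLS-residualise every frame against the component maps + intercept.

    The residual is spatially orthogonal to each regressed map.  Collinear
    maps are dropped with a warning.
    """
    if comp.maps.shape[1] != run.n_voxels:
        raise ValueError("component maps are not on the run grid")
    D = np.column_stack([np.ones(run.n_voxels), comp.maps.T])   # V x (K+1)
    q, r = np.linalg.qr(D)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} collinear component map(s)")
        D = D[:, keep]
    beta, *_ = np.linalg.lstsq(D, run.data, rcond=None)
    return run.with_data(run.data - D @ beta)


@dataclass
class RecursiveResult:
    """Per-iteration record of a recursive ICA run."""

    components: list = field(default_factory=list)   # ComponentSet per iteration
    residual_norms: list = field(default_factory=list)
    target_match: list = field(default_factory=list)  # best |r| to reference
    target_component: SpatialMap | None = None
    iterations: int = 0
    success: bool = False
    stop_reason: str = ""


def recursive_ica(
    eat_runs: list,
    reference: SpatialMap,
    max_iters: int = 3,
    match_threshold: float = 0.5,
    model_order: int = 3,
    n_runs: int = 10,
    iq_min: float = 0.8,
    seed: int = 0,
) -> RecursiveResult:
    """Iterate group ICA on residuals until the reference network appears.

    Per iteration: (i) group ICA with stability filtering on the current
    data; (ii) stop with success if any component matches the reference at
    ``|r| >= match_threshold``; (iii) otherwise regress the stable
    *non-target* components (Iq > ``iq_min`` and |r| below threshold — a
    candidate target is never removed) out of each subject and continue.
    Stops with a failure flag after ``max_iters`` or when the data rank is
    exhausted.
    """
    if not eat_runs:
        raise ValueError("need at least one run")
    ref = reference.values
    runs = [r.with_data(r.data.copy()) for r in eat_runs]
    result = RecursiveResult()
    result.residual_norms.append(
        float(np.sqrt(sum(np.sum(r.data**2) for r in runs)))
    )
    for it in range(1, max_iters + 1):
        result.iterations = it
        try:
            comp = run_group_ica(
                runs, model_order=model_order, n_runs=n_runs,
                seed=seed + 1000 * it, iq_min=iq_min,
            )
        except ValueError as err:
            result.stop_reason = f"rank exhausted: {err}"
            return result
        result.components.append(comp)
        r_to_ref = np.array([abs(pearson(m, ref)) for m in comp.maps])
        best = int(np.argmax(r_to_ref))
        result.target_match.append(float(r_to_ref[best]))
        if r_to_ref[best] >= match_threshold:
            result.success = True
            result.stop_reason = f"matched reference at iteration {it}"
            result.target_component = SpatialMap(
                comp.maps[best], kind="ICA", zscored=True,
                provenance={"iteration": it, "match_r": float(r_to_ref[best])},
            )
            return result
        stable = (comp.stability > iq_min) & (r_to_ref < match_threshold)
        if not stable.any():
            result.stop_reason = "no stable non-target components to remove"
            return result
        removal = ComponentSet(maps=comp.maps[stable], model_order=int(stable.sum()))
        runs = [regress_out_components(r, removal) for r in runs]
        result.residual_norms.append(
            float(np.sqrt(sum(np.sum(r.data**2) for r in runs)))
        )
    result.stop_reason = f"no match after {max_iters} iterations"
    return result
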