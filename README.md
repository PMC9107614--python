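# eptkit

Tools for testing whether an intrinsic connectivity network (ICN) in
resting-state BOLD fMRI behaves as a **continuous** process or as a string of
**discrete events** — by analysing the frames where the network should be
*least* present.

Event-detection approaches select a node's highest-amplitude frames (the
event-present time points, **EPTs**) and build co-activation maps from them
alone. `eptkit` implements the complementary interrogation: select the
frames with the *minimum* node amplitude (the event-absent time points,
**EATs**) and ask whether the network is still there. If a network can be
recovered from its own EATs, it is not adequately described as a set of
sparse events.

## What it computes

Given a node time course `w(t)` and a frame selection (EPTs, EATs, or all
time points), with `T` the number of selected frames:

- **weighted activation spatial map** — `wASM(v) = (1/T) Σ_t w(t)·X(v,t)`
- **activation spatial map** — `ASM(v) = (1/T) Σ_t sign(w(t))·X(v,t)`
  (sign correction prevents frames of opposite node polarity cancelling)
- **functional connectivity map** — per-voxel Pearson `r(w, X(v,·))` over
  the selection
- **group spatial ICA** — variance normalisation → subject spatial PCA
  (>99% variance) → group PCA to the model order → Infomax, repeated with
  random restarts and stability-clustered (quality index
  `Iq = within-cluster − between-cluster mean |spatial r|`; components with
  `Iq > 0.8` identify networks)
- **GIG-ICA** — reference-guided one-unit negentropy maximisation giving
  subject-specific maps and courses
- **recursive ICA** — regress stable non-target components out of each
  subject's EAT data and re-run ICA on the residual, exposing networks too
  weak for a single pass
- **FNC + association** — correlations between a target network's course
  and the other networks' courses per frame selection, residualised on
  age/sex/site/motion, related to a symptom score by cross-validated LASSO
  (10-fold, 50 Monte-Carlo repetitions) and to diagnosis by logistic
  regression with Benjamini–Hochberg correction

A synthetic-data module generates multi-subject BOLD with known network
maps and switchable ground truth — band-limited continuous courses, or
sparse events convolved with a double-gamma HRF that are exactly zero
outside event support — plus trends, motion-coupled signal, spikes, noise,
and a cohort layer with covariates and symptom scores tied to designated
FNC pairs. Every downstream claim is validated against this generator.

## Worked example

```python
import numpy as np
from eptkit.synthetic_data import SimConfig, simulate_dataset
from eptkit.preprocess import clean_run
from eptkit.nodes import NodeSpec, resolve_node_mask, node_timecourse
from eptkit.timepoints import select_timepoints, subset_run
from eptkit.group_ica import run_group_ica
from eptkit.core import pearson

cfg = SimConfig(seed=1, snr=2.0)                 # 5 networks, 20x20x10, T=200
runs, nuisance, truths = simulate_dataset(cfg, 10)
cleaned = [clean_run(r, n)[0] for r, n in zip(runs, nuisance)]

# node = top-27 voxels of network 0's map; EATs = its 20 lowest frames
node = resolve_node_mask(
    NodeSpec(kind="mask", stat_map=truths[0].true_maps[0], top_n=27), cleaned[0])
eat_runs = []
for run in cleaned:
    tc = node_timecourse(run, node)
    sel = select_timepoints(tc, "bottom_amplitude", 20)
    eat_runs.append(subset_run(run, sel))

comp = run_group_ica(eat_runs, model_order=20, n_runs=10, seed=11)
best = max(abs(pearson(m, truths[0].true_maps[0])) for m in comp.maps)
print(f"network recovered from its own EATs at |r| = {best:.2f}")
```

Output:

```
network recovered from its own EATs at |r| = 0.62
```

The network is recoverable from the 20 frames per subject where its node
was *least* active — the signature of a continuously present process. Under
an event-driven ground truth (`SimConfig(..., regime="event")`) the same
analysis yields |r| ≈ 0.1: genuinely event-driven networks leave nothing at
their event-absent frames, so the pipeline separates the two hypotheses.

There is also a CLI (`eptkit simulate|clean|detect|map|gica|assoc|run`) for
file-based use.

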