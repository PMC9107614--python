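"""Synthetic multi-subject BOLD generator with known ground truth.

The generator emulates the two competing accounts of resting-state network
dynamics: a *continuous* regime, in which each network's time course is a
band-limited Gaussian signal occupying the standard resting-state analysis
band (0.01-0.15 Hz), and an *event* regime, in which a network is driven by
a sparse binary spike train convolved with a canonical double-gamma
haemodynamic response and is exactly zero outside the HRF support of its
events.  Both regimes are mixed through the same linear model

    X(v, t) = sum_k map_k(v) * tc_k(t) + trend + motion signal + spikes + noise

so every downstream stage (cleaning, node extraction, extreme-time-point
selection, ICA, connectivity) has a recovery oracle: the true maps and
courses are recorded in a :class:`GroundTruth` alongside every run.

A cohort layer adds diagnosis labels, covariates (age, sex, 3-level site,
mean framewise displacement) and a symptom score generated from designated
functional-network-connectivity (FNC) pairs, so that the association stage
can be validated against planted effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import BoldRun, NuisanceSet, SpatialMap

__all__ = [
    "SimConfig",
    "SymptomModel",
    "GroundTruth",
    "double_gamma_hrf",
    "hrf_support_frames",
    "make_network_maps",
    "make_timecourses",
    "assemble_bold",
    "simulate_dataset",
    "make_cohort",
    "make_symptom_cohort",
]

# rng stream codes, so each purpose/subject gets an independent deterministic
# stream derived from the one master seed
_STREAM_MAPS = 1
_STREAM_TC = 2
_STREAM_NOISE = 3
_STREAM_COHORT = 4


def _rng(seed: int, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream), int(index)])


@dataclass
class SymptomModel:
    """Linear model tying a symptom score to designated FNC pairs.

    ``score = sum_j betas[j] * FNC[pairs[j]] + covariate effects + noise``
    for case subjects; controls carry no score.
    """

    pairs: tuple = (0, 1)
    betas: tuple = (2.0, 4.0)
    noise_sd: float = 1.0
    fnc_sd: float = 0.15           # across-subject sd of each FNC pair
    group_offset: dict = field(default_factory=dict)  # pair index -> case offset


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the study conditions.

    Grid 20 x 20 x 10 at TR = 2 s with T = 200 frames mirrors a typical
    2-second-TR resting-state acquisition at toy spatial scale.  The
    continuous band is the analysis band [0.01, 0.15] Hz; SNR (network
    signal variance over noise variance) defaults to 2.
    """

    nx: int = 20
    ny: int = 20
    nz: int = 10
    n_networks: int = 5
    n_frames: int = 200
    tr: float = 2.0
    regime: str = "continuous"            # "continuous" | "event"
    event_rate: float = 2.0               # events per 100 frames per network
    band: tuple = (0.01, 0.15)            # Hz, continuous regime
    overlap: float = 0.0                  # [0, 1) between adjacent maps
    blob_sigma: float = 2.0               # voxels
    trend_coeffs: tuple = (1.0, 0.5, 0.3)  # linear/quad/cubic on u in [-1,1]
    spike_rate: float = 0.05              # spikes per 100 frames per voxel
    spike_mag: float = 6.0                # in robust-sigma (MAD) units
    motion_amp: float = 0.5
    snr: float | None = 2.0
    noise_sd: float | None = None         # overrides snr when set
    n_subjects: int = 10
    symptom_model: SymptomModel = field(default_factory=SymptomModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in ("continuous", "event"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap fraction must be in [0, 1)")
        lo, hi = self.band
        if not (0.01 - 1e-12 <= lo < hi <= 0.15 + 1e-12):
            raise ValueError("continuous band must lie inside [0.01, 0.15] Hz")
        if self.n_networks < 2:
            raise ValueError("need at least 2 networks")
        if self.n_frames < 100:
            raise ValueError("need at least 100 frames")

    @property
    def grid(self) -> tuple:
        return (self.nx, self.ny, self.nz)

    @property
    def n_voxels(self) -> int:
        return self.nx * self.ny * self.nz


@dataclass
class GroundTruth:
    """Everything the generator knows, for downstream recovery checks."""

    true_maps: np.ndarray          # K x V loadings
    true_timecourses: np.ndarray   # T x K (per subject: list indexed outside)
    regime: str
    event_onsets: list             # per-network frame-index lists
    hrf_params: dict
    noise_sd: float
    seed: int
    spike_locations: np.ndarray | None = None   # (n, 2) voxel/frame pairs
    motion: np.ndarray | None = None            # T x 6
    symptom_betas: np.ndarray | None = None
    symptom_pairs: tuple | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = self.true_maps.shape[0]
        if k < 2:
            raise ValueError("ground truth needs K >= 2 networks")
        mx = np.abs(self.true_maps).max(axis=1)
        if np.any(self.true_maps.max(axis=1) <= 0.5 * mx):
            raise ValueError("every map needs a voxel above half its maximum")
        if (self.regime == "continuous") != all(
            len(o) == 0 for o in self.event_onsets
        ):
            raise ValueError("event_onsets must be empty iff regime=continuous")


def double_gamma_hrf(
    tr: float,
    duration: float = 32.0,
    peak: float = 6.0,
    undershoot: float = 16.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at the repetition time.

    Peak at ``peak`` seconds, undershoot at ``undershoot`` seconds, with
    undershoot-to-peak amplitude ``ratio``; max-normalised to 1.
    """
    from scipy.stats import gamma

    t = np.arange(0.0, duration + tr / 2, tr)
    h = gamma.pdf(t, a=peak, scale=1.0) - ratio * gamma.pdf(t, a=undershoot, scale=1.0)
    return h / np.abs(h).max()


def hrf_support_frames(tr: float, rel_tol: float = 0.01, **hrf_kwargs) -> int:
    """Number of frames where the HRF magnitude exceeds ``rel_tol`` of its max."""
    h = double_gamma_hrf(tr, **hrf_kwargs)
    above = np.flatnonzero(np.abs(h) > rel_tol)
    return int(above[-1] + 1) if above.size else 0


def _gaussian_blob(grid: tuple, center: np.ndarray, sigma: float) -> np.ndarray:
    axes = [np.arange(n, dtype=float) for n in grid]
    zz = sum(
        ((ax.reshape([-1 if i == j else 1 for j in range(3)]) - center[i]) ** 2)
        for i, ax in enumerate(axes)
    )
    return np.exp(-zz / (2.0 * sigma**2))


def make_network_maps(config: SimConfig) -> list[SpatialMap]:
    """K smooth blob-like network maps (sums of 3-D Gaussians).

    Centres are placed by greedy repulsion so that with ``overlap = 0`` the
    maps are close to spatially disjoint; ``overlap > 0`` adds a bridging
    blob halfway between adjacent networks, raising their spatial
    correlation.  Each map is max-normalised to 1 and deterministic given
    the configuration seed.
    """
    if config.n_voxels < 8 * config.n_networks:
        raise ValueError(
            f"grid of {config.n_voxels} voxels is too small for "
            f"{config.n_networks} non-degenerate networks"
        )
    rng = _rng(config.seed, _STREAM_MAPS)
    grid = np.array(config.grid, dtype=float)
    sigma = config.blob_sigma
    margin = np.minimum(1.5 * sigma, grid / 4)
    # greedy repulsion; if a seed's draws stall, relax the separation — but
    # never below the distance keeping zero-overlap maps at |r| < 0.2
    # (exp(-d^2 / 4 sigma^2) < 0.2  =>  d > 2.54 sigma)
    d_min = 3.0 * sigma
    d_floor = 2.6 * sigma
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < config.n_networks:
        attempts += 1
        if attempts > 2000:
            d_min *= 0.95
            attempts = 0
            centers = []
            if d_min < d_floor:
                raise ValueError(
                    f"grid {config.grid} too small to place {config.n_networks} "
                    f"blobs of sigma {sigma} without degeneracy"
                )
        cand = margin + rng.random(3) * (grid - 2 * margin)
        if all(np.linalg.norm(cand - c) >= d_min for c in centers):
            centers.append(cand)

    maps = []
    for k, c in enumerate(centers):
        m = _gaussian_blob(config.grid, c, sigma)
        if config.overlap > 0:
            mid = 0.5 * (c + centers[(k + 1) % len(centers)])
            m = m + config.overlap * _gaussian_blob(config.grid, mid, sigma)
        m = m / m.max()
        maps.append(
            SpatialMap(m.ravel(), kind="stat", provenance={"network": k, "center": c.tolist()})
        )
    return maps


def _bandlimited_course(n_frames: int, tr: float, band: tuple, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian course band-limited by forward-backward Butterworth."""
    white = rng.standard_normal(n_frames + 200)  # pad to wash out filter edges
    nyq = 0.5 / tr
    sos = sps.butter(5, [band[0] / nyq, band[1] / nyq], btype="bandpass", output="sos")
    x = sps.sosfiltfilt(sos, white)[100 : 100 + n_frames]
    return (x - x.mean()) / x.std()


def make_timecourses(
    config: SimConfig, subject: int = 0
) -> tuple[np.ndarray, list]:
    """Per-network time courses under the configured regime.

    Returns a ``T x K`` matrix and per-network event-onset lists (empty in
    the continuous regime).  Event-regime courses are a binary spike train
    convolved with the double-gamma HRF, rescaled to unit variance without
    demeaning, so they stay exactly zero outside the HRF support of events.
    """
    rng = _rng(config.seed, _STREAM_TC, subject)
    T, K = config.n_frames, config.n_networks
    tcs = np.empty((T, K))
    onsets: list = []
    if config.regime == "continuous":
        for k in range(K):
            tcs[:, k] = _bandlimited_course(T, config.tr, config.band, rng)
            onsets.append([])
        return tcs, onsets

    if config.event_rate <= 0:
        raise ValueError("event regime requires a positive event rate")
    # truncate the kernel at its support so the course is *exactly* zero
    # outside the HRF support of events
    hrf = double_gamma_hrf(config.tr)[: hrf_support_frames(config.tr)]
    p = config.event_rate / 100.0
    for k in range(K):
        for _ in range(100):
            train = rng.random(T) < p
            if train.any():
                break
        else:  # pragma: no cover - p > 0 makes this astronomically unlikely
            raise ValueError("failed to draw any event")
        course = np.convolve(train.astype(float), hrf)[:T]
        sd = course.std()
        if sd == 0:
            raise ValueError("degenerate event course (zero variance)")
        tcs[:, k] = course / sd
        onsets.append(np.flatnonzero(train).tolist())
    return tcs, onsets


def _synthetic_motion(n_frames: int, rng: np.random.Generator) -> np.ndarray:
    """Six slow random-walk motion parameter traces (3 translation, 3 rotation)."""
    steps = rng.standard_normal((n_frames, 6)) * 0.02
    walk = np.cumsum(steps, axis=0)
    kernel = np.ones(5) / 5.0
    smooth = np.apply_along_axis(lambda c: np.convolve(c, kernel, mode="same"), 0, walk)
    return smooth - smooth.mean(axis=0)


def assemble_bold(
    maps: list[SpatialMap] | np.ndarray,
    timecourses: np.ndarray,
    config: SimConfig,
    subject: int = 0,
    event_onsets: list | None = None,
) -> tuple[BoldRun, NuisanceSet, GroundTruth]:
    """Mix maps and courses into one subject's run plus artifacts.

    ``X(v,t) = sum_k map_k(v) tc_k(t) + trend(t) + motion-coupled signal +
    spikes + N(0, noise_sd)``.  The returned :class:`NuisanceSet` carries the
    six synthetic motion parameters actually injected (plus derivatives);
    spike locations and motion are recorded in the :class:`GroundTruth`.
    """
    S = np.vstack([m.values if isinstance(m, SpatialMap) else np.ravel(m) for m in maps])
    tcs = np.asarray(timecourses, dtype=float)
    if S.shape[0] != tcs.shape[1]:
        raise ValueError(
            f"{S.shape[0]} maps but {tcs.shape[1]} time-course columns"
        )
    V, T = S.shape[1], tcs.shape[0]
    rng = _rng(config.seed, _STREAM_NOISE, subject)
    X = S.T @ tcs.T  # V x T

    # polynomial trend, per-voxel random amplitude
    u = np.linspace(-1.0, 1.0, T)
    c1, c2, c3 = config.trend_coeffs
    trend = c1 * u + c2 * u**2 + c3 * u**3
    if np.any(np.asarray(config.trend_coeffs) != 0):
        amp = rng.uniform(0.5, 1.5, size=V)
        X = X + amp[:, None] * trend[None, :]

    # motion-coupled nuisance signal in a random 20% of voxels
    motion = _synthetic_motion(T, rng)
    if config.motion_amp > 0:
        coupled = rng.random(V) < 0.2
        coupling = rng.standard_normal((6, V)) * config.motion_amp * coupled[None, :]
        X = X + (motion @ coupling).T

    # spikes, magnitude in robust-sigma units of each voxel's own course
    spike_locs = np.empty((0, 2), dtype=int)
    if config.spike_rate > 0:
        hits = rng.random((V, T)) < config.spike_rate / 100.0
        if hits.any():
            med = np.median(X, axis=1, keepdims=True)
            mad = np.median(np.abs(X - med), axis=1, keepdims=True)
            scale = 1.4826 * np.where(mad == 0, 1.0, mad)
            signs = np.where(rng.random((V, T)) < 0.5, -1.0, 1.0)
            X = X + hits * signs * config.spike_mag * scale
            spike_locs = np.argwhere(hits)

    # additive Gaussian noise calibrated to the requested SNR
    if config.noise_sd is not None:
        noise_sd = float(config.noise_sd)
    elif config.snr is not None and np.isfinite(config.snr):
        # SNR referenced to the peak network voxel: maps are max-normalised
        # to 1 and courses unit-variance, so peak signal variance is ~1
        sig_var = float(np.mean(np.max(S, axis=1) ** 2))
        noise_sd = float(np.sqrt(sig_var / config.snr))
    else:
        noise_sd = 0.0
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, size=(V, T))

    mask = np.ones(config.grid, dtype=bool)
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    run = BoldRun(X, mask, config.tr, subject_id=f"sub-{subject:02d}", affine=affine)
    nuisance = NuisanceSet.from_motion(motion)
    onsets = event_onsets if event_onsets is not None else [[] for _ in range(S.shape[0])]
    truth = GroundTruth(
        true_maps=S,
        true_timecourses=tcs,
        regime=config.regime,
        event_onsets=onsets,
        hrf_params={"peak": 6.0, "undershoot": 16.0, "ratio": 1.0 / 6.0},
        noise_sd=noise_sd,
        seed=config.seed,
        spike_locations=spike_locs,
        motion=motion,
    )
    return run, nuisance, truth


def simulate_dataset(
    config: SimConfig, n_subjects: int | None = None
) -> tuple[list[BoldRun], list[NuisanceSet], list[GroundTruth]]:
    """Simulate ``n_subjects`` runs sharing one set of true maps.

    Time courses, noise and artifacts are redrawn per subject from
    independent streams of the master seed.
    """
    n = config.n_subjects if n_subjects is None else n_subjects
    maps = make_network_maps(config)
    runs, nuis, truths = [], [], []
    for s in range(n):
        tcs, onsets = make_timecourses(config, subject=s)
        run, nn, gt = assemble_bold(maps, tcs, config, subject=s, event_onsets=onsets)
        runs.append(run)
        nuis.append(nn)
        truths.append(gt)
    return runs, nuis, truths


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": rng.uniform(18.0, 65.0, n),
            "sex": rng.integers(0, 2, n),
            "site": rng.integers(0, 3, n).astype(str),
            "mfd": rng.uniform(0.05, 0.25, n),
        }
    )


# linear confound effects injected into the symptom score
_COV_EFFECTS = {"age": 0.05, "sex": 1.0, "mfd": 3.0}
_SITE_EFFECTS = {"0": 0.0, "1": 0.5, "2": -0.5}


def _symptom_from(
    fnc: np.ndarray, cov: pd.DataFrame, model: SymptomModel, rng: np.random.Generator
) -> np.ndarray:
    score = np.zeros(len(cov))
    for pair, beta in zip(model.pairs, model.betas):
        score = score + beta * fnc[:, pair]
    score = (
        score
        + _COV_EFFECTS["age"] * cov["age"].to_numpy()
        + _COV_EFFECTS["sex"] * cov["sex"].to_numpy()
        + _COV_EFFECTS["mfd"] * cov["mfd"].to_numpy()
        + cov["site"].map(_SITE_EFFECTS).to_numpy()
    )
    return score + rng.normal(0.0, model.noise_sd, len(cov))


def make_cohort(
    config: SimConfig,
) -> tuple[list[BoldRun], pd.DataFrame, GroundTruth]:
    """Full imaging cohort: runs, covariate/symptom table and ground truth.

    Network 0 plays the target-network role; the K-1 FNC pairs are its
    correlations with the other networks.  Per-subject FNC targets are
    drawn around a common base, shifted by any case-group offsets in the
    symptom model, and realised by Cholesky-correlating the latent network
    courses.  Symptom scores exist for case subjects only.
    """
    n = config.n_subjects
    if n < 20:
        raise ValueError("cohort needs at least 20 subjects")
    model = config.symptom_model
    K = config.n_networks
    n_pairs = K - 1
    for p in model.pairs:
        if not (0 <= p < n_pairs):
            raise ValueError(f"symptom model pair index {p} out of range (K-1={n_pairs})")

    rng = _rng(config.seed, _STREAM_COHORT)
    cov = _draw_covariates(n, rng)
    diagnosis = np.array(["case" if i < n // 2 else "control" for i in range(n)])
    base = rng.uniform(0.15, 0.45, n_pairs)

    maps = make_network_maps(config)
    runs: list[BoldRun] = []
    fnc_target = np.empty((n, n_pairs))
    fnc_achieved = np.empty((n, n_pairs))
    for s in range(n):
        r_target = base + rng.normal(0.0, model.fnc_sd, n_pairs)
        if diagnosis[s] == "case":
            for pair, off in model.group_offset.items():
                r_target[pair] += off
        r_target = np.clip(r_target, -0.9, 0.9)
        fnc_target[s] = r_target

        latent, _ = make_timecourses(config, subject=s)
        tcs = latent.copy()
        for j in range(n_pairs):
            r = r_target[j]
            mixed = r * latent[:, 0] + np.sqrt(1 - r**2) * latent[:, j + 1]
            tcs[:, j + 1] = (mixed - mixed.mean()) / mixed.std()
        run, _, _ = assemble_bold(maps, tcs, config, subject=s)
        runs.append(run)
        centered = tcs - tcs.mean(axis=0)
        denom = np.linalg.norm(centered, axis=0)
        fnc_achieved[s] = (centered[:, 0] @ centered[:, 1:]) / (denom[0] * denom[1:])

    score = _symptom_from(fnc_achieved, cov, model, rng)
    score = np.where(diagnosis == "case", score, np.nan)

    table = cov.copy()
    table.insert(0, "subject_id", [f"sub-{i:02d}" for i in range(n)])
    table["diagnosis"] = diagnosis
    table["symptom"] = score
    for j in range(n_pairs):
        table[f"fnc_{j}"] = fnc_achieved[:, j]

    truth = GroundTruth(
        true_maps=np.vstack([m.values for m in maps]),
        true_timecourses=np.zeros((config.n_frames, K)),
        regime=config.regime,
        event_onsets=[[] for _ in range(K)] if config.regime == "continuous" else [[0]] * K,
        hrf_params={"peak": 6.0, "undershoot": 16.0, "ratio": 1.0 / 6.0},
        noise_sd=config.noise_sd if config.noise_sd is not None else -1.0,
        seed=config.seed,
        symptom_betas=np.asarray(model.betas, dtype=float),
        symptom_pairs=tuple(model.pairs),
        extras={"fnc_base": base.tolist(), "fnc_target": fnc_target},
    )
    return runs, table, truth


def make_symptom_cohort(
    n_subjects: int = 300,
    n_pairs: int = 9,
    model: SymptomModel | None = None,
    seed: int = 0,
    portion_models: dict | None = None,
    cross_portion_r: float = 0.5,
    score_all: bool = False,
) -> pd.DataFrame:
    """Cohort layer only: FNC vectors + covariates + symptom, no imaging.

    This is the fast path for validating the association stage at realistic
    cohort sizes.  When ``portion_models`` maps portion names (e.g. "all",
    "ept", "eat") to :class:`SymptomModel` instances, one FNC table is drawn
    per portion — tables share a subject-level factor with correlation
    ``cross_portion_r`` — and the symptom sums the designated effects across
    portions, letting tests plant pair effects unique to one portion.
    """
    if model is None and portion_models is None:
        model = SymptomModel()
    if portion_models is None:
        portion_models = {"all": model}
    rng = _rng(seed, _STREAM_COHORT, 1)
    cov = _draw_covariates(n_subjects, rng)
    diagnosis = np.array(
        ["case" if i < n_subjects // 2 else "control" for i in range(n_subjects)]
    )
    base = rng.uniform(0.15, 0.45, n_pairs)
    shared = rng.standard_normal((n_subjects, n_pairs))

    table = cov.copy()
    table.insert(0, "subject_id", [f"sub-{i:03d}" for i in range(n_subjects)])
    table["diagnosis"] = diagnosis
    score = np.zeros(n_subjects)
    any_model = None
    for portion, pmodel in portion_models.items():
        any_model = pmodel
        for p in pmodel.pairs:
            if not (0 <= p < n_pairs):
                raise ValueError(f"pair index {p} out of range for {n_pairs} pairs")
        own = rng.standard_normal((n_subjects, n_pairs))
        z = cross_portion_r * shared + np.sqrt(1 - cross_portion_r**2) * own
        fnc = base[None, :] + pmodel.fnc_sd * z
        for pair, off in pmodel.group_offset.items():
            fnc[diagnosis == "case", pair] += off
        fnc = np.clip(fnc, -1.0, 1.0)
        for j in range(n_pairs):
            col = f"fnc_{j}" if len(portion_models) == 1 else f"fnc_{portion}_{j}"
            table[col] = fnc[:, j]
        for pair, beta in zip(pmodel.pairs, pmodel.betas):
            score = score + beta * fnc[:, pair]
    score = (
        score
        + _COV_EFFECTS["age"] * cov["age"].to_numpy()
        + _COV_EFFECTS["sex"] * cov["sex"].to_numpy()
        + _COV_EFFECTS["mfd"] * cov["mfd"].to_numpy()
        + cov["site"].map(_SITE_EFFECTS).to_numpy()
        + rng.normal(0.0, any_model.noise_sd, n_subjects)
    )
    if score_all:
        table["symptom"] = score
    else:
        table["symptom"] = np.where(diagnosis == "case", score, np.nan)
    return table
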