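"""Group spatial ICA: two-level PCA, Infomax, run stability, GIG-ICA.

The group decomposition follows the standard two-level scheme: voxel time
courses are variance-normalised, each subject's data is reduced by spatial
PCA retaining > 99% of subject-level variance, the reductions are
concatenated over the time dimension and reduced again by group-level PCA
to the model order, and the whitened group subspace is unmixed with the
Infomax algorithm (natural-gradient maximum-likelihood ICA with a logistic
nonlinearity, appropriate for super-Gaussian spatial sources).

Because ICA is a stochastic optimisation, the unmixing is repeated from
many random initialisations and the pooled components are clustered by
absolute spatial correlation; each cluster's quality index

    Iq = mean within-cluster similarity - mean between-cluster similarity

measures run-to-run stability, and only components with Iq above a floor
(default 0.8) are used to identify networks.  The most central member of
each cluster (the centrotype) represents it.

Subject-specific maps and time courses are estimated by group
information-guided ICA (GIG-ICA): a one-unit negentropy maximisation
initialised from, and softly constrained to stay spatially close to, a
group reference map — falling back to dual regression when the reference
matches nothing in the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from scipy.stats import skew

from .core import BoldRun, ComponentSet, PcaReduction, SpatialMap, pearson, zscore

__all__ = [
    "variance_normalize",
    "subject_pca",
    "group_reduce",
    "infomax_ica",
    "icasso_stability",
    "gig_ica",
    "match_components",
    "run_group_ica",
    "MatchResult",
]


def variance_normalize(run: BoldRun) -> BoldRun:
    """Z-score every voxel time course (mean 0, sd 1 over time).

    Zero-variance voxels are removed from the mask with a warning; an
    all-constant run is an error.
    """
    sd = run.data.std(axis=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all voxel courses are constant")
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance voxel(s)")
        mask = run.mask.copy()
        mask[tuple(np.argwhere(run.mask)[~keep].T)] = False
        data = run.data[keep]
        data = (data - data.mean(axis=1, keepdims=True)) / data.std(axis=1, keepdims=True)
        from dataclasses import replace

        return replace(run, data=data, mask=mask)
    data = (run.data - run.data.mean(axis=1, keepdims=True)) / sd[:, None]
    return run.with_data(data)


def subject_pca(run: BoldRun, var_frac: float = 0.99) -> PcaReduction:
    """Subject-level spatial PCA over the time dimension.

    Frames are the variables and voxels the observations; the smallest
    number of components whose cumulative explained variance reaches
    ``var_frac`` is retained.
    """
    if run.n_frames < 2:
        raise ValueError("need at least 2 frames for PCA")
    A = run.data.T.copy()                   # T x V
    A -= A.mean(axis=1, keepdims=True)      # centre each frame across voxels
    U, s, _ = np.linalg.svd(A, full_matrices=False)
    ev = s**2
    total = ev.sum()
    if total == 0:
        raise ValueError("data has no variance")
    cum = np.cumsum(ev) / total
    if var_frac >= 1.0:
        m = int((s > s[0] * 1e-12).sum())
    else:
        m = int(np.searchsorted(cum, var_frac) + 1)
    basis = U[:, :m]                        # T x m
    reduced = basis.T @ A                   # m x V
    return PcaReduction(
        basis=basis,
        singular_values=s[:m],
        variance_retained=float(cum[m - 1]),
        level="subject",
        reduced=reduced,
    )


def group_reduce(reductions: list, model_order: int = 20) -> tuple[np.ndarray, dict]:
    """Group-level PCA of time-concatenated subject reductions, whitened.

    Returns ``(Y, info)`` where ``Y`` is ``model_order x V`` with
    ``Y @ Y.T / V = I`` (whitened over voxels).
    """
    if len(reductions) < 1:
        raise ValueError("need at least one subject reduction")
    R = np.vstack([r.reduced for r in reductions])
    R = R - R.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if rank < model_order:
        raise ValueError(
            f"combined data rank {rank} is below the requested model order "
            f"{model_order}; achievable order is {rank}"
        )
    V = R.shape[1]
    Y = np.sqrt(V) * Vt[:model_order]
    info = {
        "singular_values": s[:model_order],
        "explained_fraction": float((s[:model_order] ** 2).sum() / (s**2).sum()),
        "rank": rank,
    }
    return Y, info


def _logistic(u: np.ndarray) -> np.ndarray:
    out = np.empty_like(u)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    eu = np.exp(u[~pos])
    out[~pos] = eu / (1.0 + eu)
    return out


def infomax_ica(
    whitened: np.ndarray,
    seed: int = 0,
    lrate: float = 0.5,
    max_epochs: int = 512,
    tol: float = 1e-6,
) -> ComponentSet:
    """Single Infomax run on a whitened K x V matrix.

    Full-batch natural-gradient ascent of the Infomax likelihood with the
    logistic nonlinearity; the learning rate is annealed whenever an update
    overshoots.  Components are z-scored over voxels and sign-fixed so each
    spatial map has positive skewness.  Deterministic given the seed; a run
    that does not reach the tolerance is returned flagged, never silently.
    """
    X = np.asarray(whitened, dtype=float)
    K, V = X.shape
    rng = np.random.default_rng([int(seed), 77])
    W = np.linalg.qr(rng.standard_normal((K, K)))[0]
    eye = np.eye(K)
    lr = lrate
    prev_delta = np.inf
    converged = False
    for _ in range(max_epochs):
        U = W @ X
        Y = _logistic(U)
        grad = (eye + (1.0 - 2.0 * Y) @ U.T / V) @ W
        delta = np.linalg.norm(lr * grad)
        if not np.isfinite(delta) or delta > 1e6:
            # blow-up: restart from a fresh rotation with a smaller step
            lr *= 0.5
            W = np.linalg.qr(rng.standard_normal((K, K)))[0]
            prev_delta = np.inf
            continue
        W = W + lr * grad
        if delta < tol:
            converged = True
            break
        if delta > prev_delta * 1.1:
            lr *= 0.9
        prev_delta = delta
    S = W @ X
    # sign convention: spatial maps are super-Gaussian -> positive skewness
    signs = np.where(skew(S, axis=1) < 0, -1.0, 1.0)
    S *= signs[:, None]
    W *= signs[:, None]
    maps = zscore(S, axis=1)
    if not converged:
        warnings.warn("Infomax did not reach tolerance; result flagged")
    return ComponentSet(
        maps=maps,
        model_order=K,
        converged=converged,
        meta={"unmixing": W, "seed": int(seed), "lrate_final": lr},
    )


def icasso_stability(
    whitened: np.ndarray,
    n_runs: int = 20,
    iq_min: float = 0.8,
    seed: int = 0,
) -> ComponentSet:
    """Multi-run Infomax with agglomerative stability clustering.

    All ``n_runs x K`` components are pooled, clustered into K groups by
    average-linkage on ``1 - |spatial correlation|``, and each cluster is
    represented by its centrotype (the member most similar to the rest).
    Components are ordered by descending Iq; the full Iq vector is kept so
    callers can filter with :meth:`ComponentSet.stable`.
    """
    if n_runs < 2:
        raise ValueError("stability is undefined for a single run; need n_runs >= 2")
    X = np.asarray(whitened, dtype=float)
    K = X.shape[0]
    pool = []
    conv = []
    for r in range(n_runs):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cs = infomax_ica(X, seed=int(seed) * 10007 + r)
        pool.append(cs.maps)
        conv.append(cs.converged)
    P = np.vstack(pool)                      # (n_runs*K) x V
    sim = np.abs(np.corrcoef(P))
    np.fill_diagonal(sim, 1.0)
    dist = np.clip(1.0 - sim, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=K, criterion="maxclust")
    if len(np.unique(labels)) < K:
        raise ValueError(f"clustering produced fewer than {K} clusters")

    centros = np.empty((K, X.shape[1]))
    iq = np.empty(K)
    sizes = np.empty(K, dtype=int)
    for c, lab in enumerate(np.unique(labels)):
        members = np.flatnonzero(labels == lab)
        others = np.flatnonzero(labels != lab)
        sub = sim[np.ix_(members, members)]
        if members.size > 1:
            intra = (sub.sum() - members.size) / (members.size * (members.size - 1))
        else:
            intra = 1.0
        inter = sim[np.ix_(members, others)].mean() if others.size else 0.0
        iq[c] = intra - inter
        centrality = sub.sum(axis=1)
        centros[c] = P[members[int(np.argmax(centrality))]]
        sizes[c] = members.size
    order = np.argsort(-iq)
    return ComponentSet(
        maps=zscore(centros[order], axis=1),
        stability=iq[order],
        model_order=K,
        converged=all(conv),
        meta={
            "n_runs": n_runs,
            "iq_min": iq_min,
            "cluster_sizes": sizes[order].tolist(),
            "seed": int(seed),
        },
    )


def _dual_regression(data: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map and course from plain dual regression against one reference map."""
    rc = ref - ref.mean()
    tc = (rc @ data) / (rc @ rc)                       # length T
    tcc = tc - tc.mean()
    mp = (data @ tcc) / (tcc @ tcc)                    # length V
    return mp, tc


def gig_ica(
    run: BoldRun,
    references: list,
    rho_min: float = 0.2,
    max_iter: int = 200,
    max_rank: int = 60,
) -> ComponentSet:
    """Subject-specific maps/courses via reference-guided one-unit ICA.

    Per reference: the whitened subject data is initialised from the
    regression of the reference map, then a one-unit negentropy
    approximation (log-cosh contrast, FastICA fixed point) is maximised
    while keeping the estimate's spatial correlation with the reference at
    or above ``rho_min``.  If even the initial regression matches the data
    at |r| < ``rho_min`` the estimate falls back to dual regression and is
    flagged.  The returned time course is the least-squares projection of
    the data onto the final map.
    """
    refs = [r.values if isinstance(r, SpatialMap) else np.asarray(r, float).ravel()
            for r in references]
    if any(r.size != run.n_voxels for r in refs):
        raise ValueError("reference maps must live on the run grid")
    Xc = run.data - run.data.mean(axis=1, keepdims=True)   # V x T, centred

    A = Xc.T.copy()                                    # T x V
    A -= A.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum())
    p = min(rank, max_rank)
    V = A.shape[1]
    Z = np.sqrt(V) * Vt[:p]                            # p x V, Z Z^T / V = I

    internal = np.empty((len(refs), run.n_voxels))
    fallback = []
    match_r = []
    for j, ref in enumerate(refs):
        r = (ref - ref.mean()) / ref.std()
        # does the reference match anything in the data? compare against
        # the subject PCA component maps
        comp_match = float(np.abs([pearson(z, r) for z in Z]).max()) if p else 0.0
        w = Z @ r / V                                  # projection coefficients
        nw = np.linalg.norm(w)
        if nw == 0 or comp_match < rho_min:
            warnings.warn(
                f"reference {j}: uncorrelated with all data components "
                f"(best |r|={comp_match:.2f} < {rho_min}); falling back to "
                "dual regression"
            )
            mp, _ = _dual_regression(Xc, r)
            internal[j] = mp
            fallback.append(True)
            match_r.append(comp_match)
            continue
        w /= nw
        w0 = w.copy()
        c0 = pearson(w @ Z, r)
        for _ in range(max_iter):
            u = w @ Z
            g = np.tanh(u)
            w_new = Z @ g / V - (1.0 - g**2).mean() * w
            w_new /= np.linalg.norm(w_new)
            if w_new @ w < 0:
                w_new = -w_new
            # closeness constraint: blend back toward the reference direction
            alpha = 0.5
            for _ in range(20):
                if abs(pearson(w_new @ Z, r)) >= rho_min:
                    break
                w_new = w_new + alpha * (w0 if c0 >= 0 else -w0)
                w_new /= np.linalg.norm(w_new)
            if abs(w_new @ w) > 1.0 - 1e-10:
                w = w_new
                break
            w = w_new
        m = w @ Z
        if pearson(m, r) < 0:
            m = -m
        internal[j] = m
        fallback.append(False)
        match_r.append(0.0)  # filled after finalisation

    # joint back-reconstruction: courses from the internal maps, final maps
    # from the *raw* data regressed on all courses at once (removes
    # cross-network contamination), denoised by projection onto the subject
    # PCA spatial subspace
    Dm = np.column_stack([np.ones(run.n_voxels), internal.T])
    tcs_beta, *_ = np.linalg.lstsq(Dm, Xc, rcond=None)
    tcs = tcs_beta[1:].T                                   # T x n_refs
    Dt = np.column_stack([np.ones(run.n_frames), tcs])
    maps_beta, *_ = np.linalg.lstsq(Dt, run.data.T, rcond=None)
    maps = np.empty((len(refs), run.n_voxels))
    for j in range(len(refs)):
        mp = Z.T @ (Z @ maps_beta[1 + j]) / V
        maps[j] = zscore(mp)
        match_r[j] = pearson(maps[j], refs[j] - refs[j].mean())
    return ComponentSet(
        maps=maps,
        timecourses=tcs,
        model_order=len(refs),
        meta={"fallback": fallback, "reference_match": match_r, "rho_min": rho_min},
    )


@dataclass
class MatchResult:
    """One-to-one component matching between two sets."""

    pairs: list                 # (index in a, index in b)
    correlations: np.ndarray    # signed spatial r per pair
    unmatched_a: list
    unmatched_b: list

    def mean_abs_r(self) -> float:
        return float(np.abs(self.correlations).mean())


def match_components(a: ComponentSet, b: ComponentSet) -> MatchResult:
    """Optimal one-to-one assignment maximising total |spatial r|."""
    if a.maps.shape[1] != b.maps.shape[1]:
        raise ValueError("component sets are on different grids")
    ka, kb = a.n_components, b.n_components
    C = np.empty((ka, kb))
    for i in range(ka):
        for j in range(kb):
            C[i, j] = pearson(a.maps[i], b.maps[j])
    rows, cols = linear_sum_assignment(-np.abs(C))
    pairs = list(zip(rows.tolist(), cols.tolist()))
    corr = np.array([C[i, j] for i, j in pairs])
    return MatchResult(
        pairs=pairs,
        correlations=corr,
        unmatched_a=sorted(set(range(ka)) - {i for i, _ in pairs}),
        unmatched_b=sorted(set(range(kb)) - {j for _, j in pairs}),
    )


def run_group_ica(
    runs: list,
    model_order: int = 8,
    n_runs: int = 20,
    seed: int = 0,
    var_frac: float = 0.99,
    iq_min: float = 0.8,
) -> ComponentSet:
    """Full group pipeline: normalise, two-level PCA, multi-run Infomax.

    The toy-scale default model order is 8; the extreme-time-point count in
    the selection stage is conventionally tied to this order.
    """
    if len(runs) < 2:
        raise ValueError("group ICA needs at least 2 subjects")
    reductions = [subject_pca(variance_normalize(r), var_frac) for r in runs]
    Y, info = group_reduce(reductions, model_order)
    comp = icasso_stability(Y, n_runs=n_runs, iq_min=iq_min, seed=seed)
    comp.meta["group_pca"] = {k: v for k, v in info.items() if k != "singular_values"}
    return comp
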