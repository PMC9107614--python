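"""Functional network connectivity and clinical association statistics.

Given per-subject network time courses, functional network connectivity
(FNC) is the Pearson correlation between a target network's course and each
other network's course, computed over any frame selection (all frames, or
the target's extreme time points only).  The association stage then asks
which FNC pairs relate to a continuous symptom score:

1. FNC values and the score are residualised on age, sex, site (one-hot)
   and mean framewise displacement;
2. LASSO with 10-fold cross-validation, repeated over 50 Monte-Carlo fold
   draws, selects the pairs with non-zero coefficients at the
   minimum-cross-validated-MSE penalty;
3. the selected pairs are tested for case/control discrimination with a
   logistic model, p-values Benjamini-Hochberg corrected;
4. voxel-wise group differences in subject spatial maps are assessed with a
   per-voxel OLS contrast under the same confounds and FDR correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .core import TimepointSelection

__all__ = [
    "fnc",
    "residualize_covariates",
    "lasso_select",
    "group_discrimination",
    "voxelwise_group_glm",
    "LassoReport",
    "covariate_design",
]

COVARIATE_COLUMNS = ("age", "sex", "site", "mfd")


def fnc(
    target_tc: np.ndarray,
    other_tcs: np.ndarray,
    sel: TimepointSelection | None = None,
) -> np.ndarray:
    """FNC vector: Pearson r between the target course and each other course.

    Restricted to the selection when one is given.  A pair whose course is
    constant over the selection yields NaN with a warning (flagged entry).
    """
    t = np.asarray(target_tc, dtype=float).ravel()
    O = np.atleast_2d(np.asarray(other_tcs, dtype=float))
    if O.shape[0] == t.size and O.shape[1] != t.size:
        O = O.T                                # accept T x K or K x T
    if sel is not None:
        if len(sel) < 3:
            raise ValueError("need at least 3 selected frames for FNC")
        t = t[sel.indices]
        O = O[:, sel.indices]
    tc = t - t.mean()
    nt = np.linalg.norm(tc)
    if nt == 0:
        raise ValueError("target course constant over the selection")
    Oc = O - O.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(Oc, axis=1) * nt
    bad = denom == 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} constant course(s); FNC entries set to NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Oc @ tc) / np.where(bad, np.nan, denom)
    return np.clip(r, -1.0, 1.0)


def covariate_design(cohort: pd.DataFrame) -> np.ndarray:
    """Intercept + age + sex + mFD + one-hot site (first level dropped)."""
    site = pd.get_dummies(cohort["site"].astype(str), prefix="site", drop_first=True)
    D = np.column_stack(
        [
            np.ones(len(cohort)),
            cohort["age"].to_numpy(float),
            cohort["sex"].to_numpy(float),
            cohort["mfd"].to_numpy(float),
            site.to_numpy(float),
        ]
    )
    return D


def residualize_covariates(values: np.ndarray, cohort: pd.DataFrame) -> np.ndarray:
    """OLS residuals of a per-subject vector (or n x p matrix) on covariates.

    Site is one-hot coded; rank-deficient designs are reduced with a
    warning.  Residuals are orthogonal to the retained design columns.
    """
    X = np.asarray(values, dtype=float)
    squeeze = X.ndim == 1
    X = np.atleast_2d(X.T).T if squeeze else X
    D = covariate_design(cohort)
    if D.shape[0] != X.shape[0]:
        raise ValueError("covariate table and values have different lengths")
    q, r = np.linalg.qr(D)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} collinear covariate column(s)")
        D = D[:, keep]
    beta, *_ = np.linalg.lstsq(D, X, rcond=None)
    res = X - D @ beta
    return res[:, 0] if squeeze else res


@dataclass
class LassoReport:
    """Outcome of repeated cross-validated LASSO selection."""

    chosen_lambda: float
    lambdas: np.ndarray                  # per repetition
    coefficients: np.ndarray             # reps x p, per-repetition refit
    selection_frequency: np.ndarray      # per predictor, over repetitions
    min_cv_mse: float
    final_coefficients: np.ndarray       # refit at the repetition-median lambda
    nonzero: list                        # final non-zero predictor indices
    all_zero: bool = False
    meta: dict = field(default_factory=dict)


def lasso_select(
    X: np.ndarray,
    y: np.ndarray,
    cv: int = 10,
    reps: int = 50,
    seed: int = 0,
    n_lambdas: int = 100,
    se_tolerance: float = 1.0,
) -> LassoReport:
    """LASSO feature selection with Monte-Carlo cross-validation.

    Per repetition the folds are redrawn at random, the penalty path is
    cross-validated, the minimum-mean-CV-MSE lambda is located, and the
    model is refit on all data at that lambda.  The final non-zero set
    comes from a refit at the repetition-median lambda; an all-zero final
    model is reported explicitly — it means no predictor relates to the
    outcome beyond a constant.

    Because the CV MSE is itself an estimate, differences smaller than its
    standard error cannot justify a denser model: lambdas whose mean MSE is
    within ``se_tolerance`` standard errors of the minimum are treated as
    ties and the heaviest such penalty wins.  ``se_tolerance=0`` gives the
    literal minimum, which on a fixed dataset admits every predictor with a
    chance correlation; the default of 1 resolves ties at the resolution
    the CV estimate actually supports.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 50:
        raise ValueError("need at least 50 subjects for stable selection")
    if n < cv:
        raise ValueError("fewer subjects than folds")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in predictors or outcome")

    lambdas = np.empty(reps)
    coefs = np.empty((reps, p))
    mses = np.empty(reps)
    for rep in range(reps):
        folds = KFold(
            n_splits=cv, shuffle=True,
            random_state=(int(seed) * 1009 + rep) % (2**32 - 1),
        )
        model = LassoCV(cv=folds, alphas=n_lambdas, max_iter=50_000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, y)
        # alphas_ is descending; argmin takes the first (largest-penalty) tie
        mean_mse = model.mse_path_.mean(axis=1)
        best = int(np.argmin(mean_mse))
        if se_tolerance > 0:
            se = model.mse_path_.std(axis=1) / np.sqrt(model.mse_path_.shape[1])
            within = mean_mse <= mean_mse[best] + se_tolerance * se[best]
            best = int(np.flatnonzero(within)[0])
        lam = float(model.alphas_[best])
        refit = Lasso(alpha=lam, max_iter=50_000).fit(X, y)
        lambdas[rep] = lam
        coefs[rep] = refit.coef_
        mses[rep] = float(mean_mse[best])

    lam_final = float(np.median(lambdas))
    final = Lasso(alpha=lam_final, max_iter=50_000).fit(X, y)
    nonzero = np.flatnonzero(final.coef_ != 0).tolist()
    return LassoReport(
        chosen_lambda=lam_final,
        lambdas=lambdas,
        coefficients=coefs,
        selection_frequency=(coefs != 0).mean(axis=0),
        min_cv_mse=float(mses.min()),
        final_coefficients=final.coef_.copy(),
        nonzero=nonzero,
        all_zero=len(nonzero) == 0,
        meta={"cv": cv, "reps": reps, "seed": int(seed)},
    )


def _ridge_logistic(
    X: np.ndarray, y: np.ndarray, eps: float = 1e-3, max_iter: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Newton logistic fit with a small ridge; returns (beta, bse)."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = mu * (1 - mu)
        H = X.T @ (X * w[:, None]) + 2 * eps * np.eye(p)
        g = X.T @ (y - mu) - 2 * eps * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.linalg.norm(step) < 1e-10:
            break
    cov = np.linalg.inv(H)
    return beta, np.sqrt(np.diag(cov))


def group_discrimination(
    features: np.ndarray,
    diagnosis: np.ndarray,
    cohort: pd.DataFrame | None = None,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Logistic case/control model on (residualised) features with FDR.

    Features are residualised on the covariates when a cohort table is
    given.  Returns one row per feature with the coefficient, Wald p-value
    and Benjamini-Hochberg significance flag.  Perfect separation triggers
    a lightly ridge-penalised refit, flagged in the output.
    """
    import statsmodels.api as sm

    F = np.atleast_2d(np.asarray(features, dtype=float))
    if F.shape[0] != np.asarray(diagnosis).size:
        F = F.T
    y = (np.asarray(diagnosis) == np.asarray(diagnosis)[0]).astype(float)
    classes, counts = np.unique(diagnosis, return_counts=True)
    if len(classes) != 2 or counts.min() < 20:
        raise ValueError("need two classes with at least 20 subjects each")
    if cohort is not None:
        F = residualize_covariates(F, cohort)
    D = np.column_stack([np.ones(len(y)), F])
    penalized = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, D).fit(disp=0, maxiter=200)
        beta, bse = fit.params, fit.bse
        if not np.all(np.isfinite(bse)) or np.any(np.abs(beta) > 50):
            raise ValueError("separation")
    except Exception:
        penalized = True
        beta, bse = _ridge_logistic(D, y)
    from scipy.stats import norm

    z = beta[1:] / bse[1:]
    pvals = 2 * norm.sf(np.abs(z))
    sig, p_adj, *_ = multipletests(pvals, alpha=fdr_alpha, method="fdr_bh")
    return pd.DataFrame(
        {
            "coefficient": beta[1:],
            "p_value": pvals,
            "p_fdr": p_adj,
            "significant": sig,
            "penalized": penalized,
        }
    )


def voxelwise_group_glm(
    subject_maps: np.ndarray,
    diagnosis: np.ndarray,
    cohort: pd.DataFrame | None = None,
    fdr_alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel OLS group contrast with confounds and BH-FDR.

    ``subject_maps`` is n x V.  Returns the per-voxel t statistic for the
    diagnosis contrast and the boolean FDR-significant mask.
    """
    from scipy.stats import t as tdist

    Y = np.asarray(subject_maps, dtype=float)
    y_group = (np.asarray(diagnosis) == np.asarray(diagnosis)[0]).astype(float)
    classes, counts = np.unique(diagnosis, return_counts=True)
    if len(classes) != 2 or counts.min() < 20:
        raise ValueError("need two classes with at least 20 subjects each")
    if np.allclose(Y.std(axis=0), 0):
        raise ValueError("subject maps are constant across the cohort")
    cols = [np.ones(len(y_group)), y_group - y_group.mean()]
    if cohort is not None:
        D_cov = covariate_design(cohort)[:, 1:]
        cols.extend(D_cov.T)
    D = np.column_stack(cols)
    n, q = D.shape
    pinv = np.linalg.pinv(D)
    beta = pinv @ Y                                    # q x V
    resid = Y - D @ beta
    dof = n - np.linalg.matrix_rank(D)
    sigma2 = (resid**2).sum(axis=0) / dof
    c = np.zeros(q)
    c[1] = 1.0
    var_c = float(c @ pinv @ pinv.T @ c)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta[1] / np.sqrt(sigma2 * var_c)
    tstat = np.nan_to_num(tstat)
    pvals = 2 * tdist.sf(np.abs(tstat), dof)
    sig, *_ = multipletests(pvals, alpha=fdr_alpha, method="fdr_bh")
    return tstat, sig
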