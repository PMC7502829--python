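"""Covariate-adjusted normative model and voxelwise EZ deviation maps.

The reference half of the control cohort defines, per skeleton voxel, what
FA a healthy brain of a given age, sex and education should show.  A
subject's deviation map is

    EZ(v) = (FA_adj(v) - mu(v)) / sigma(v)

where FA_adj removes the reference-fitted covariate effects (only where
the per-voxel omnibus regression is significant at p < .05, uncorrected)
and mu, sigma are bootstrap-aggregated reference statistics.

Estimating sigma from a small reference sample inflates |EZ| tail rates,
so sigma is a *predictive* SD built from the exact pivotal quantity: a
held-out subject satisfies (x - mean)/(s sqrt(1+1/n)) ~ t(nu), so the
averaged bootstrap replicate variances (computed over the distinct
reference subjects, adjusted with each replicate's coefficients) are
df-corrected for the regression at adjusted voxels, inflated by
sqrt(1 + (1+p)/n) for the sampling error of the mean and the adjustment,
and scaled by t_{nu,.975}/z_{.975} so the fixed normal threshold 1.96
achieves its nominal 5% two-tailed rate on held-out null controls (see
docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "COV_COLS",
    "CovariateModel",
    "NormativeModel",
    "split_controls",
    "fit_covariate_model",
    "adjust_fa",
    "build_normative_model",
    "compute_ez",
    "NormativeEZ",
]

COV_COLS = ("age", "sex", "education")


def _design(covariates: pd.DataFrame) -> np.ndarray:
    missing = set(COV_COLS) - set(covariates.columns)
    if missing:
        raise ValueError(f"covariates missing columns: {sorted(missing)}")
    X = covariates.loc[:, list(COV_COLS)].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = covariates.loc[np.isnan(X).any(axis=1)]
        raise ValueError(f"covariates missing for subjects: {list(bad.index)}")
    return X


@dataclass
class CovariateModel:
    """Per-voxel OLS of FA on (age, sex, education) from one reference fit."""

    coef: np.ndarray  # (3, V) slopes, covariate order COV_COLS
    intercept: np.ndarray  # (V,)
    pvalues: np.ndarray  # (V,) omnibus F-test
    sig_mask: np.ndarray  # (V,) bool, p < alpha
    cov_means: np.ndarray  # (3,) reference covariate means
    n: int
    alpha: float = 0.05


def split_controls(
    covariates: pd.DataFrame, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split controls into covariate-balanced reference / normal halves.

    Greedy pairwise matching: subjects are paired by nearest neighbour in
    standardized (age, sex, education) space, and each pair is split
    randomly between the halves.  Disjoint, exhaustive, deterministic
    given ``seed``.
    """
    n = len(covariates)
    if n < 8:
        raise ValueError(f"need at least 8 controls to split, got {n}")
    X = _design(covariates)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    d2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(axis=-1)
    np.fill_diagonal(d2, np.inf)
    rng = np.random.default_rng(seed)
    unused = list(range(n))
    ref_rows: list[int] = []
    norm_rows: list[int] = []
    while len(unused) >= 2:
        sub = d2[np.ix_(unused, unused)]
        i, j = np.unravel_index(np.argmin(sub), sub.shape)
        a, b = unused[i], unused[j]
        if rng.random() < 0.5:
            a, b = b, a
        ref_rows.append(a)
        norm_rows.append(b)
        unused.remove(a)
        unused.remove(b)
    if unused:  # odd count: leftover goes to a random half
        (ref_rows if rng.random() < 0.5 else norm_rows).append(unused.pop())
    return covariates.iloc[sorted(ref_rows)], covariates.iloc[sorted(norm_rows)]


def fit_covariate_model(
    fa: np.ndarray, covariates: pd.DataFrame, alpha: float = 0.05
) -> CovariateModel:
    """OLS of FA on (age, sex, education) at every voxel.

    A voxel enters the significance mask when the regression's omnibus
    F-test has p < ``alpha`` (uncorrected, by design).
    """
    fa = np.atleast_2d(np.asarray(fa, dtype=float))
    X = _design(covariates)
    n, V = fa.shape
    p = X.shape[1]
    if n != X.shape[0]:
        raise ValueError(f"{n} FA rows but {X.shape[0]} covariate rows")
    if n <= p + 1:
        raise ValueError(f"reference size {n} must exceed number of covariates + 1 ({p + 1})")
    for k, name in enumerate(COV_COLS):
        if np.ptp(X[:, k]) == 0:
            raise ValueError(f"covariate '{name}' is constant: design is rank deficient")
    cov_means = X.mean(axis=0)
    Xc = X - cov_means
    design = np.column_stack([np.ones(n), Xc])
    if np.linalg.matrix_rank(design) < p + 1:
        raise ValueError("covariate design is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(design, fa, rcond=None)
    resid = fa - design @ beta
    rss = (resid**2).sum(axis=0)
    tss = ((fa - fa.mean(axis=0)) ** 2).sum(axis=0)
    df_den = n - p - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((tss - rss) / p) / (rss / df_den)
    pvals = np.where(np.isfinite(F), stats.f.sf(F, p, df_den), np.where(tss > 0, 0.0, 1.0))
    return CovariateModel(
        coef=beta[1:],
        intercept=beta[0],
        pvalues=pvals,
        sig_mask=pvals < alpha,
        cov_means=cov_means,
        n=n,
        alpha=alpha,
    )


def adjust_fa(
    fa: np.ndarray,
    model: CovariateModel,
    covariates: pd.DataFrame,
) -> np.ndarray:
    """Remove covariate effects at significant voxels.

    FA minus (covariate deviation from reference means) . slopes where the
    significance mask holds; unchanged elsewhere.  A subject at the
    reference covariate means is returned untouched.
    """
    fa = np.asarray(fa, dtype=float)
    single = fa.ndim == 1
    fa2 = np.atleast_2d(fa)
    X = _design(covariates)
    if X.shape[0] != fa2.shape[0]:
        raise ValueError(f"{fa2.shape[0]} FA rows but {X.shape[0]} covariate rows")
    delta = (X - model.cov_means) @ model.coef  # (n, V)
    adjusted = fa2 - delta * model.sig_mask
    return adjusted[0] if single else adjusted


@dataclass
class NormativeModel:
    """Bootstrap-aggregated reference statistics plus covariate model."""

    mu: np.ndarray  # (V,)
    sigma: np.ndarray  # (V,) predictive SD, > 0 everywhere
    covariate_model: CovariateModel
    n_reference: int
    B: int
    seed: int
    n_redraws: int = 0

    def __post_init__(self) -> None:
        if np.any(self.sigma <= 0):
            bad = int(np.sum(self.sigma <= 0))
            raise ValueError(
                f"sigma must be positive on all modelled voxels ({bad} voxels at zero: "
                "degenerate reference sample)"
            )


def build_normative_model(
    reference_fa: np.ndarray,
    reference_covariates: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> NormativeModel:
    """Bootstrap the reference half into per-voxel mu and predictive sigma.

    For each of B resamples (with replacement): refit the covariate
    slopes on the resample, adjust the *full* reference set with them
    under the frozen full-fit significance mask, and accumulate per-voxel
    mean and variance over the n distinct reference subjects.  Replicate
    variances therefore include the sampling variation of the adjustment
    coefficients, the quantity the bootstrap exists to capture, without
    the resample-duplicate shrinkage that plagues variances computed on
    the resampled rows themselves.  Replicates with a rank-deficient
    design (e.g. a single-sex resample) are redrawn; more than 50%
    redraws aborts.  ``B=1`` with an identity resample reduces to the
    plain sample mean/SD of adjusted reference FA up to the documented
    bias-correction factors.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    fa = np.atleast_2d(np.asarray(reference_fa, dtype=float))
    n, V = fa.shape
    rng = np.random.default_rng(seed)
    full_fit = fit_covariate_model(fa, reference_covariates, alpha=alpha)
    X_dev = _design(reference_covariates) - full_fit.cov_means

    mu_acc = np.zeros(V)
    var_acc = np.zeros(V)
    coef_acc = np.zeros_like(full_fit.coef)
    n_redraws = 0
    max_redraws = max(1, B // 2)
    b = 0
    while b < B:
        idx = rng.integers(0, n, n)
        try:
            fit_b = fit_covariate_model(
                fa[idx], reference_covariates.iloc[idx], alpha=alpha
            )
        except ValueError:
            n_redraws += 1
            if n_redraws > max_redraws:
                raise ValueError(
                    f"more than 50% of bootstrap replicates rank deficient "
                    f"({n_redraws} redraws for B={B})"
                )
            continue
        adj = fa - (X_dev @ fit_b.coef) * full_fit.sig_mask
        mu_acc += adj.mean(axis=0)
        var_acc += adj.var(axis=0, ddof=1)
        coef_acc += fit_b.coef
        b += 1

    mu = mu_acc / B
    # predictive SD from the t pivot of a held-out subject:
    #   unadjusted voxels: (x - mean)/(s sqrt(1+1/n)) ~ t(n-1)
    #   adjusted voxels:   regression soaks p df out of the replicate
    #                      variance and adds ~p/n prediction variance
    p = full_fit.coef.shape[0]
    p_vox = np.where(full_fit.sig_mask, p, 0)
    nu = n - 1 - p_vox
    df_corr = (n - 1) / nu  # undo regression shrinkage of the variance
    t_scale = stats.t.ppf(0.975, nu) / stats.norm.ppf(0.975)
    sigma = (
        np.sqrt(var_acc / B * df_corr)
        * t_scale
        * np.sqrt(1.0 + (1.0 + p_vox) / n)
    )
    cov_model = CovariateModel(
        coef=coef_acc / B,
        intercept=full_fit.intercept,
        pvalues=full_fit.pvalues,
        sig_mask=full_fit.sig_mask,
        cov_means=full_fit.cov_means,
        n=n,
        alpha=alpha,
    )
    return NormativeModel(
        mu=mu,
        sigma=sigma,
        covariate_model=cov_model,
        n_reference=n,
        B=B,
        seed=seed,
        n_redraws=n_redraws,
    )


def compute_ez(
    fa: np.ndarray, model: NormativeModel, covariates: pd.DataFrame | None = None
) -> np.ndarray:
    """Voxelwise EZ deviation map(s): (FA_adj - mu) / sigma.

    If ``covariates`` is given the FA is covariate-adjusted first;
    otherwise it is assumed already adjusted.
    """
    fa = np.asarray(fa, dtype=float)
    if fa.shape[-1] != model.mu.size:
        raise ValueError(
            f"model covers {model.mu.size} voxels but image has {fa.shape[-1]}"
        )
    adj = adjust_fa(fa, model.covariate_model, covariates) if covariates is not None else fa
    return (adj - model.mu) / model.sigma


class NormativeEZ(BaseEstimator, TransformerMixin):
    """Scikit-learn style wrapper: fit on the reference controls, transform
    any subject stack into EZ deviation maps.

    Parameters
    ----------
    B : int
        Bootstrap replicate count (default 1000).
    alpha : float
        Per-voxel covariate significance level (default .05, uncorrected).
    seed : int
        Bootstrap seed.
    """

    def __init__(self, B: int = 1000, alpha: float = 0.05, seed: int = 0):
        self.B = B
        self.alpha = alpha
        self.seed = seed

    def fit(self, X: np.ndarray, covariates: pd.DataFrame) -> "NormativeEZ":
        self.model_ = build_normative_model(
            X, covariates, B=self.B, seed=self.seed, alpha=self.alpha
        )
        self.n_features_in_ = self.model_.mu.size
        return self

    def transform(self, X: np.ndarray, covariates: pd.DataFrame | None = None) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise ValueError("NormativeEZ is not fitted")
        return compute_ez(X, self.model_, covariates)
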