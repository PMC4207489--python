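"""The L1-penalised fitting contract and the two-stage regression.

Stage 1 fits, per sample s, the gene-wise model

    y_gs = alpha_s + phi_s * c_gs + psi_s * d_gs
           + sum_t w_ts * b_tg + sum_m u_ms * (s_mg * x_ms) + eps

recovering sample-specific TF activities W (T x N) and miRNA activities
U (M x N) alongside intercept and CNV/methylation offsets.  Stage 2 fits,
per gene g, the sample-wise model

    y_gs = beta0_g + beta_c,g * c_gs + beta_d,g * d_gs
           + sum_{t: b_tg > 0} theta_gt * w_ts
           + sum_{m: s_mg > 0} theta_gm * u~_ms + eps

where u~ is the miRNA activity row-weighted by its cross-sample mean,
yielding interaction-score matrices Theta_TF (G x T) and Theta_miR (G x M)
restricted to candidate regulators with nonzero binding signal / seed sites.

Both stages use the same fitting contract: least squares with an L1
penalty, predictors standardised internally to unit variance, intercept
unpenalised, coefficients reported on the original predictor scale, and —
when ``lam="cv"`` — the penalty weight chosen to minimise mean k-fold
cross-validated squared error over a 100-point log-spaced path from
lambda_max down to 1e-3 * lambda_max, with fold assignment fixed by seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .core_io import OmicsBundle

logger = logging.getLogger(__name__)

__all__ = [
    "LassoFit",
    "Stage1Fit",
    "Stage2Fit",
    "lasso_fit",
    "fit_stage1",
    "weight_mir_activities",
    "fit_stage2",
    "predict_expression",
    "stage1_design",
    "stage2_design",
]

N_LAMBDA = 100
LAMBDA_MIN_RATIO = 1e-3


@dataclass
class LassoFit:
    """One penalised least-squares fit on the original predictor scale."""

    coefficients: np.ndarray
    intercept: float
    lambda_selected: float
    rss: float
    fitted: np.ndarray


@dataclass
class Stage1Fit:
    """Per-sample intercepts/offsets and activity matrices W (T x N), U (M x N)."""

    alpha: np.ndarray
    phi: np.ndarray
    psi: np.ndarray
    W: np.ndarray
    U: np.ndarray
    rss_per_sample: np.ndarray
    lambda_per_sample: np.ndarray


@dataclass
class Stage2Fit:
    """Per-gene offsets and interaction scores Theta_TF (G x T), Theta_miR (G x M)."""

    gene_intercept: np.ndarray
    gene_cnv_coef: np.ndarray
    gene_dm_coef: np.ndarray
    Theta_TF: np.ndarray
    Theta_miR: np.ndarray
    rss_per_gene: np.ndarray
    lambda_per_gene: np.ndarray
    use_cnv_dm: bool = True
    # activities the model was trained on, kept so predictions are self-contained
    W: np.ndarray | None = None
    U_weighted: np.ndarray | None = None


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares with intercept via lstsq; returns (coef, intercept)."""
    n = X.shape[0]
    Z = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return beta[1:], float(beta[0])


def lasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float | str = "cv",
    cv_folds: int = 10,
    seed: int = 0,
) -> LassoFit:
    """L1-penalised least squares under the module's fitting contract.

    ``lam`` is the penalty weight in the objective
    (1/2n) * ||y - Xb||^2 + lam * ||b||_1 evaluated on unit-variance
    predictors, or ``"cv"`` to select it by seeded k-fold cross-validation.
    ``lam=0`` is the exact OLS limit.  Zero-variance predictor columns are
    dropped to coefficient 0; ``p=0`` yields an intercept-only fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be n x p with len(y) == n")
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 observations")

    coef = np.zeros(p)
    y_mean = float(y.mean())
    if p == 0:
        fitted = np.full(n, y_mean)
        return LassoFit(coef, y_mean, 0.0, float(((y - fitted) ** 2).sum()), fitted)

    mu = X.mean(axis=0)
    sigma = X.std(axis=0)
    keep = sigma > 0
    if not keep.all():
        logger.debug("lasso_fit: dropping %d zero-variance columns", int((~keep).sum()))
    Xs = (X[:, keep] - mu[keep]) / sigma[keep]
    yc = y - y_mean

    if Xs.shape[1] == 0 or not np.any(yc):
        fitted = np.full(n, y_mean)
        lam_out = 0.0 if isinstance(lam, str) else float(lam)
        return LassoFit(coef, y_mean, lam_out, float(((y - fitted) ** 2).sum()), fitted)

    if isinstance(lam, str):
        if lam != "cv":
            raise ValueError("lam must be a number or 'cv'")
        lam_max = float(np.abs(Xs.T @ yc).max() / n)
        if lam_max <= 0:
            lam_sel, coef_std = 0.0, np.zeros(Xs.shape[1])
        else:
            alphas = np.logspace(
                np.log10(lam_max), np.log10(lam_max * LAMBDA_MIN_RATIO), N_LAMBDA
            )
            folds = KFold(n_splits=cv_folds, shuffle=True, random_state=int(seed) % (2**31))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model = LassoCV(alphas=alphas, cv=folds, fit_intercept=False, max_iter=5000)
                model.fit(Xs, yc)
            lam_sel = float(model.alpha_)
            coef_std = model.coef_
    else:
        lam_sel = float(lam)
        if lam_sel < 0:
            raise ValueError("lam must be >= 0")
        if lam_sel == 0:
            coef_std, _ = _ols(Xs, yc)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model = Lasso(alpha=lam_sel, fit_intercept=False, max_iter=5000)
                model.fit(Xs, yc)
            coef_std = model.coef_

    coef[keep] = coef_std / sigma[keep]
    intercept = y_mean - float(coef[keep] @ mu[keep])
    fitted = X @ coef + intercept
    rss = float(((y - fitted) ** 2).sum())
    return LassoFit(coef, intercept, lam_sel, rss, fitted)


def stage1_design(bundle: OmicsBundle, sample_idx: int) -> np.ndarray:
    """G x (2 + T + M) predictor matrix for one sample's gene-wise regression.

    Columns: CNV, methylation, the T binding-score profiles (B rows), and
    the M seed-count profiles scaled by the sample's miRNA expression.
    """
    s = sample_idx
    mir_block = (bundle.S * bundle.X[:, s][:, None]).T  # G x M
    return np.column_stack([bundle.C[:, s], bundle.D[:, s], bundle.B.T, mir_block])


def fit_stage1(
    bundle: OmicsBundle,
    lam: float | str = "cv",
    seed: int = 0,
    cv_folds: int = 10,
) -> Stage1Fit:
    """Fit the per-sample activity model independently for every sample."""
    G, M, T, N = bundle.n_genes, bundle.n_mirnas, bundle.n_tfs, bundle.n_samples
    if G <= 2 + T + M:
        logger.warning(
            "stage 1 is under-determined: G=%d <= 2+T+M=%d (sparse fit still defined)",
            G,
            2 + T + M,
        )
    fit = Stage1Fit(
        alpha=np.zeros(N),
        phi=np.zeros(N),
        psi=np.zeros(N),
        W=np.zeros((T, N)),
        U=np.zeros((M, N)),
        rss_per_sample=np.zeros(N),
        lambda_per_sample=np.zeros(N),
    )
    for s in range(N):
        design = stage1_design(bundle, s)
        res = lasso_fit(design, bundle.E[:, s], lam=lam, cv_folds=cv_folds, seed=seed + s)
        fit.alpha[s] = res.intercept
        fit.phi[s] = res.coefficients[0]
        fit.psi[s] = res.coefficients[1]
        fit.W[:, s] = res.coefficients[2 : 2 + T]
        fit.U[:, s] = res.coefficients[2 + T :]
        fit.rss_per_sample[s] = res.rss
        fit.lambda_per_sample[s] = res.lambda_selected
    return fit


def weight_mir_activities(U: np.ndarray) -> np.ndarray:
    """Scale each miRNA activity row by its cross-sample mean.

    u~_ms = u_ms * mean_s(u_ms).  Note the weighting squares the sign: a
    negated row yields the same weighted row.
    """
    return U * U.mean(axis=1, keepdims=True)


def stage2_design(
    bundle: OmicsBundle,
    W: np.ndarray,
    U_weighted: np.ndarray,
    gene_idx: int,
    use_cnv_dm: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Design matrix and candidate index arrays for one gene's regression.

    Returns ``(design, tf_idx, mir_idx)``: candidate TFs are those with
    nonzero binding signal for the gene, candidate miRNAs those with nonzero
    seed-site counts.
    """
    g = gene_idx
    tf_idx = np.flatnonzero(bundle.B[:, g] > 0)
    mir_idx = np.flatnonzero(bundle.S[:, g] > 0)
    blocks = []
    if use_cnv_dm:
        blocks.extend([bundle.C[g, :][:, None], bundle.D[g, :][:, None]])
    if tf_idx.size:
        blocks.append(W[tf_idx, :].T)
    if mir_idx.size:
        blocks.append(U_weighted[mir_idx, :].T)
    if blocks:
        design = np.column_stack(blocks)
    else:
        design = np.empty((bundle.n_samples, 0))
    return design, tf_idx, mir_idx


def fit_stage2(
    bundle: OmicsBundle,
    stage1: Stage1Fit,
    use_cnv_dm: bool = True,
    lam: float | str = "cv",
    seed: int = 0,
    cv_folds: int = 10,
) -> Stage2Fit:
    """Fit the per-gene interaction model independently for every gene.

    Interaction scores stay identically zero wherever the candidate masks
    B[t,g] = 0 or S[m,g] = 0 hold; genes with empty candidate sets get a
    CNV/DM + intercept fit only.
    """
    G, M, T, N = bundle.n_genes, bundle.n_mirnas, bundle.n_tfs, bundle.n_samples
    Uw = weight_mir_activities(stage1.U)
    fit = Stage2Fit(
        gene_intercept=np.zeros(G),
        gene_cnv_coef=np.zeros(G),
        gene_dm_coef=np.zeros(G),
        Theta_TF=np.zeros((G, T)),
        Theta_miR=np.zeros((G, M)),
        rss_per_gene=np.zeros(G),
        lambda_per_gene=np.zeros(G),
        use_cnv_dm=use_cnv_dm,
        W=stage1.W.copy(),
        U_weighted=Uw,
    )
    warned = False
    for g in range(G):
        design, tf_idx, mir_idx = stage2_design(bundle, stage1.W, Uw, g, use_cnv_dm)
        if not warned and design.shape[1] >= N:
            logger.warning(
                "stage 2: candidate count %d >= N=%d for gene %s (sparse fit still defined)",
                design.shape[1],
                N,
                bundle.genes[g],
            )
            warned = True
        res = lasso_fit(design, bundle.E[g, :], lam=lam, cv_folds=cv_folds, seed=seed + g)
        fit.gene_intercept[g] = res.intercept
        offset = 0
        if use_cnv_dm:
            fit.gene_cnv_coef[g] = res.coefficients[0]
            fit.gene_dm_coef[g] = res.coefficients[1]
            offset = 2
        fit.Theta_TF[g, tf_idx] = res.coefficients[offset : offset + tf_idx.size]
        fit.Theta_miR[g, mir_idx] = res.coefficients[offset + tf_idx.size :]
        fit.rss_per_gene[g] = res.rss
        fit.lambda_per_gene[g] = res.lambda_selected
    return fit


def predict_expression(bundle: OmicsBundle, fit: Stage1Fit | Stage2Fit) -> np.ndarray:
    """G x N expression prediction from either stage's linear model."""
    G, N = bundle.n_genes, bundle.n_samples
    if isinstance(fit, Stage1Fit):
        if fit.W.shape != (bundle.n_tfs, N) or fit.U.shape != (bundle.n_mirnas, N):
            raise ValueError("stage-1 fit dimensions do not match bundle")
        pred = (
            fit.alpha[None, :]
            + bundle.C * fit.phi[None, :]
            + bundle.D * fit.psi[None, :]
            + bundle.B.T @ fit.W
            + np.einsum("mg,ms,ms->gs", bundle.S, bundle.X, fit.U)
        )
        return pred
    if isinstance(fit, Stage2Fit):
        if fit.Theta_TF.shape != (G, bundle.n_tfs) or fit.Theta_miR.shape != (
            G,
            bundle.n_mirnas,
        ):
            raise ValueError("stage-2 fit dimensions do not match bundle")
        if fit.W is None or fit.U_weighted is None:
            raise ValueError("stage-2 fit lacks the activities it was trained on")
        pred = (
            fit.gene_intercept[:, None]
            + fit.Theta_TF @ fit.W
            + fit.Theta_miR @ fit.U_weighted
        )
        if fit.use_cnv_dm:
            pred = pred + bundle.C * fit.gene_cnv_coef[:, None]
            pred = pred + bundle.D * fit.gene_dm_coef[:, None]
        return pred
    raise TypeError("fit must be a Stage1Fit or Stage2Fit")
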