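"""Cross-validated comparison of the full model against reduced variants.

Reproduces the full-vs-reduced design: 10-fold CV over genes within each
sample (stage 1) or over samples within each gene (stage 2), scoring
held-out predictions by Spearman rank correlation and out-of-sample R^2,
with paired Wilcoxon signed-rank tests between variants.  Variants exclude
one of {CNV, DM, TF, miRNA}, swap the ChIP binding matrix for motif counts,
drop the miRNA-expression weighting of seed counts, or shuffle gene labels
as a negative control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .core_io import OmicsBundle
from .regression import fit_stage1, lasso_fit, stage1_design, stage2_design, weight_mir_activities

__all__ = [
    "ModelVariant",
    "CVMetrics",
    "FULL",
    "standard_variants",
    "apply_variant",
    "cv_stage1",
    "cv_stage2",
    "compare_paired_metrics",
    "comparison_table",
]

_FACTORS = {"CNV", "DM", "TF", "miRNA"}


@dataclass(frozen=True)
class ModelVariant:
    """One row of the model-comparison design."""

    name: str
    exclude: frozenset = frozenset()
    tf_source: str = "binding_scores"  # or "motif_counts"
    mir_weighting: str = "expression_weighted"  # or "counts_only"
    shuffle_labels: bool = False

    def __post_init__(self) -> None:
        if not set(self.exclude) <= _FACTORS:
            raise ValueError(f"exclude must be a subset of {_FACTORS}")
        if self.shuffle_labels and self.exclude:
            raise ValueError("the shuffled baseline uses the full predictor set")
        if self.tf_source not in {"binding_scores", "motif_counts"}:
            raise ValueError("unknown tf_source")
        if self.mir_weighting not in {"expression_weighted", "counts_only"}:
            raise ValueError("unknown mir_weighting")


FULL = ModelVariant("full")


def standard_variants(include_shuffle: bool = True) -> list[ModelVariant]:
    """The full model, the four leave-one-factor-out models, and the shuffle."""
    out = [FULL]
    for factor in ["CNV", "miRNA", "DM", "TF"]:
        out.append(ModelVariant(f"excluding_{factor}", exclude=frozenset({factor})))
    if include_shuffle:
        out.append(ModelVariant("shuffled", shuffle_labels=True))
    return out


@dataclass
class CVMetrics:
    """Per-unit CV metrics, averaged over folds (unit = sample or gene)."""

    unit: str
    spearman: np.ndarray
    r2: np.ndarray
    undefined: np.ndarray = field(default=None)  # True where Spearman was undefined

    def median_spearman(self) -> float:
        return float(np.median(self.spearman))

    def median_r2(self) -> float:
        return float(np.median(self.r2))


def apply_variant(
    bundle: OmicsBundle,
    variant: ModelVariant,
    seed: int = 0,
    motif_counts: pd.DataFrame | None = None,
) -> OmicsBundle:
    """Return a bundle realising the variant's predictor set.

    Excluded factors are zeroed out (a zero predictor column is dropped to
    coefficient 0 by the fitting contract, which is equivalent to removing
    it).  ``counts_only`` sets the miRNA expression to 1 so the stage-1
    miRNA predictor reduces to the seed counts alone.  ``shuffle_labels``
    permutes the gene labels of E with a seeded permutation.
    """
    out = bundle.copy()
    if "CNV" in variant.exclude:
        out.C = np.zeros_like(out.C)
    if "DM" in variant.exclude:
        out.D = np.zeros_like(out.D)
    if "TF" in variant.exclude:
        out.B = np.zeros_like(out.B)
    if "miRNA" in variant.exclude:
        out.S = np.zeros_like(out.S)
    if variant.tf_source == "motif_counts":
        if motif_counts is None:
            raise ValueError("tf_source='motif_counts' requires a motif-count matrix")
        out.B = (
            motif_counts.reindex(columns=out.genes, fill_value=0)
            .to_numpy(dtype=float)
        )
        out.tfs = list(motif_counts.index)
    if variant.mir_weighting == "counts_only":
        out.X = np.ones_like(out.X)
    if variant.shuffle_labels:
        rng = np.random.default_rng(seed)
        out.E = out.E[rng.permutation(out.n_genes), :]
    return out


def _fold_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, bool]:
    """Spearman and out-of-sample R^2 for one held-out fold.

    An undefined Spearman (constant vector) is recorded as 0 with a flag so
    the per-unit vectors stay full length for paired tests.  R^2 is
    1 - SS_res/SS_tot and may be negative; a constant truth gives R^2 0 by
    the same degenerate-input convention.
    """
    undefined = False
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        rho = 0.0
        undefined = True
    else:
        rho = stats.spearmanr(y_true, y_pred).statistic
        if not np.isfinite(rho):
            rho, undefined = 0.0, True
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot == 0:
        r2 = 0.0
    else:
        r2 = 1.0 - float(((y_true - y_pred) ** 2).sum()) / ss_tot
    return float(rho), r2, undefined


def cv_stage1(
    bundle: OmicsBundle,
    variant: ModelVariant = FULL,
    folds: int = 10,
    seed: int = 0,
    lam: float | str = "cv",
    motif_counts: pd.DataFrame | None = None,
) -> CVMetrics:
    """Per-sample 10-fold CV over genes for one model variant.

    For every sample, genes are partitioned into seeded folds; the model is
    trained on the remaining genes (with the penalty re-selected inside
    every training fold) and scored on the held-out genes; the per-sample
    value is the mean over folds.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    vb = apply_variant(bundle, variant, seed=seed, motif_counts=motif_counts)
    N, G = vb.n_samples, vb.n_genes
    if G // folds < 2:
        raise ValueError("each fold needs at least 2 genes")
    spearman = np.zeros(N)
    r2 = np.zeros(N)
    undefined = np.zeros(N, dtype=bool)
    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    fold_pairs = list(splitter.split(np.arange(G)))
    for s in range(N):
        design = stage1_design(vb, s)
        y = vb.E[:, s]
        rhos, r2s, flags = [], [], []
        for f, (train, test) in enumerate(fold_pairs):
            fit = lasso_fit(design[train], y[train], lam=lam, seed=seed + 31 * s + f)
            pred = design[test] @ fit.coefficients + fit.intercept
            rho_f, r2_f, und_f = _fold_metrics(y[test], pred)
            rhos.append(rho_f)
            r2s.append(r2_f)
            flags.append(und_f)
        spearman[s] = np.mean(rhos)
        r2[s] = np.mean(r2s)
        undefined[s] = any(flags)
    return CVMetrics(unit="sample", spearman=spearman, r2=r2, undefined=undefined)


def cv_stage2(
    bundle: OmicsBundle,
    stage1=None,
    variant: ModelVariant = FULL,
    folds: int = 10,
    seed: int = 0,
    lam: float | str = "cv",
    motif_counts: pd.DataFrame | None = None,
) -> CVMetrics:
    """Per-gene 10-fold CV over samples for one model variant.

    Stage-1 activities are fitted on the variant bundle if not supplied.
    Genes whose held-out expression is constant get Spearman 0 with the
    undefined flag set.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    vb = apply_variant(bundle, variant, seed=seed, motif_counts=motif_counts)
    if vb.n_samples < folds:
        raise ValueError("need at least as many samples as folds")
    if stage1 is None:
        stage1 = fit_stage1(vb, lam=lam, seed=seed)
    Uw = weight_mir_activities(stage1.U)
    G, N = vb.n_genes, vb.n_samples
    spearman = np.zeros(G)
    r2 = np.zeros(G)
    undefined = np.zeros(G, dtype=bool)
    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    fold_pairs = list(splitter.split(np.arange(N)))
    for g in range(G):
        design, _, _ = stage2_design(vb, stage1.W, Uw, g)
        y = vb.E[g, :]
        rhos, r2s, flags = [], [], []
        for f, (train, test) in enumerate(fold_pairs):
            fit = lasso_fit(design[train], y[train], lam=lam, seed=seed + 31 * g + f)
            pred = design[test] @ fit.coefficients + fit.intercept
            rho_f, r2_f, und_f = _fold_metrics(y[test], pred)
            rhos.append(rho_f)
            r2s.append(r2_f)
            flags.append(und_f)
        spearman[g] = np.mean(rhos)
        r2[g] = np.mean(r2s)
        undefined[g] = any(flags)
    return CVMetrics(unit="gene", spearman=spearman, r2=r2, undefined=undefined)


def compare_paired_metrics(
    a: np.ndarray, b: np.ndarray, alternative: str = "two-sided"
) -> dict[str, float]:
    """Paired Wilcoxon signed-rank test between two per-unit metric vectors.

    Exact null distribution for n <= 25 nonzero differences, normal
    approximation with continuity correction otherwise.  All-zero
    differences give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("metric vectors must be paired (equal length)")
    diff = a - b
    nonzero = diff[diff != 0]
    if nonzero.size == 0:
        return {"statistic": 0.0, "p_value": 1.0}
    method = "exact" if nonzero.size <= 25 else "approx"
    res = stats.wilcoxon(
        nonzero, alternative=alternative, method=method, correction=(method == "approx")
    )
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue)}


def comparison_table(
    bundle: OmicsBundle,
    variants: list[ModelVariant] | None = None,
    folds: int = 10,
    seed: int = 0,
    lam: float | str = "cv",
    stage: int = 1,
) -> pd.DataFrame:
    """Run CV for every variant and tabulate medians plus p-values vs the full model."""
    if variants is None:
        variants = standard_variants()
    runner = cv_stage1 if stage == 1 else cv_stage2
    metrics = {v.name: runner(bundle, variant=v, folds=folds, seed=seed, lam=lam) for v in variants}
    full_name = variants[0].name
    rows = []
    for v in variants:
        m = metrics[v.name]
        if v.name == full_name:
            p_sp = p_r2 = float("nan")
        else:
            p_sp = compare_paired_metrics(
                metrics[full_name].spearman, m.spearman, alternative="greater"
            )["p_value"]
            p_r2 = compare_paired_metrics(
                metrics[full_name].r2, m.r2, alternative="greater"
            )["p_value"]
        rows.append(
            {
                "variant": v.name,
                "median_spearman": m.median_spearman(),
                "median_r2": m.median_r2(),
                "p_vs_full_spearman": p_sp,
                "p_vs_full_r2": p_r2,
            }
        )
    return pd.DataFrame(rows)
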