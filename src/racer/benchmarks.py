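"""Reproducible simulation studies exercising every stage of the pipeline.

Each routine generates synthetic cohorts at a documented scale, runs the
relevant stage(s), and returns summary statistics: solver agreement with
the closed-form soft-threshold solution on orthonormal designs, stage-1
activity recovery, stage-2 edge recovery against the planted truth and the
two expression-only baselines, cross-validated full-vs-reduced model
ordering, and the null calibration / power of the leave-one-regulator-out
F-test.  Problem sizes are chosen so the full battery runs in minutes on
one core; docs/methods.md discusses the choices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .compare import comparison_table
from .evaluate import expression_lasso_baseline, pcc_baseline, precision_recall
from .regression import fit_stage1, fit_stage2, lasso_fit
from .selection import select_regulators
from .synthetic import SyntheticConfig, generate_bundle

__all__ = [
    "lasso_soft_threshold_agreement",
    "stage1_recovery",
    "mir_edge_recovery",
    "model_comparison_study",
    "ftest_calibration",
]


def _orthonormal_design(rng: np.random.Generator, n: int, p: int) -> np.ndarray:
    """Mean-zero columns with X'X = n I (unit population variance)."""
    raw = rng.standard_normal((n, p))
    raw -= raw.mean(axis=0)
    Q, _ = np.linalg.qr(raw)
    return np.sqrt(n) * Q


def lasso_soft_threshold_agreement(
    seed: int = 0, n_instances: int = 20, n: int = 64, p: int = 8
) -> dict:
    """Worst-case solver deviation from the closed-form orthonormal solution.

    On a design with orthonormal (unit-variance, mutually orthogonal,
    mean-zero) predictors, the penalised solution is the soft-thresholded
    OLS estimate; coordinate descent must reproduce it to numerical
    accuracy.
    """
    worst = 0.0
    for i in range(n_instances):
        rng = np.random.default_rng(seed + i)
        X = _orthonormal_design(rng, n, p)
        beta = 2.0 * rng.standard_normal(p)
        y = X @ beta + rng.standard_normal(n)
        lam = 0.05 + 0.5 * abs(rng.standard_normal())
        fit = lasso_fit(X, y, lam=lam)
        yc = y - y.mean()
        ols = X.T @ yc / n
        oracle = np.sign(ols) * np.maximum(np.abs(ols) - lam, 0.0)
        worst = max(worst, float(np.abs(fit.coefficients - oracle).max()))
    return {"max_abs_error": worst, "n": n_instances}


def stage1_recovery(seed: int = 1, config: SyntheticConfig | None = None) -> dict:
    """Per-sample Pearson correlation between inferred and planted TF activities."""
    if config is None:
        config = SyntheticConfig(seed=seed)
    bundle, truth = generate_bundle(config)
    stage1 = fit_stage1(bundle, lam="cv", seed=seed)
    cors = [
        stats.pearsonr(stage1.W[:, s], truth.W_true[:, s]).statistic
        for s in range(bundle.n_samples)
    ]
    return {
        "median_pearson": float(np.median(cors)),
        "min_pearson": float(np.min(cors)),
        "n": bundle.n_samples,
    }


def mir_edge_recovery(seed: int = 1, config: SyntheticConfig | None = None) -> dict:
    """PR-AUC of stage-2 miRNA scores against planted edges, with baselines.

    Positives are the planted functional seed-match pairs; negatives the
    remaining seed-match candidates.  All three methods are ranked
    most-negative-first (repression semantics).
    """
    if config is None:
        config = SyntheticConfig(seed=seed)
    bundle, truth = generate_bundle(config)
    stage1 = fit_stage1(bundle, lam="cv", seed=seed)
    stage2 = fit_stage2(bundle, stage1, lam="cv", seed=seed)
    gi = {g: i for i, g in enumerate(bundle.genes)}
    mi = {m: i for i, m in enumerate(bundle.mirnas)}
    candidates = {
        (m, bundle.genes[j])
        for i, m in enumerate(bundle.mirnas)
        for j in np.flatnonzero(bundle.S[i] > 0)
    }
    positives = truth.mir_edges() & candidates
    negatives = candidates - positives
    racer_scores = {(m, g): stage2.Theta_miR[gi[g], mi[m]] for m, g in candidates}
    pcc = pcc_baseline(bundle.X, bundle.E)
    pcc_scores = {(m, g): pcc[mi[m], gi[g]] for m, g in candidates}
    lb = expression_lasso_baseline(bundle, seed=seed)
    lasso_scores = {(m, g): lb[mi[m], gi[g]] for m, g in candidates}
    out = {"n": len(candidates), "prevalence": len(positives) / len(candidates)}
    for name, sc in [
        ("racer", racer_scores),
        ("pcc_baseline", pcc_scores),
        ("lasso_baseline", lasso_scores),
    ]:
        out[f"{name}_pr_auc"] = precision_recall(
            sc, positives, negatives, direction="most_negative_first"
        ).auc
    return out


def model_comparison_study(
    seed: int = 4, G: int = 250, N: int = 40, folds: int = 10
) -> pd.DataFrame:
    """Full-vs-reduced-vs-shuffled CV comparison on an all-factors-active cohort."""
    config = SyntheticConfig(G=G, N=N, seed=seed)
    bundle, _ = generate_bundle(config)
    return comparison_table(bundle, folds=folds, seed=seed)


def ftest_calibration(
    seed: int = 0,
    n_null_reps: int = 200,
    n_power_reps: int = 50,
    fdr_threshold: float = 0.1,
) -> dict:
    """Null uniformity, false-selection proportion and power of the F-test.

    Null replicates: G=200, T=5, M=5, N=20 with 4 of 10 regulators active
    and a fully specified model; the p-values of the inactive regulators
    are pooled for a KS uniformity test and the overall false-discovery
    proportion at the FDR threshold is recorded.  Powered replicates plant
    3 drivers among 25 regulators and count how often they occupy the top
    3 F ranks.
    """
    null_ps: list[float] = []
    n_false = n_selected = 0
    for rep in range(n_null_reps):
        config = SyntheticConfig(
            G=200, T=5, M=5, N=20, n_active_regulators=4, effect_fraction=1.0,
            noise_sd=0.1, seed=seed + 10_000 + rep,
        )
        bundle, truth = generate_bundle(config)
        tests = select_regulators(bundle, fdr_threshold=fdr_threshold, seed=seed + rep)
        for t in tests:
            if t.selected:
                n_selected += 1
            if t.regulator_id not in truth.active_set:
                null_ps.append(t.p_value)
                if t.selected:
                    n_false += 1
    ks_p = float(stats.kstest(null_ps, "uniform").pvalue)
    top_hits = 0
    for rep in range(n_power_reps):
        config = SyntheticConfig(
            G=200, T=10, M=15, N=20, n_active_regulators=3, effect_fraction=1.0,
            noise_sd=0.1, seed=seed + 20_000 + rep,
        )
        bundle, truth = generate_bundle(config)
        tests = select_regulators(bundle, fdr_threshold=fdr_threshold, seed=seed + rep)
        if {t.regulator_id for t in tests[:3]} == truth.active_set:
            top_hits += 1
    return {
        "null_ks_pvalue": ks_p,
        "false_selection_proportion": n_false / max(n_selected, 1),
        "driver_top_rank_rate": top_hits / n_power_reps,
        "n_null_pvalues": len(null_ps),
        "n": n_null_reps,
    }
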