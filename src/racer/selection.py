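"""Leave-one-regulator-out F-test feature selection with BH correction.

For each TF/miRNA regulator, the per-sample stage-1 regressions are refitted
with that regulator's predictor column removed; the pooled residual sum of
squares of the reduced model is compared with the full model's through

    F = ((RSS_reduced - RSS_full) / df_num) / (RSS_full / df_den)

with df_num = N (one activity parameter removed per sample) and
df_den = N * (G - T - M - 3) (per-sample residual degrees of freedom,
pooled).  p-values come from the upper tail of F(df_num, df_den) and are
BH-adjusted over the T + M regulators; regulators with FDR below the
threshold are flagged as selected.

By default both models are refitted by ordinary least squares on the full
candidate set (``mode="refit_ols"``), which guarantees exact nesting and a
valid F reference distribution; ``mode="lasso"`` reuses the penalised fits,
in which case a negative numerator (possible because penalised fits are not
exactly nested) is clipped to F = 0, p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import OmicsBundle
from .regression import lasso_fit, stage1_design

__all__ = [
    "RegulatorTest",
    "leave_one_out_rss",
    "f_statistic",
    "bh_adjust",
    "select_regulators",
]


@dataclass
class RegulatorTest:
    """Per-regulator nested-model test result."""

    regulator_id: str
    kind: str  # "TF" or "miRNA"
    rss_full: float
    rss_reduced: float
    f_statistic: float
    p_value: float
    fdr: float
    selected: bool


def _pooled_rss_ols(bundle: OmicsBundle, drop_column: int | None = None) -> float:
    """Pooled across samples RSS of the per-sample OLS on the full design.

    ``drop_column`` is an index into the stage-1 design (0 = CNV, 1 = DM,
    2..2+T-1 = TFs, then miRNAs); None keeps every column.
    """
    total = 0.0
    for s in range(bundle.n_samples):
        design = stage1_design(bundle, s)
        if drop_column is not None:
            design = np.delete(design, drop_column, axis=1)
        Z = np.column_stack([np.ones(design.shape[0]), design])
        beta, res, _, _ = np.linalg.lstsq(Z, bundle.E[:, s], rcond=None)
        if res.size:
            total += float(res[0])
        else:  # rank-deficient: lstsq omits residuals, compute explicitly
            total += float(((bundle.E[:, s] - Z @ beta) ** 2).sum())
    return total


def _pooled_rss_lasso(
    bundle: OmicsBundle, drop_column: int | None, lam, seed: int
) -> float:
    total = 0.0
    for s in range(bundle.n_samples):
        design = stage1_design(bundle, s)
        if drop_column is not None:
            design = np.delete(design, drop_column, axis=1)
        total += lasso_fit(design, bundle.E[:, s], lam=lam, seed=seed + s).rss
    return total


def _regulator_column(bundle: OmicsBundle, regulator_id: str) -> tuple[int, str]:
    if regulator_id in bundle.tfs:
        return 2 + bundle.tfs.index(regulator_id), "TF"
    if regulator_id in bundle.mirnas:
        return 2 + bundle.n_tfs + bundle.mirnas.index(regulator_id), "miRNA"
    raise KeyError(f"unknown regulator {regulator_id!r}")


def leave_one_out_rss(
    bundle: OmicsBundle,
    regulator_id: str,
    seed: int = 0,
    mode: str = "refit_ols",
    lam: float | str = "cv",
) -> float:
    """Pooled stage-1 RSS with the regulator's predictor column removed."""
    col, _ = _regulator_column(bundle, regulator_id)
    if mode == "refit_ols":
        return _pooled_rss_ols(bundle, drop_column=col)
    if mode == "lasso":
        return _pooled_rss_lasso(bundle, drop_column=col, lam=lam, seed=seed)
    raise ValueError("mode must be 'refit_ols' or 'lasso'")


def f_statistic(
    rss_full: float, rss_reduced: float, df_num: int, df_den: int
) -> dict[str, float]:
    """Nested-model F statistic and upper-tail p-value.

    A negative numerator (non-nested penalised fits) is clipped to F = 0,
    p = 1.
    """
    if df_num < 1 or df_den < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if rss_full <= 0:
        raise ValueError("rss_full must be positive")
    f = max(0.0, ((rss_reduced - rss_full) / df_num) / (rss_full / df_den))
    p = float(stats.f.sf(f, df_num, df_den))
    return {"f": float(f), "p": p}


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_regulators(
    bundle: OmicsBundle,
    fdr_threshold: float = 0.1,
    seed: int = 0,
    mode: str = "refit_ols",
    lam: float | str = "cv",
    df_num: int | None = None,
    df_den: int | None = None,
) -> list[RegulatorTest]:
    """Test every TF and miRNA regulator; return tests ranked by F descending.

    Degrees of freedom default to df_num = N and
    df_den = N * (G - T - M - 3) and are overridable.
    """
    if not 0 < fdr_threshold < 1:
        raise ValueError("fdr_threshold must lie in (0, 1)")
    G, M, T, N = bundle.n_genes, bundle.n_mirnas, bundle.n_tfs, bundle.n_samples
    if df_num is None:
        df_num = N
    if df_den is None:
        df_den = N * (G - T - M - 3)
    if df_den <= 0:
        raise ValueError("too few genes: N * (G - T - M - 3) must be positive")

    if mode == "refit_ols":
        rss_full = _pooled_rss_ols(bundle)
    else:
        rss_full = _pooled_rss_lasso(bundle, None, lam, seed)

    regulators = [(t, "TF") for t in bundle.tfs] + [(m, "miRNA") for m in bundle.mirnas]
    results = []
    for reg, kind in regulators:
        rss_red = leave_one_out_rss(bundle, reg, seed=seed, mode=mode, lam=lam)
        ft = f_statistic(rss_full, rss_red, df_num, df_den)
        results.append((reg, kind, rss_red, ft["f"], ft["p"]))

    fdrs = bh_adjust([r[4] for r in results])
    tests = [
        RegulatorTest(
            regulator_id=reg,
            kind=kind,
            rss_full=rss_full,
            rss_reduced=rss_red,
            f_statistic=f,
            p_value=p,
            fdr=float(q),
            selected=bool(q < fdr_threshold),
        )
        for (reg, kind, rss_red, f, p), q in zip(results, fdrs)
    ]
    tests.sort(key=lambda t: (-t.f_statistic, t.regulator_id))
    return tests
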