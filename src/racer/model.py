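"""Model / Results interface over the two-stage regression.

``RacerModel`` is constructed from an aligned :class:`OmicsBundle` (or the
corresponding labelled DataFrames) and ``fit()`` returns a
:class:`RacerResults` carrying the per-sample activities, the per-gene
interaction scores, residual diagnostics, and ``summary()`` tables.
Cross-validated model comparison, regulator feature selection and target
evaluation hang off the results object and delegate to the corresponding
functional modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import compare as _compare
from . import evaluate as _evaluate
from . import selection as _selection
from .core_io import OmicsBundle, align_bundle
from .regression import (
    Stage1Fit,
    Stage2Fit,
    fit_stage1,
    fit_stage2,
    predict_expression,
    weight_mir_activities,
)

__all__ = ["RacerModel", "RacerResults"]


class RacerModel:
    """Two-stage sparse regression of expression on regulatory inputs.

    Parameters
    ----------
    bundle
        Aligned multi-omics matrices.
    lam
        Penalty weight, or ``"cv"`` (default) for seeded cross-validated
        selection per regression.
    use_cnv_dm_stage2
        Whether stage 2 keeps per-gene CNV/methylation covariates.
    seed
        Base seed for every stochastic choice (fold assignment).
    """

    def __init__(
        self,
        bundle: OmicsBundle,
        lam: float | str = "cv",
        use_cnv_dm_stage2: bool = True,
        seed: int = 0,
    ) -> None:
        bundle.validate()
        self.bundle = bundle
        self.lam = lam
        self.use_cnv_dm_stage2 = use_cnv_dm_stage2
        self.seed = seed

    @classmethod
    def from_dataframes(cls, E, X, C, D, B, S, **kwargs) -> "RacerModel":
        """Build a model from labelled matrices, aligning identifiers first."""
        return cls(align_bundle(E, X, C, D, B, S), **kwargs)

    def fit(self, stages: tuple[int, ...] = (1, 2)) -> "RacerResults":
        """Fit the requested stages and return a results object."""
        stage1 = stage2 = None
        if 1 in stages:
            stage1 = fit_stage1(self.bundle, lam=self.lam, seed=self.seed)
        if 2 in stages:
            if stage1 is None:
                raise ValueError("stage 2 requires stage 1")
            stage2 = fit_stage2(
                self.bundle,
                stage1,
                use_cnv_dm=self.use_cnv_dm_stage2,
                lam=self.lam,
                seed=self.seed,
            )
        return RacerResults(self, stage1, stage2)


class RacerResults:
    """Fitted activities, interaction scores and diagnostics."""

    def __init__(
        self,
        model: RacerModel,
        stage1: Stage1Fit | None,
        stage2: Stage2Fit | None,
    ) -> None:
        self.model = model
        self.bundle = model.bundle
        self.stage1 = stage1
        self.stage2 = stage2

    # -- accessors ---------------------------------------------------------

    @property
    def tf_activities(self) -> pd.DataFrame:
        """T x N inferred TF activities."""
        return pd.DataFrame(
            self.stage1.W, index=self.bundle.tfs, columns=self.bundle.samples
        )

    @property
    def mir_activities(self) -> pd.DataFrame:
        """M x N inferred miRNA activities."""
        return pd.DataFrame(
            self.stage1.U, index=self.bundle.mirnas, columns=self.bundle.samples
        )

    @property
    def mir_activities_weighted(self) -> pd.DataFrame:
        return pd.DataFrame(
            weight_mir_activities(self.stage1.U),
            index=self.bundle.mirnas,
            columns=self.bundle.samples,
        )

    @property
    def tf_scores(self) -> pd.DataFrame:
        """G x T interaction scores (zero off the candidate support)."""
        return pd.DataFrame(
            self.stage2.Theta_TF, index=self.bundle.genes, columns=self.bundle.tfs
        )

    @property
    def mir_scores(self) -> pd.DataFrame:
        """G x M interaction scores (zero off the candidate support)."""
        return pd.DataFrame(
            self.stage2.Theta_miR, index=self.bundle.genes, columns=self.bundle.mirnas
        )

    def predict(self, stage: int = 1) -> np.ndarray:
        """G x N fitted expression from the requested stage's linear model."""
        fit = self.stage1 if stage == 1 else self.stage2
        if fit is None:
            raise ValueError(f"stage {stage} was not fitted")
        return predict_expression(self.bundle, fit)

    def resid(self, stage: int = 1) -> np.ndarray:
        return self.bundle.E - self.predict(stage=stage)

    def rss(self, stage: int = 1) -> float:
        if stage == 1:
            return float(self.stage1.rss_per_sample.sum())
        return float(self.stage2.rss_per_gene.sum())

    # -- downstream analyses ----------------------------------------------

    def select_regulators(self, fdr_threshold: float = 0.1, **kwargs):
        """Leave-one-regulator-out F-test selection (see :mod:`racer.selection`)."""
        return _selection.select_regulators(
            self.bundle, fdr_threshold=fdr_threshold, seed=self.model.seed, **kwargs
        )

    def compare_variants(self, variants=None, folds: int = 10, stage: int = 1):
        """Cross-validated full-vs-reduced comparison table."""
        return _compare.comparison_table(
            self.bundle,
            variants=variants,
            folds=folds,
            seed=self.model.seed,
            lam=self.model.lam,
            stage=stage,
        )

    def rank_mir_targets(self) -> _evaluate.RankedInteractions:
        """miRNA-gene pairs ranked most-negative-first over the seed support."""
        return _evaluate.rank_interactions(
            self.stage2.Theta_miR.T,
            self.bundle.S > 0,
            self.bundle.mirnas,
            self.bundle.genes,
            kind="miRNA",
        )

    def rank_tf_targets(self) -> _evaluate.RankedInteractions:
        """TF-gene pairs ranked by absolute score over the binding support."""
        return _evaluate.rank_interactions(
            self.stage2.Theta_TF.T,
            self.bundle.B > 0,
            self.bundle.tfs,
            self.bundle.genes,
            kind="TF",
        )

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary of dimensions, sparsity and fit quality."""
        b = self.bundle
        lines = [
            "Two-stage regulatory activity regression",
            "=" * 46,
            f"genes (G): {b.n_genes}   miRNAs (M): {b.n_mirnas}   "
            f"TFs (T): {b.n_tfs}   samples (N): {b.n_samples}",
            f"penalty: {self.model.lam!r}   seed: {self.model.seed}",
        ]
        if self.stage1 is not None:
            resid1 = self.bundle.E - predict_expression(b, self.stage1)
            sst = float(((b.E - b.E.mean()) ** 2).sum())
            r2 = 1 - float((resid1**2).sum()) / sst if sst else float("nan")
            nz_w = int((self.stage1.W != 0).sum())
            nz_u = int((self.stage1.U != 0).sum())
            lines += [
                "-" * 46,
                "Stage 1 (per-sample activities)",
                f"  pooled RSS: {self.rss(1):.4g}   in-sample R2: {r2:.4f}",
                f"  nonzero activities: W {nz_w}/{self.stage1.W.size}, "
                f"U {nz_u}/{self.stage1.U.size}",
                f"  median lambda: {np.median(self.stage1.lambda_per_sample):.4g}",
            ]
        if self.stage2 is not None:
            nz_t = int((self.stage2.Theta_TF != 0).sum())
            nz_m = int((self.stage2.Theta_miR != 0).sum())
            lines += [
                "-" * 46,
                "Stage 2 (per-gene interaction scores)",
                f"  pooled RSS: {self.rss(2):.4g}",
                f"  nonzero scores: TF-gene {nz_t}, miRNA-gene {nz_m}",
                f"  median lambda: {np.median(self.stage2.lambda_per_gene):.4g}",
            ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        fitted = [s for s, f in [(1, self.stage1), (2, self.stage2)] if f is not None]
        return f"<RacerResults stages={fitted} G={self.bundle.n_genes} N={self.bundle.n_samples}>"
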