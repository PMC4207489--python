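"""Power analysis of regulator-target predictions.

Ranks interaction scores, counts validated interactions among top-k
predictions (k = 1000..5000 in steps of 200 by default), computes
precision-recall curves with trapezoidal AUC, and provides the three
comparison baselines: Pearson correlation between miRNA and mRNA
expression, a per-gene expression-only sparse regression, and raw ChIP
peak scores for TF-gene pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import OmicsBundle
from .regression import lasso_fit

logger = logging.getLogger(__name__)

__all__ = [
    "RankedInteractions",
    "PRCurve",
    "rank_interactions",
    "validated_overlap_curve",
    "precision_recall",
    "pcc_baseline",
    "expression_lasso_baseline",
    "peak_score_baseline",
    "build_positive_set",
]


@dataclass
class RankedInteractions:
    """Strictly ordered (regulator, gene, score) triples.

    ``direction`` records the ranking key: ``most_negative_first``
    (repression semantics, used for miRNAs) or ``largest_magnitude_first``
    (used for TFs, where activation and repression both count).  Ties break
    lexicographically by (regulator, gene).
    """

    pairs: list[tuple[str, str, float]]
    direction: str

    def top(self, k: int) -> list[tuple[str, str]]:
        return [(r, g) for r, g, _ in self.pairs[:k]]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class PRCurve:
    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auc: float


def rank_interactions(
    Theta: np.ndarray,
    mask: np.ndarray,
    regulators: list[str],
    genes: list[str],
    kind: str = "miRNA",
) -> RankedInteractions:
    """Rank candidate regulator-gene pairs by their interaction scores.

    ``Theta`` and ``mask`` are (n_regulators, n_genes); pass transposed
    stage-2 score matrices.  Only candidate pairs (mask true) with nonzero
    score enter the list.  miRNA scores are ranked most-negative-first; TF
    scores by absolute magnitude descending.
    """
    if Theta.shape != mask.shape:
        raise ValueError("Theta and mask shapes differ")
    if Theta.shape != (len(regulators), len(genes)):
        raise ValueError("Theta must be (n_regulators, n_genes)")
    if kind not in {"miRNA", "TF"}:
        raise ValueError("kind must be 'miRNA' or 'TF'")
    direction = "most_negative_first" if kind == "miRNA" else "largest_magnitude_first"
    rows, cols = np.nonzero(np.asarray(mask, dtype=bool) & (Theta != 0))
    if direction == "most_negative_first":
        key = lambda t: (t[0], regulators[t[1]], genes[t[2]])
    else:
        key = lambda t: (-abs(t[0]), regulators[t[1]], genes[t[2]])
    ordered = sorted(((float(Theta[i, j]), i, j) for i, j in zip(rows, cols)), key=key)
    pairs = [(regulators[i], genes[j], v) for v, i, j in ordered]
    return RankedInteractions(pairs=pairs, direction=direction)


def validated_overlap_curve(
    ranked: RankedInteractions,
    validated: set[tuple[str, str]],
    ks=None,
) -> np.ndarray:
    """Counts of validated interactions among the top-k predictions.

    ``ks`` defaults to 1000..5000 in steps of 200 and must be ascending; ks
    beyond the list length are truncated to it (with a warning).
    """
    if ks is None:
        ks = range(1000, 5001, 200)
    ks = list(ks)
    if ks != sorted(ks):
        raise ValueError("ks must be sorted ascending")
    n = len(ranked)
    if ks and ks[-1] > n:
        logger.warning("validated_overlap_curve: max k %d exceeds list length %d", ks[-1], n)
    counts = []
    hits = 0
    idx = 0
    pair_iter = [(r, g) for r, g, _ in ranked.pairs]
    for k in ks:
        k_eff = min(k, n)
        while idx < k_eff:
            if pair_iter[idx] in validated:
                hits += 1
            idx += 1
        counts.append(hits)
    return np.asarray(counts, dtype=int)


def precision_recall(
    scores: dict[tuple[str, str], float],
    positives: set,
    negatives: set,
    direction: str = "most_negative_first",
) -> PRCurve:
    """PR curve over all score thresholds with trapezoidal AUC over recall.

    Items absent from ``scores`` get score 0 (unranked by the method).
    Tied scores are grouped so no threshold splits equal scores; the curve
    is anchored at (recall 0, first precision) before integration.
    """
    positives = set(positives)
    negatives = set(negatives)
    if not positives:
        raise ValueError("positives must be nonempty")
    if not negatives:
        raise ValueError("negatives must be nonempty")
    if positives & negatives:
        raise ValueError("positives and negatives must be disjoint")
    items = sorted(positives | negatives)
    raw = np.array([scores.get(it, 0.0) for it in items], dtype=float)
    if direction == "most_negative_first":
        goodness = -raw
    elif direction == "largest_magnitude_first":
        goodness = np.abs(raw)
    elif direction == "largest_first":
        goodness = raw
    else:
        raise ValueError("unknown direction")
    labels = np.array([it in positives for it in items])
    order = np.argsort(-goodness, kind="stable")
    g_sorted = goodness[order]
    l_sorted = labels[order]
    P = labels.sum()
    tp = np.cumsum(l_sorted)
    fp = np.cumsum(~l_sorted)
    # thresholds sit between distinct goodness values
    distinct = np.flatnonzero(np.diff(g_sorted) != 0)
    cut = np.append(distinct, len(g_sorted) - 1)
    precision = tp[cut] / (tp[cut] + fp[cut])
    recall = tp[cut] / P
    thresholds = g_sorted[cut]
    r_curve = np.concatenate([[0.0], recall])
    p_curve = np.concatenate([[precision[0]], precision])
    auc = float(np.trapezoid(p_curve, r_curve))
    return PRCurve(thresholds=thresholds, precision=precision, recall=recall, auc=auc)


def pcc_baseline(X: np.ndarray, E: np.ndarray) -> np.ndarray:
    """M x G Pearson correlation of each miRNA row with each gene row.

    Constant rows (zero variance) get correlation 0.
    """
    M, N = X.shape
    G = E.shape[0]
    if E.shape[1] != N:
        raise ValueError("X and E must share the sample axis")
    if N < 3:
        raise ValueError("need at least 3 samples for correlations")
    Xc = X - X.mean(axis=1, keepdims=True)
    Ec = E - E.mean(axis=1, keepdims=True)
    xs = np.sqrt((Xc**2).sum(axis=1))
    es = np.sqrt((Ec**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ Ec.T) / np.outer(xs, es)
    bad = ~np.isfinite(r)
    if bad.any():
        logger.info("pcc_baseline: %d correlations undefined (constant rows), set to 0", int(bad.sum()))
        r[bad] = 0.0
    return np.clip(r, -1.0, 1.0)


def expression_lasso_baseline(
    bundle: OmicsBundle, seed: int = 0, lam: float | str = "cv"
) -> np.ndarray:
    """M x G scores from per-gene sparse regression on seed-matched miRNA expression.

    For each gene, its expression is regressed on the expression of the
    miRNAs with nonzero seed-site counts for it; the fitted coefficients
    are scattered into the score matrix (genes with no seed-matched miRNA
    get a zero column).
    """
    M, G = bundle.n_mirnas, bundle.n_genes
    scores = np.zeros((M, G))
    for g in range(G):
        mir_idx = np.flatnonzero(bundle.S[:, g] > 0)
        if mir_idx.size == 0:
            continue
        design = bundle.X[mir_idx, :].T
        fit = lasso_fit(design, bundle.E[g, :], lam=lam, seed=seed + g)
        scores[mir_idx, g] = fit.coefficients
    return scores


def peak_score_baseline(
    B: np.ndarray, tfs: list[str], genes: list[str]
) -> RankedInteractions:
    """TF-gene pairs ranked by raw binding score, largest first."""
    if (B < 0).any():
        raise ValueError("binding scores must be nonnegative")
    rows, cols = np.nonzero(B > 0)
    ordered = sorted(
        ((B[i, j], i, j) for i, j in zip(rows, cols)),
        key=lambda t: (-t[0], tfs[t[1]], genes[t[2]]),
    )
    pairs = [(tfs[i], genes[j], float(v)) for v, i, j in ordered]
    return RankedInteractions(pairs=pairs, direction="largest_magnitude_first")


def build_positive_set(list_a, list_b) -> set:
    """Intersection of two gene lists (deduplicated)."""
    out = set(list_a) & set(list_b)
    if not out:
        logger.warning("build_positive_set: intersection is empty")
    return out
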