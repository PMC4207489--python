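"""Phenotype-level characterisation of selected regulators.

Clusters samples by regulator activity (1 - Pearson distance, average
linkage, dendrogram cut into k groups), compares partitions to cytogenetic
risk groups with the Rand index, tests mean-split survival differences by
log-rank, scores target-set enrichment by hypergeometric tests, and assigns
regulators to the top/middle/bottom layers of the regulator-regulator
network.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from sklearn.metrics import adjusted_rand_score

from .core_io import ClinicalTable
from .selection import bh_adjust

__all__ = [
    "ClusterAssignment",
    "SurvivalSplitTest",
    "hierarchical_cluster",
    "rand_index",
    "logrank_split_test",
    "hypergeometric_enrichment",
    "assign_network_layers",
]


@dataclass
class ClusterAssignment:
    """Sample -> cluster label (1..k) plus the dendrogram merge heights."""

    labels: dict[str, int]
    merge_heights: np.ndarray

    def label_vector(self, samples: list[str]) -> np.ndarray:
        return np.array([self.labels[s] for s in samples])


@dataclass
class SurvivalSplitTest:
    """Mean-split two-group log-rank test for one feature."""

    feature_id: str
    logrank_statistic: float
    p_value: float
    n_high: int
    n_low: int
    degenerate: bool = False
    fdr: float = float("nan")


def _correlation_distance(features: np.ndarray) -> np.ndarray:
    """N x N matrix of 1 - Pearson(sample_i, sample_j) over the feature axis.

    A constant sample column has undefined correlation; its distance to
    every other sample is set to the maximum (2.0).
    """
    X = features.T  # samples x features
    sd = X.std(axis=1)
    constant = sd == 0
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.sqrt((Xc**2).sum(axis=1))
    norm[norm == 0] = 1.0
    corr = (Xc @ Xc.T) / np.outer(norm, norm)
    dist = 1.0 - np.clip(corr, -1.0, 1.0)
    if constant.any():
        dist[constant, :] = 2.0
        dist[:, constant] = 2.0
    np.fill_diagonal(dist, 0.0)
    return dist


def hierarchical_cluster(
    features: np.ndarray, samples: list[str], k: int = 4
) -> ClusterAssignment:
    """Average-linkage clustering of samples on 1 - Pearson distance, cut at k."""
    features = np.asarray(features, dtype=float)
    N = features.shape[1]
    if len(samples) != N:
        raise ValueError("sample list does not match feature matrix columns")
    if k > N:
        raise ValueError("k must not exceed the number of samples")
    dist = _correlation_distance(features)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterAssignment(
        labels={s: int(l) for s, l in zip(samples, labels)},
        merge_heights=Z[:, 2].copy(),
    )


def rand_index(labels_a, labels_b) -> float:
    """Fraction of item pairs on which two partitions agree (unadjusted)."""
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError("partitions must label the same items")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 items")
    agree = 0
    for i, j in combinations(range(n), 2):
        same_a = a[i] == a[j]
        same_b = b[i] == b[j]
        agree += same_a == same_b
    return agree / (n * (n - 1) / 2)


def adjusted_rand(labels_a, labels_b) -> float:
    """Chance-corrected Rand index (reported alongside the headline value)."""
    return float(adjusted_rand_score(list(labels_a), list(labels_b)))


def logrank_split_test(
    values: dict[str, float], clinical: ClinicalTable, feature_id: str = ""
) -> SurvivalSplitTest:
    """Two-group log-rank test after splitting samples at the feature mean.

    Samples with values strictly above the arithmetic mean form the "high"
    group.  A split leaving fewer than 2 samples in either group returns a
    flagged degenerate result with statistic 0 and p = 1.
    """
    frame = clinical.frame
    common = [s for s in frame["sample_id"] if s in values]
    if len(common) < 4:
        raise ValueError("need at least 4 samples with feature values")
    sub = frame.set_index("sample_id").loc[common]
    v = np.array([values[s] for s in common])
    high = v > v.mean()
    n_high, n_low = int(high.sum()), int((~high).sum())
    if n_high < 2 or n_low < 2:
        return SurvivalSplitTest(
            feature_id=feature_id,
            logrank_statistic=0.0,
            p_value=1.0,
            n_high=n_high,
            n_low=n_low,
            degenerate=True,
        )
    res = logrank_test(
        sub["time_to_event"].to_numpy()[high],
        sub["time_to_event"].to_numpy()[~high],
        event_observed_A=sub["event"].to_numpy()[high],
        event_observed_B=sub["event"].to_numpy()[~high],
    )
    stat = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(stat):  # identical curves with no events etc.
        stat, p = 0.0, 1.0
    return SurvivalSplitTest(
        feature_id=feature_id,
        logrank_statistic=stat,
        p_value=p,
        n_high=n_high,
        n_low=n_low,
    )


def survival_panel(
    panel: dict[str, dict[str, float]], clinical: ClinicalTable
) -> list[SurvivalSplitTest]:
    """Mean-split log-rank tests for a feature panel, BH-adjusted across it."""
    tests = [logrank_split_test(vals, clinical, feature_id=fid) for fid, vals in panel.items()]
    fdrs = bh_adjust([t.p_value for t in tests])
    for t, q in zip(tests, fdrs):
        t.fdr = float(q)
    return tests


def hypergeometric_enrichment(
    targets: set,
    sets: dict[str, list[str]],
    background: set,
    min_set: int = 5,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a target list in gene sets.

    Gene sets are intersected with the background; sets smaller than
    ``min_set`` after intersection are dropped; BH correction runs across
    the surviving sets.  Requires targets to be a subset of the background.
    """
    background = set(background)
    if not background:
        raise ValueError("background must be nonempty")
    targets = set(targets)
    if not targets <= background:
        raise ValueError("targets must be a subset of the background")
    Nbg = len(background)
    n = len(targets)
    rows = []
    for name, members in sets.items():
        members_bg = set(members) & background
        K = len(members_bg)
        if K < min_set:
            continue
        hits = len(targets & members_bg)
        p = float(hypergeom.sf(hits - 1, Nbg, K, n))
        rows.append({"set": name, "hits": hits, "set_size": K, "p": p})
    frame = pd.DataFrame(rows, columns=["set", "hits", "set_size", "p"])
    if len(frame):
        frame["fdr"] = bh_adjust(frame["p"].to_numpy())
        frame = frame.sort_values(["p", "set"]).reset_index(drop=True)
    else:
        frame["fdr"] = []
    return frame


def assign_network_layers(
    edges: list[tuple[str, str]], regulators: set[str]
) -> dict[str, str]:
    """Assign regulators to a 3-layer hierarchy from regulator-regulator edges.

    top: regulates another regulator, regulated by none (isolated regulators
    also land here); middle: both regulates and is regulated by regulators
    (cycles fall here); bottom: regulated by a regulator but regulating only
    non-regulator targets.
    """
    regulates = {r: False for r in regulators}
    regulated = {r: False for r in regulators}
    for src, dst in edges:
        if src in regulators and dst in regulators and src != dst:
            regulates[src] = True
            regulated[dst] = True
    layers = {}
    for r in regulators:
        if regulates[r] and regulated[r]:
            layers[r] = "middle"
        elif regulated[r]:
            layers[r] = "bottom"
        else:
            layers[r] = "top"
    return layers
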