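"""Synthetic multi-omics bundles with planted regulatory ground truth.

The generator mirrors the additive generative reading of the stage-1 model:
expression is an intercept plus CNV and methylation offsets plus
activity-weighted TF binding and miRNA seed-count-times-expression terms
plus Gaussian noise.  Expression is left on the model scale: its per-gene
means are the model's own mean regulatory load, which keeps cross-sample
mean activities (and hence the mean-activity weighting and the sign of
repressive interaction scores) identifiable.  Planted quantities — the
activity matrices, the active-regulator set, the regulator-gene edge set,
risk-group labels and a survival-linked clinical table — are returned as a
:class:`SyntheticTruth` so every downstream stage can be scored against a
known answer.

Emulated features of the real inputs: sparse nonnegative binding scores
with heavy-tailed (ChIP-like) magnitudes; small nonnegative integer seed
counts with mean near 1 on their support; nonnegative right-skewed
(RPM-like) miRNA expression; methylation betas in [0, 1]; negative-mean
miRNA activities (repression); group-structured activities tied to risk
labels; exponential survival with ~25% independent censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import ClinicalTable, OmicsBundle, write_matrix_tsv

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_bundle",
    "generate_validated_set",
    "write_fixture_dir",
]


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the scale used throughout the test suite: 500 genes, 15
    miRNAs, 10 TFs, 40 samples, 5% regulator-gene edge density, expression
    noise sd 0.1, 15 of the 25 regulators active, 4 risk groups with unit
    activity shift between groups.
    """

    G: int = 500
    M: int = 15
    T: int = 10
    N: int = 40
    edge_density: float = 0.05
    noise_sd: float = 0.1
    n_active_regulators: int | None = None
    effect_fraction: float = 0.5
    risk_groups: int = 4
    activity_group_shift: float = 1.0
    survival_link_feature: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if min(self.G, self.M, self.T, self.N) < 1:
            raise ValueError("G, M, T, N must be positive")
        if not 0 < self.edge_density <= 1:
            raise ValueError("edge_density must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_active_regulators is not None and not (
            0 <= self.n_active_regulators <= self.T + self.M
        ):
            raise ValueError("n_active_regulators must be <= T + M")
        if not 0 < self.effect_fraction <= 1:
            raise ValueError("effect_fraction must lie in (0, 1]")
        if self.risk_groups < 1:
            raise ValueError("risk_groups must be >= 1")


@dataclass
class SyntheticTruth:
    """Planted ground truth paired with a generated bundle."""

    W_true: np.ndarray
    U_true: np.ndarray
    alpha_true: np.ndarray
    phi_true: np.ndarray
    psi_true: np.ndarray
    edges_true: set[tuple[str, str]]
    active_set: set[str]
    risk_labels: dict[str, str]
    clinical: ClinicalTable
    config: SyntheticConfig = field(repr=False, default=None)

    def tf_edges(self) -> set[tuple[str, str]]:
        return {(r, g) for r, g in self.edges_true if r.startswith("TF")}

    def mir_edges(self) -> set[tuple[str, str]]:
        return {(r, g) for r, g in self.edges_true if r.startswith("miR")}


def _ids(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def generate_bundle(config: SyntheticConfig) -> tuple[OmicsBundle, SyntheticTruth]:
    """Draw one bundle plus its planted truth, deterministically from the seed.

    All randomness flows from a single seeded generator with per-matrix
    sub-streams spawned deterministically, so identical configs give
    bitwise-identical output.
    """
    config.validate()
    G, M, T, N = config.G, config.M, config.T, config.N
    root = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ["B", "S", "X", "C", "D", "act", "noise", "clinical"], root.spawn(8)
        )
    }

    genes = _ids("G", G)
    mirnas = _ids("miR", M)
    tfs = _ids("TF", T)
    samples = _ids("S", N)

    # binding scores: sparse support, heavy-tailed nonnegative magnitudes
    rng = streams["B"]
    B_support = rng.random((T, G)) < config.edge_density
    B = np.where(B_support, np.abs(rng.standard_t(df=3, size=(T, G))), 0.0)

    # seed counts: sparse support, small-mean counts (>= 1 on support)
    rng = streams["S"]
    S_support = rng.random((M, G)) < config.edge_density
    S = np.where(S_support, 1 + rng.poisson(0.25, size=(M, G)), 0).astype(float)

    # miRNA expression: nonnegative, right-skewed (RPM-like scale); modest
    # cross-sample spread so activity heterogeneity, not abundance, carries
    # the sample-specific signal
    X = streams["X"].lognormal(mean=0.0, sigma=0.25, size=(M, N))
    # copy number: centred log-scale segment means
    C = streams["C"].standard_normal((G, N))
    # methylation betas in [0, 1]
    D = streams["D"].beta(2.0, 2.0, size=(G, N))

    # risk groups: near-equal random assignment
    rng = streams["act"]
    group_names = [f"group{k + 1}" for k in range(config.risk_groups)]
    assignment = np.repeat(np.arange(config.risk_groups), int(np.ceil(N / config.risk_groups)))[:N]
    assignment = rng.permutation(assignment)
    risk_labels = {samples[s]: group_names[assignment[s]] for s in range(N)}

    # active regulators: seeded subset of the T + M regulator ids
    # (default: all expressed regulators carry activity)
    all_regs = tfs + mirnas
    n_active = config.n_active_regulators
    if n_active is None:
        n_active = T + M
    active_idx = rng.choice(T + M, size=n_active, replace=False)
    active_set = {all_regs[i] for i in sorted(active_idx)}

    # functional edges: every binding event of an active TF drives expression,
    # but only a fraction of seed-match pairs are functional (most predicted
    # miRNA sites are non-functional in vivo)
    tf_functional = B_support.copy()
    mir_functional = S_support & (rng.random((M, G)) < config.effect_fraction)

    # activities: per-regulator baseline + per-(regulator, group) shift + noise;
    # miRNA baselines are negative (repression) so cross-sample means keep sign
    W_true = np.zeros((T, N))
    U_true = np.zeros((M, N))
    tf_base = rng.normal(0.0, 1.0, size=T)
    mir_base = -(1.0 + np.abs(rng.normal(0.5, 0.25, size=M)))
    tf_shift = config.activity_group_shift * rng.standard_normal((T, config.risk_groups))
    mir_shift = 0.75 * config.activity_group_shift * rng.standard_normal((M, config.risk_groups))
    for t in range(T):
        if all_regs[t] in active_set:
            W_true[t, :] = (
                tf_base[t] + tf_shift[t, assignment] + rng.normal(0.0, 0.3, size=N)
            )
    for m in range(M):
        if all_regs[T + m] in active_set:
            U_true[m, :] = (
                mir_base[m] + mir_shift[m, assignment] + rng.normal(0.0, 0.5, size=N)
            )

    alpha_true = rng.normal(0.0, 0.5, size=N)
    phi_true = rng.normal(0.8, 0.2, size=N)   # copy gain raises expression
    psi_true = rng.normal(-0.8, 0.2, size=N)  # promoter methylation lowers it

    B_eff = np.where(tf_functional, B, 0.0)
    S_eff = np.where(mir_functional, S, 0.0)
    E = (
        alpha_true[None, :]
        + C * phi_true[None, :]
        + D * psi_true[None, :]
        + B_eff.T @ W_true
        + np.einsum("mg,ms,ms->gs", S_eff, X, U_true)
        + streams["noise"].normal(0.0, config.noise_sd, size=(G, N))
    )

    edges_true: set[tuple[str, str]] = set()
    for t in range(T):
        if all_regs[t] in active_set:
            for g in np.flatnonzero(tf_functional[t]):
                edges_true.add((tfs[t], genes[g]))
    for m in range(M):
        if all_regs[T + m] in active_set:
            for g in np.flatnonzero(mir_functional[m]):
                edges_true.add((mirnas[m], genes[g]))

    clinical = _simulate_clinical(
        config, samples, risk_labels, W_true, U_true, tfs, mirnas, streams["clinical"]
    )

    bundle = OmicsBundle(
        genes=genes, mirnas=mirnas, tfs=tfs, samples=samples, E=E, X=X, C=C, D=D, B=B, S=S
    )
    bundle.validate()
    truth = SyntheticTruth(
        W_true=W_true,
        U_true=U_true,
        alpha_true=alpha_true,
        phi_true=phi_true,
        psi_true=psi_true,
        edges_true=edges_true,
        active_set=active_set,
        risk_labels=risk_labels,
        clinical=clinical,
        config=config,
    )
    return bundle, truth


def _simulate_clinical(
    config: SyntheticConfig,
    samples: list[str],
    risk_labels: dict[str, str],
    W_true: np.ndarray,
    U_true: np.ndarray,
    tfs: list[str],
    mirnas: list[str],
    rng: np.random.Generator,
) -> ClinicalTable:
    """Exponential survival, hazard increasing in the linked activity.

    Censoring is independent exponential at one third of the baseline
    hazard, giving roughly 25% censored samples.
    """
    N = len(samples)
    base_rate = 1.0 / 365.0
    hazard = np.full(N, base_rate)
    link = config.survival_link_feature
    if link is not None:
        if link in tfs:
            z = W_true[tfs.index(link), :]
        elif link in mirnas:
            z = U_true[mirnas.index(link), :]
        else:
            raise ValueError(f"unknown survival_link_feature {link!r}")
        sd = z.std()
        zs = (z - z.mean()) / sd if sd > 0 else np.zeros(N)
        hazard = base_rate * np.exp(1.0 * zs)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.exponential(1.0 / (base_rate / 3.0), size=N)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    frame = pd.DataFrame(
        {
            "sample_id": samples,
            "risk_group": [risk_labels[s] for s in samples],
            "time_to_event": np.round(observed, 1),
            "event": event,
        }
    )
    return ClinicalTable(frame)


def generate_validated_set(
    truth: SyntheticTruth,
    fraction: float,
    fdr_contamination: float = 0.0,
    seed: int = 0,
    kind: str = "miRNA",
) -> set[tuple[str, str]]:
    """Sample a mock validated-interaction set from the planted edges.

    Takes ``fraction`` of the true edges of the requested regulator kind and
    adds contaminating non-edges so the contaminants make up about
    ``fdr_contamination`` of the returned set.
    """
    if not 0 <= fraction <= 1 or not 0 <= fdr_contamination <= 1:
        raise ValueError("fraction and fdr_contamination must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    edges = sorted(truth.mir_edges() if kind == "miRNA" else truth.tf_edges())
    n_take = int(round(fraction * len(edges)))
    if n_take == 0:
        return set()
    taken_idx = rng.choice(len(edges), size=n_take, replace=False)
    taken = {edges[i] for i in sorted(taken_idx)}
    if fdr_contamination > 0:
        config = truth.config
        regs = (
            _ids("miR", config.M) if kind == "miRNA" else _ids("TF", config.T)
        )
        genes = _ids("G", config.G)
        n_bad = int(round(fdr_contamination * n_take / max(1e-12, 1 - fdr_contamination)))
        all_edges = truth.edges_true
        added = 0
        while added < n_bad:
            pair = (regs[rng.integers(len(regs))], genes[rng.integers(len(genes))])
            if pair not in all_edges and pair not in taken:
                taken.add(pair)
                added += 1
    return taken


# ---------------------------------------------------------------------------
# fixture directory in the dialects the readers consume


def write_fixture_dir(bundle: OmicsBundle, truth: SyntheticTruth, outdir) -> None:
    """Write a complete raw-input fixture directory for the CLI pipeline.

    Emits gene annotation (BED), TF peaks (narrowPeak), CNV segments, probe
    betas, a TargetScan-style site table, raw mRNA expression (inverse of
    the log2 + centring transform so preprocessing reproduces E exactly),
    miRNA expression, the clinical table and the planted edge list.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, samples = bundle.genes, bundle.samples
    gene_len = 1000
    spacing = 10_000
    starts = {g: 1000 + i * spacing for i, g in enumerate(genes)}

    with open(outdir / "genes.bed", "w") as fh:
        for g in genes:
            s = starts[g]
            fh.write(f"chrS\t{s}\t{s + gene_len}\t{g}\t0\t+\n")

    flank = 50
    with open(outdir / "peaks.narrowPeak", "w") as fh:
        for t, tf in enumerate(bundle.tfs):
            for j in np.flatnonzero(bundle.B[t] > 0):
                g = genes[j]
                tss = starts[g]
                fh.write(
                    f"chrS\t{max(0, tss - flank)}\t{tss + flank + 1}\t{tf}\t0\t.\t"
                    f"{float(bundle.B[t, j])!r}\t-1\t-1\t{flank}\n"
                )

    seg_rows = []
    for s_idx, s in enumerate(samples):
        for g_idx, g in enumerate(genes):
            seg_rows.append(
                (s, "chrS", starts[g], starts[g] + gene_len, bundle.C[g_idx, s_idx])
            )
    pd.DataFrame(
        seg_rows, columns=["sample_id", "chrom", "start", "end", "segment_mean"]
    ).to_csv(outdir / "cnv_segments.tsv", sep="\t", index=False)

    probe_rows = []
    for s_idx, s in enumerate(samples):
        for g_idx, g in enumerate(genes):
            probe_rows.append((s, g, bundle.D[g_idx, s_idx]))
    pd.DataFrame(probe_rows, columns=["sample_id", "gene_id", "beta"]).to_csv(
        outdir / "methylation_probes.tsv", sep="\t", index=False
    )

    site_rows = []
    for m_idx, m in enumerate(bundle.mirnas):
        for g_idx in np.flatnonzero(bundle.S[m_idx] > 0):
            site_rows.append(
                (m, f"{genes[g_idx]}.t1", genes[g_idx], 500, int(bundle.S[m_idx, g_idx]))
            )
    pd.DataFrame(
        site_rows, columns=["mirna", "transcript", "gene", "utr3_length", "count"]
    ).to_csv(outdir / "seed_sites.tsv", sep="\t", index=False)

    # raw mRNA expression: invert log2 + per-gene centring with an offset that
    # keeps values positive; centring in preprocessing cancels the offset
    pseudo = 0.05
    offsets = 1.0 - bundle.E.min(axis=1, keepdims=True)
    raw = np.power(2.0, bundle.E + offsets) - pseudo
    write_matrix_tsv(
        pd.DataFrame(raw, index=genes, columns=samples), outdir / "mrna_expression_raw.tsv"
    )
    write_matrix_tsv(
        pd.DataFrame(bundle.X, index=bundle.mirnas, columns=samples),
        outdir / "mirna_expression.tsv",
    )
    truth.clinical.frame.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(truth.edges_true), columns=["regulator", "gene"]).to_csv(
        outdir / "true_edges.tsv", sep="\t", index=False
    )
    pd.DataFrame(sorted(truth.active_set), columns=["regulator"]).to_csv(
        outdir / "active_regulators.tsv", sep="\t", index=False
    )

    # gene sets: each active regulator's planted target genes (>= 3 members),
    # in GMT dialect, usable as enrichment input against the gene background
    with open(outdir / "gene_sets.gmt", "w") as fh:
        by_reg: dict[str, list[str]] = {}
        for reg, gene in sorted(truth.edges_true):
            by_reg.setdefault(reg, []).append(gene)
        for reg, targets in sorted(by_reg.items()):
            if len(targets) >= 3:
                fh.write("\t".join([f"TARGETS_OF_{reg}", "planted targets", *targets]) + "\n")
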