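"""Construction of the regression input matrices from genomic inputs.

Builds, from peaks / segment tables / probe tables / site tables:

* B (T x G): mean ChIP signal of each TF's peaks overlapping each gene's
  promoter, defined as TSS +/- ``flank`` bp (any >=1 bp overlap counts,
  multiple peaks averaged to a single score per TF-gene pair);
* C (G x N): mean copy-number segment value over segments overlapping any
  exon of the gene, per sample;
* D (G x N): mean methylation beta per gene and sample;
* S (M x G): conserved seed-match site counts, taken from the transcript
  with the longest 3'UTR when a gene has several transcripts;
* E: log2(x + pseudo-count) expression, optionally per-gene mean-centred.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core_io import GeneModel, PeakRecord

logger = logging.getLogger(__name__)

__all__ = [
    "IntervalSet",
    "promoter_regions",
    "build_tf_binding_matrix",
    "build_cnv_matrix",
    "build_methylation_matrix",
    "normalize_expression",
    "build_seed_matrix",
]


@dataclass
class IntervalSet:
    """Chromosome-keyed half-open intervals with a payload (e.g. gene id)."""

    by_chrom: dict[str, list[tuple[int, int, object]]] = field(default_factory=dict)

    def add(self, chrom: str, start: int, end: int, payload: object) -> None:
        if not start < end:
            raise ValueError(f"empty interval [{start}, {end})")
        self.by_chrom.setdefault(chrom, []).append((start, end, payload))

    def sort(self) -> None:
        for ivs in self.by_chrom.values():
            ivs.sort(key=lambda iv: (iv[0], iv[1]))

    def trees(self) -> dict[str, IntervalTree]:
        return {
            chrom: IntervalTree.from_tuples(ivs) for chrom, ivs in self.by_chrom.items()
        }


def promoter_regions(genes: list[GeneModel], flank: int = 50) -> IntervalSet:
    """Promoter windows [tss - flank, tss + flank + 1), clipped at 0.

    The half-open window spans 2*flank + 1 bases, i.e. TSS-flank..TSS+flank
    inclusive.  Strand only decides which coordinate is the TSS.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out = IntervalSet()
    for gene in genes:
        start = max(0, gene.tss - flank)
        end = gene.tss + flank + 1
        out.add(gene.chrom, start, end, gene.gene_id)
    out.sort()
    return out


def build_tf_binding_matrix(
    peaks: list[PeakRecord],
    promoters: IntervalSet,
    tfs: list[str] | None = None,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """T x G binding-score matrix: mean signal of a TF's promoter-overlapping peaks.

    Any >=1 bp overlap between a peak and a gene's promoter counts; multiple
    peaks of the same TF over the same promoter are averaged into a single
    binding score.  Pairs with no overlapping peak get 0.
    """
    if tfs is None:
        tfs = sorted({p.tf_name for p in peaks})
    if genes is None:
        genes = sorted({iv[2] for ivs in promoters.by_chrom.values() for iv in ivs})
    trees = promoters.trees()
    tf_index = {t: i for i, t in enumerate(tfs)}
    gene_index = {g: j for j, g in enumerate(genes)}
    total = np.zeros((len(tfs), len(genes)))
    count = np.zeros((len(tfs), len(genes)), dtype=int)
    for peak in peaks:
        i = tf_index.get(peak.tf_name)
        tree = trees.get(peak.chrom)
        if i is None or tree is None:
            continue
        for hit in tree.overlap(peak.start, peak.end):
            j = gene_index.get(hit.data)
            if j is not None:
                total[i, j] += peak.signal_value
                count[i, j] += 1
    with np.errstate(invalid="ignore"):
        B = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    return pd.DataFrame(B, index=tfs, columns=genes)


def build_cnv_matrix(
    segments: pd.DataFrame,
    genes: list[GeneModel],
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """G x N copy-number matrix: mean segment value over exon-overlapping segments.

    ``segments`` needs columns sample_id, chrom, start, end, segment_mean
    (half-open coordinates).  Genes with no overlapping segment in a sample
    get 0, interpreted as neutral copy number on the log segment-mean scale.
    """
    need = {"sample_id", "chrom", "start", "end", "segment_mean"}
    missing = need - set(segments.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    if (segments["start"] >= segments["end"]).any():
        raise ValueError("segment intervals must have start < end")
    if samples is None:
        samples = sorted(segments["sample_id"].unique())
    exons = IntervalSet()
    for gene in genes:
        for start, end in gene.exons:
            exons.add(gene.chrom, start, end, gene.gene_id)
    trees = exons.trees()
    gene_ids = [g.gene_id for g in genes]
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    sample_index = {s: j for j, s in enumerate(samples)}
    total = np.zeros((len(gene_ids), len(samples)))
    count = np.zeros((len(gene_ids), len(samples)), dtype=int)
    for row in segments.itertuples(index=False):
        j = sample_index.get(row.sample_id)
        tree = trees.get(row.chrom)
        if j is None or tree is None:
            continue
        hit_genes = {hit.data for hit in tree.overlap(int(row.start), int(row.end))}
        for g in hit_genes:
            i = gene_index[g]
            total[i, j] += row.segment_mean
            count[i, j] += 1
    C = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    uncovered = int((count.sum(axis=1) == 0).sum())
    if uncovered:
        logger.warning("build_cnv_matrix: %d genes have no overlapping segment; set to 0", uncovered)
    return pd.DataFrame(C, index=gene_ids, columns=samples)


def build_methylation_matrix(probes: pd.DataFrame) -> pd.DataFrame:
    """G x N methylation matrix: mean beta over each gene's probes per sample.

    ``probes`` needs columns sample_id, gene_id, beta with beta in [0, 1].
    """
    need = {"sample_id", "gene_id", "beta"}
    missing = need - set(probes.columns)
    if missing:
        raise ValueError(f"probe table missing columns: {sorted(missing)}")
    if ((probes["beta"] < 0) | (probes["beta"] > 1)).any():
        raise ValueError("beta values must lie in [0, 1]")
    D = probes.pivot_table(index="gene_id", columns="sample_id", values="beta", aggfunc="mean")
    D = D.fillna(0.0)
    D.index.name = None
    D.columns.name = None
    return D.sort_index()


def normalize_expression(
    raw: pd.DataFrame, pseudo: float = 0.05, center: str = "gene"
) -> pd.DataFrame:
    """log2(raw + pseudo), then optional per-gene (per-row) mean-centring.

    ``center='gene'`` subtracts each row's mean across samples so every
    output row sums to zero; ``center='none'`` leaves the log values as is.
    Negative input values are an error (inputs are RPKM/RPM-like).
    """
    if center not in {"gene", "none"}:
        raise ValueError("center must be 'gene' or 'none'")
    values = raw.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("expression values must be nonnegative")
    out = np.log2(values + pseudo)
    if center == "gene":
        out = out - out.mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=raw.index, columns=raw.columns)


def build_seed_matrix(
    site_table: pd.DataFrame,
    mirnas: list[str] | None = None,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """M x G conserved seed-match count matrix from a TargetScan-style table.

    ``site_table`` needs columns mirna, transcript, gene, utr3_length, count.
    For genes with several transcripts, counts come from the transcript with
    the longest 3'UTR; ties go to the lexicographically smallest transcript
    id.  miRNAs/genes absent from the table get zero rows/columns.
    """
    need = {"mirna", "transcript", "gene", "utr3_length", "count"}
    missing = need - set(site_table.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    if (site_table["count"] < 0).any():
        raise ValueError("site counts must be >= 0")
    if not np.allclose(site_table["count"], np.round(site_table["count"])):
        raise ValueError("site counts must be integers")
    # pick, per gene, the transcript with maximal utr3_length (tie -> smallest id)
    tx = (
        site_table[["gene", "transcript", "utr3_length"]]
        .drop_duplicates()
        .sort_values(["gene", "utr3_length", "transcript"], ascending=[True, False, True])
        .drop_duplicates("gene")
    )
    chosen = site_table.merge(tx[["gene", "transcript"]], on=["gene", "transcript"])
    if mirnas is None:
        mirnas = sorted(site_table["mirna"].unique())
    if genes is None:
        genes = sorted(site_table["gene"].unique())
    S = chosen.pivot_table(index="mirna", columns="gene", values="count", aggfunc="sum")
    S = S.reindex(index=mirnas, columns=genes, fill_value=0).fillna(0).astype(int)
    S.index.name = None
    S.columns.name = None
    return S
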