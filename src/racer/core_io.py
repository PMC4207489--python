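"""Domain types, identifier alignment, and readers/writers for standard formats.

The pipeline consumes ENCODE narrowPeak files (TF ChIP-seq peaks), gene
annotation in GTF or BED dialect, TargetScan-style seed-match site tables,
labelled TSV matrices (expression, copy number, methylation), GMT gene sets
and a clinical table.  All genomic coordinates are normalised to 0-based
half-open intervals at parse time and stay that way internally.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "GeneModel",
    "PeakRecord",
    "OmicsBundle",
    "ClinicalTable",
    "read_narrowpeak",
    "read_gene_annotation",
    "read_gmt",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_clinical",
    "align_bundle",
]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GeneModel:
    """A gene with its TSS, exon structure and per-transcript 3'UTR lengths.

    ``tss`` is a 0-based position: the interval start for '+' genes and
    ``end - 1`` for '-' genes.  ``exons`` are half-open ``(start, end)``
    intervals.  ``utr3_lengths`` maps transcript id -> 3'UTR length in bases.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr3_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ParseError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        for start, end in self.exons:
            if not start < end:
                raise ParseError(
                    f"gene {self.gene_id}: exon interval [{start}, {end}) is empty"
                )
        if any(l < 0 for l in self.utr3_lengths.values()):
            raise ParseError(f"gene {self.gene_id}: negative 3'UTR length")


@dataclass
class PeakRecord:
    """One ChIP-seq peak: half-open interval plus the ENCODE score columns."""

    chrom: str
    start: int
    end: int
    tf_name: str
    score_col5: float
    signal_value: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ParseError(f"peak [{self.start}, {self.end}) is empty")
        if self.signal_value < 0:
            raise ParseError("peak signalValue must be >= 0")


@dataclass
class OmicsBundle:
    """Aligned multi-omics matrices sharing gene/miRNA/TF/sample identifiers.

    E : G x N log-scale, per-gene mean-centred mRNA expression (response).
    X : M x N miRNA expression.
    C : G x N copy-number segment means.
    D : G x N methylation beta averages.
    B : T x G nonnegative TF-promoter binding scores.
    S : M x G nonnegative integer conserved seed-match site counts.
    """

    genes: list[str]
    mirnas: list[str]
    tfs: list[str]
    samples: list[str]
    E: np.ndarray
    X: np.ndarray
    C: np.ndarray
    D: np.ndarray
    B: np.ndarray
    S: np.ndarray

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirnas)

    @property
    def n_tfs(self) -> int:
        return len(self.tfs)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def validate(self) -> None:
        G, M, T, N = self.n_genes, self.n_mirnas, self.n_tfs, self.n_samples
        shapes = {
            "E": (self.E, (G, N)),
            "X": (self.X, (M, N)),
            "C": (self.C, (G, N)),
            "D": (self.D, (G, N)),
            "B": (self.B, (T, G)),
            "S": (self.S, (M, G)),
        }
        for name, (mat, want) in shapes.items():
            if mat.shape != want:
                raise ValueError(f"{name} has shape {mat.shape}, expected {want}")
            if np.isnan(mat).any():
                raise ValueError(f"{name} contains missing values after alignment")
        if (self.B < 0).any():
            raise ValueError("B must be elementwise nonnegative")
        if (self.S < 0).any() or not np.allclose(self.S, np.round(self.S)):
            raise ValueError("S must be elementwise nonnegative integer")

    def copy(self) -> "OmicsBundle":
        return OmicsBundle(
            genes=list(self.genes),
            mirnas=list(self.mirnas),
            tfs=list(self.tfs),
            samples=list(self.samples),
            E=self.E.copy(),
            X=self.X.copy(),
            C=self.C.copy(),
            D=self.D.copy(),
            B=self.B.copy(),
            S=self.S.copy(),
        )

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "E": pd.DataFrame(self.E, index=self.genes, columns=self.samples),
            "X": pd.DataFrame(self.X, index=self.mirnas, columns=self.samples),
            "C": pd.DataFrame(self.C, index=self.genes, columns=self.samples),
            "D": pd.DataFrame(self.D, index=self.genes, columns=self.samples),
            "B": pd.DataFrame(self.B, index=self.tfs, columns=self.genes),
            "S": pd.DataFrame(self.S, index=self.mirnas, columns=self.genes),
        }


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation: risk group, follow-up time and event."""

    frame: pd.DataFrame  # columns: sample_id, risk_group, time_to_event, event

    def __post_init__(self) -> None:
        need = {"sample_id", "risk_group", "time_to_event", "event"}
        missing = need - set(self.frame.columns)
        if missing:
            raise ValueError(f"clinical table missing columns: {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            raise ValueError("clinical table sample_ids must be unique")
        if (self.frame["time_to_event"] < 0).any():
            raise ValueError("time_to_event must be >= 0")
        if not set(self.frame["event"].unique()) <= {0, 1}:
            raise ValueError("event must be 0/1")

    def subset(self, samples: list[str]) -> "ClinicalTable":
        sub = self.frame.set_index("sample_id").loc[list(samples)].reset_index()
        return ClinicalTable(sub)


# ---------------------------------------------------------------------------
# readers


def read_narrowpeak(path, score_column: str = "signalValue") -> list[PeakRecord]:
    """Read an ENCODE narrowPeak (BED6+4) file into :class:`PeakRecord` list.

    The binding score used downstream is ``signal_value``; ``score_column``
    chooses whether that field is populated from column 7 (``signalValue``,
    the default — ENCODE's enrichment magnitude) or column 5 (``score``, the
    capped display score).
    """
    if score_column not in {"signalValue", "score"}:
        raise ValueError("score_column must be 'signalValue' or 'score'")
    records: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ParseError(
                    f"{path}:{lineno}: narrowPeak needs >=10 columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                score5 = float(fields[4])
                signal = float(fields[6])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
            chosen = signal if score_column == "signalValue" else score5
            try:
                records.append(
                    PeakRecord(
                        chrom=fields[0],
                        start=start,
                        end=end,
                        tf_name=fields[3],
                        score_col5=score5,
                        signal_value=chosen,
                    )
                )
            except ParseError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return records


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def _parse_gtf_attrs(text: str) -> dict[str, str]:
    return dict(_GTF_ATTR.findall(text))


def read_gene_annotation(path, dialect: str = "gtf") -> list[GeneModel]:
    """Read gene models from GTF (1-based inclusive) or BED (0-based half-open).

    Coordinates are normalised to 0-based half-open.  TSS is the interval
    start for '+' genes and ``end - 1`` for '-' genes.  In GTF dialect,
    ``exon`` features populate the exon list and ``three_prime_UTR``/``UTR``
    features accumulate per-transcript 3'UTR lengths.  In BED dialect each
    line is one gene whose single exon is the whole interval.
    """
    if dialect not in {"gtf", "bed"}:
        raise ValueError("dialect must be 'gtf' or 'bed'")
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if dialect == "bed":
                if len(fields) < 6:
                    raise ParseError(f"{path}:{lineno}: BED needs >=6 columns")
                chrom, start, end, name, _, strand = fields[:6]
                if strand not in {"+", "-"}:
                    raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
                start_i, end_i = int(start), int(end)
                tss = start_i if strand == "+" else end_i - 1
                genes[name] = {
                    "chrom": chrom,
                    "strand": strand,
                    "tss": tss,
                    "exons": [(start_i, end_i)],
                    "utr3": {},
                }
                continue
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: GTF needs 9 columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if strand not in {"+", "-"}:
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            try:
                start_i = int(start) - 1  # GTF is 1-based inclusive
                end_i = int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from exc
            attr = _parse_gtf_attrs(attrs)
            gid = attr.get("gene_id")
            if gid is None:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            rec = genes.setdefault(
                gid, {"chrom": chrom, "strand": strand, "tss": None, "exons": [], "utr3": {}}
            )
            if feature == "gene":
                rec["chrom"] = chrom
                rec["strand"] = strand
                rec["tss"] = start_i if strand == "+" else end_i - 1
            elif feature == "exon":
                rec["exons"].append((start_i, end_i))
            elif feature in {"three_prime_UTR", "three_prime_utr", "UTR3", "UTR"}:
                tid = attr.get("transcript_id", gid)
                rec["utr3"][tid] = rec["utr3"].get(tid, 0) + (end_i - start_i)
    out = []
    for gid, rec in genes.items():
        tss = rec["tss"]
        if tss is None:
            # gene line absent: derive TSS from the exon span
            if not rec["exons"]:
                raise ParseError(f"{path}: gene {gid} has no gene or exon features")
            lo = min(s for s, _ in rec["exons"])
            hi = max(e for _, e in rec["exons"])
            tss = lo if rec["strand"] == "+" else hi - 1
        out.append(
            GeneModel(
                gene_id=gid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                tss=tss,
                exons=sorted(rec["exons"]),
                utr3_lengths=rec["utr3"],
            )
        )
    out.sort(key=lambda g: g.gene_id)
    return out


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name, description, then member genes.

    Duplicate genes within a set are deduplicated (order preserved);
    duplicate set names are an error rather than a silent merge.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >=3 fields")
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            seen: dict[str, None] = {}
            for g in fields[2:]:
                if g:
                    seen.setdefault(g)
            if not seen:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets[name] = list(seen)
    return sets


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a labelled matrix: header row = sample ids, first col = feature ids.

    Leading ``#`` comment lines (provenance headers) are skipped.
    """
    return pd.read_csv(
        path, sep="\t", index_col=0, comment="#", float_precision="round_trip"
    )


def write_matrix_tsv(frame: pd.DataFrame, path) -> None:
    """Write a labelled matrix TSV; full float precision for exact round-trips."""
    frame.to_csv(path, sep="\t", float_format="%.17g")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t")
    rename = {"days_to_death_or_censor": "time_to_event"}
    df = df.rename(columns=rename)
    return ClinicalTable(df)


# ---------------------------------------------------------------------------
# alignment


def align_bundle(
    E_raw: pd.DataFrame,
    X_raw: pd.DataFrame,
    C_raw: pd.DataFrame,
    D_raw: pd.DataFrame,
    B_raw: pd.DataFrame,
    S_raw: pd.DataFrame,
) -> OmicsBundle:
    """Align labelled matrices onto shared, sorted identifier vectors.

    Samples are the intersection of the columns of E, X, C and D.  Genes are
    those present in E, C and D and in at least one of B's or S's columns
    (genes absent from one of B/S keep an all-zero column there).  miRNAs
    need both expression (X rows) and a seed-count row (S rows).  Dropped
    identifiers are logged; an empty intersection is an error.
    """
    samples = sorted(
        set(E_raw.columns) & set(X_raw.columns) & set(C_raw.columns) & set(D_raw.columns)
    )
    if not samples:
        raise ValueError("no samples shared across E, X, C, D")
    regulated = set(B_raw.columns) | set(S_raw.columns)
    genes = sorted(set(E_raw.index) & set(C_raw.index) & set(D_raw.index) & regulated)
    if not genes:
        raise ValueError("no genes shared across E, C, D and B/S columns")
    mirnas = sorted(set(X_raw.index) & set(S_raw.index))
    if not mirnas:
        raise ValueError("no miRNAs shared between X rows and S rows")
    tfs = sorted(set(B_raw.index))

    for name, raw, kept in [
        ("samples", E_raw.columns, samples),
        ("genes", E_raw.index, genes),
        ("miRNAs", X_raw.index, mirnas),
    ]:
        dropped = sorted(set(raw) - set(kept))
        if dropped:
            logger.info("align_bundle: dropped %d %s (e.g. %s)", len(dropped), name, dropped[:5])

    E = E_raw.loc[genes, samples].to_numpy(dtype=float)
    X = X_raw.loc[mirnas, samples].to_numpy(dtype=float)
    C = C_raw.loc[genes, samples].to_numpy(dtype=float)
    D = D_raw.loc[genes, samples].to_numpy(dtype=float)
    B = B_raw.reindex(index=tfs, columns=genes, fill_value=0.0).to_numpy(dtype=float)
    S = S_raw.reindex(index=mirnas, columns=genes, fill_value=0).to_numpy(dtype=float)

    bundle = OmicsBundle(
        genes=genes, mirnas=mirnas, tfs=tfs, samples=samples, E=E, X=X, C=C, D=D, B=B, S=S
    )
    bundle.validate()
    return bundle
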