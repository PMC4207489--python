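import numpy as np
import pandas as pd
import pytest

from racer.core_io import GeneModel, PeakRecord
from racer.preprocess import (
    build_cnv_matrix,
    build_methylation_matrix,
    build_seed_matrix,
    build_tf_binding_matrix,
    normalize_expression,
    promoter_regions,
)


def _gene(gene_id, tss, strand="+", chrom="chr1", exons=None):
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand, tss=tss,
        exons=exons or [(tss, tss + 100)],
    )


class TestPromoterRegions:
    @pytest.mark.parametrize(
        "tss,flank,expected",
        [(1000, 50, (950, 1051)), (20, 50, (0, 71)), (1000, 0, (1000, 1001))],
    )
    def test_window_rule_with_clipping(self, tss, flank, expected):
        ivs = promoter_regions([_gene("g", tss)], flank=flank)
        (start, end, payload) = ivs.by_chrom["chr1"][0]
        assert (start, end) == expected
        assert payload == "g"

    def test_strand_only_moves_tss(self):
        plus = promoter_regions([_gene("g", 500, "+")])
        minus = promoter_regions([_gene("g", 500, "-")])
        assert plus.by_chrom == minus.by_chrom


class TestBindingMatrix:
    def test_multiple_peaks_average(self):
        genes = [_gene("g", 1000)]
        promoters = promoter_regions(genes)
        peaks = [
            PeakRecord("chr1", 900, 960, "TF1", 0, 5.0),
            PeakRecord("chr1", 1000, 1100, "TF1", 0, 7.0),
        ]
        B = build_tf_binding_matrix(peaks, promoters)
        assert B.loc["TF1", "g"] == 6.0

    def test_no_overlap_gives_zero(self):
        promoters = promoter_regions([_gene("g", 1000)])
        peaks = [PeakRecord("chr1", 10, 20, "TF1", 0, 5.0)]
        B = build_tf_binding_matrix(peaks, promoters, tfs=["TF1"], genes=["g"])
        assert B.loc["TF1", "g"] == 0.0

    def test_agrees_with_quadratic_overlap_oracle(self):
        rng = np.random.default_rng(5)
        genes = [_gene(f"g{i}", int(rng.integers(0, 5000))) for i in range(20)]
        promoters = promoter_regions(genes)
        tf_names = ["TF1", "TF2", "TF3"]
        peaks = [
            PeakRecord(
                "chr1",
                int(s := rng.integers(0, 5000)),
                int(s + rng.integers(1, 400)),
                tf_names[rng.integers(3)],
                0,
                float(rng.random() * 10),
            )
            for _ in range(60)
        ]
        B = build_tf_binding_matrix(peaks, promoters, tfs=tf_names)
        for t, tf in enumerate(tf_names):
            for gene in genes:
                lo, hi = max(0, gene.tss - 50), gene.tss + 51
                signals = [
                    p.signal_value
                    for p in peaks
                    if p.tf_name == tf and p.start < hi and p.end > lo
                ]
                expected = float(np.mean(signals)) if signals else 0.0
                assert B.loc[tf, gene.gene_id] == pytest.approx(expected)

    def test_invariant_to_peak_order(self):
        rng = np.random.default_rng(3)
        genes = [_gene(f"g{i}", 200 * i) for i in range(8)]
        promoters = promoter_regions(genes)
        peaks = [
            PeakRecord("chr1", int(rng.integers(0, 1500)), int(rng.integers(1501, 1700)),
                       "TF1", 0, float(rng.random()))
            for _ in range(20)
        ]
        B1 = build_tf_binding_matrix(peaks, promoters, tfs=["TF1"])
        B2 = build_tf_binding_matrix(peaks[::-1], promoters, tfs=["TF1"])
        pd.testing.assert_frame_equal(B1, B2)


class TestCnvMatrix:
    def test_overlapping_segments_average(self):
        genes = [_gene("g", 1000, exons=[(1000, 1200), (1500, 1600)])]
        segments = pd.DataFrame(
            {"sample_id": ["s1", "s1"], "chrom": ["chr1", "chr1"],
             "start": [900, 1550], "end": [1100, 1650], "segment_mean": [0.2, 0.4]}
        )
        C = build_cnv_matrix(segments, genes)
        assert C.loc["g", "s1"] == pytest.approx(0.3)

    def test_gene_without_segment_is_zero(self):
        genes = [_gene("g", 1000), _gene("h", 50_000)]
        segments = pd.DataFrame(
            {"sample_id": ["s1"], "chrom": ["chr1"], "start": [900],
             "end": [1100], "segment_mean": [0.7]}
        )
        C = build_cnv_matrix(segments, genes)
        assert C.loc["h", "s1"] == 0.0

    def test_agrees_with_bruteforce_oracle(self):
        rng = np.random.default_rng(9)
        genes = [
            _gene(f"g{i}", int(rng.integers(0, 3000)),
                  exons=[(s := int(rng.integers(0, 3000)), s + int(rng.integers(50, 300)))])
            for i in range(10)
        ]
        segments = pd.DataFrame(
            {
                "sample_id": rng.choice(["s1", "s2"], 30),
                "chrom": "chr1",
                "start": (starts := rng.integers(0, 3000, 30)),
                "end": starts + rng.integers(50, 500, 30),
                "segment_mean": rng.standard_normal(30),
            }
        )
        C = build_cnv_matrix(segments, genes, samples=["s1", "s2"])
        for gene in genes:
            for sample in ["s1", "s2"]:
                vals = []
                for row in segments.itertuples(index=False):
                    if row.sample_id != sample:
                        continue
                    if any(row.start < e and row.end > s for s, e in gene.exons):
                        vals.append(row.segment_mean)
                expected = float(np.mean(vals)) if vals else 0.0
                assert C.loc[gene.gene_id, sample] == pytest.approx(expected)


class TestMethylationMatrix:
    def test_probe_average(self):
        probes = pd.DataFrame(
            {"sample_id": ["s1", "s1", "s1"], "gene_id": ["g", "g", "h"],
             "beta": [0.1, 0.3, 0.9]}
        )
        D = build_methylation_matrix(probes)
        assert D.loc["g", "s1"] == pytest.approx(0.2)
        assert D.loc["h", "s1"] == pytest.approx(0.9)

    def test_beta_out_of_range_is_error(self):
        probes = pd.DataFrame({"sample_id": ["s1"], "gene_id": ["g"], "beta": [1.2]})
        with pytest.raises(ValueError, match="beta"):
            build_methylation_matrix(probes)


class TestNormalizeExpression:
    def test_identical_values_centre_to_zero(self):
        raw = pd.DataFrame([[1.0, 1.0]], index=["g"], columns=["a", "b"])
        out = normalize_expression(raw)
        assert np.allclose(out.to_numpy(), 0.0)

    def test_center_none_keeps_log_values(self):
        raw = pd.DataFrame([[0.0]], index=["g"], columns=["a"])
        out = normalize_expression(raw, center="none")
        assert out.iloc[0, 0] == pytest.approx(np.log2(0.05))

    def test_row_means_zero_and_monotone(self):
        rng = np.random.default_rng(2)
        raw = pd.DataFrame(rng.random((6, 9)) * 100)
        out = normalize_expression(raw)
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-9)
        row_raw = raw.iloc[0].to_numpy()
        row_out = out.iloc[0].to_numpy()
        assert np.array_equal(np.argsort(row_raw), np.argsort(row_out))

    def test_negative_input_is_error(self):
        with pytest.raises(ValueError):
            normalize_expression(pd.DataFrame([[-1.0]]))


class TestSeedMatrix:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["mirna", "transcript", "gene", "utr3_length", "count"])

    def test_longest_utr_transcript_wins(self):
        table = self._table([("m1", "tA", "g", 100, 2), ("m1", "tB", "g", 200, 1)])
        S = build_seed_matrix(table)
        assert S.loc["m1", "g"] == 1

    def test_utr_tie_breaks_to_smallest_transcript_id(self):
        table = self._table([("m1", "tB", "g", 150, 2), ("m1", "tA", "g", 150, 3)])
        S = build_seed_matrix(table)
        assert S.loc["m1", "g"] == 3

    def test_absent_mirna_gets_zero_row(self):
        table = self._table([("m1", "tA", "g", 100, 2)])
        S = build_seed_matrix(table, mirnas=["m1", "m2"])
        assert S.loc["m2"].sum() == 0

    def test_negative_count_is_error(self):
        with pytest.raises(ValueError):
            build_seed_matrix(self._table([("m1", "tA", "g", 100, -1)]))
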