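import math

import numpy as np
import pandas as pd
import pytest

from scmultidiff.atac_diff import (
    annotate_peaks,
    assign_vicinity,
    categorize_peak,
    count_fragments_in_peaks,
    filter_peaks,
    jaccard,
    run_differential_peaks,
)
from scmultidiff.core_io import FragmentRecord, GenomicInterval
from scmultidiff.simulate import simulate_peak_matrix

from conftest import fisher_oracle


def frag(chrom, start, end, barcode, count=1):
    return FragmentRecord(GenomicInterval(chrom, start, end), barcode, count)


PEAKS = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 100, 200)]


class TestCounting:
    def test_duplicate_count_weighting(self):
        matrix, ignored = count_fragments_in_peaks(
            [frag("chr1", 10, 60, "AAAC", 2)], PEAKS, {"AAAC": "A"}
        )
        assert ignored == 0
        assert matrix.counts[0, 0] == 2
        assert matrix.counts[0, 1] == 0

    def test_fragment_spanning_two_peaks_increments_both(self):
        matrix, _ = count_fragments_in_peaks(
            [frag("chr1", 90, 110, "AAAC")], PEAKS, {"AAAC": "A"}
        )
        assert matrix.counts[0, 0] == 1
        assert matrix.counts[0, 1] == 1

    def test_no_fragments_zero_matrix(self):
        matrix, _ = count_fragments_in_peaks([], PEAKS, {"AAAC": "A"})
        assert matrix.counts.nnz == 0

    def test_unknown_barcodes_ignored_and_counted(self):
        matrix, ignored = count_fragments_in_peaks(
            [frag("chr1", 10, 20, "XXXX"), frag("chr1", 10, 20, "AAAC")],
            PEAKS,
            {"AAAC": "A"},
        )
        assert ignored == 1
        assert matrix.counts.sum() == 1

    def test_grand_total_on_non_adjacent_peaks(self):
        peaks = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 500, 600)]
        rng = np.random.default_rng(5)
        frags = []
        expected = 0
        for i in range(200):
            start = int(rng.integers(0, 700))
            f = frag("chr1", start, start + 30, "AAAC", int(rng.integers(1, 4)))
            frags.append(f)
            if any(f.interval.overlaps(p) for p in peaks):
                expected += f.count
        matrix, _ = count_fragments_in_peaks(frags, peaks, {"AAAC": "A"})
        assert matrix.counts.sum() == expected


class TestFilterPeaks:
    def _matrix(self, cells_detecting):
        rows = [frag("chr1", 10, 20, f"BC{i:03d}") for i in range(cells_detecting)]
        mapping = {f"BC{i:03d}": "A" for i in range(100)}
        matrix, _ = count_fragments_in_peaks(rows, PEAKS, mapping)
        return matrix

    def test_two_percent_rule(self):
        kept = filter_peaks(self._matrix(3))  # 3/100 cells
        assert len(kept.peaks) == 1
        dropped = filter_peaks(self._matrix(1))  # 1/100 cells
        assert len(dropped.peaks) == 0

    def test_zero_threshold_is_identity(self):
        matrix = self._matrix(1)
        assert len(filter_peaks(matrix, min_cell_frac=0).peaks) == len(PEAKS)


class TestDifferentialPeaks:
    def test_identical_groups_flat(self):
        access = {"A": np.array([0.3]), "B": np.array([0.3])}
        matrix = simulate_peak_matrix(access, {"A": 100, "B": 100}, seed=0)
        # force identical detection counts by symmetrizing the draw
        det = matrix.detected().toarray()
        det[100:] = det[:100]
        from scipy import sparse

        matrix.counts = sparse.csr_matrix(det.astype(np.int64))
        res = run_differential_peaks(matrix, "A", "B")
        assert res.p_raw.iloc[0] == pytest.approx(1.0)
        assert res.effect.iloc[0] == pytest.approx(0.0)

    def test_complete_separation_matches_enumeration(self):
        access = {"A": np.array([1.0]), "B": np.array([0.0])}
        matrix = simulate_peak_matrix(access, {"A": 100, "B": 100}, seed=0)
        res = run_differential_peaks(matrix, "A", "B")
        expected = fisher_oracle(100, 0, 0, 100)
        assert expected == pytest.approx(2 / math.comb(200, 100))
        assert res.p_raw.iloc[0] == pytest.approx(expected, rel=1e-9)
        assert (res.frac_a.iloc[0], res.frac_b.iloc[0]) == (1.0, 0.0)

    def test_group_swap_symmetry(self):
        access = {"A": np.full(20, 0.2), "B": np.full(20, 0.6)}
        matrix = simulate_peak_matrix(access, {"A": 60, "B": 60}, seed=3)
        ab = run_differential_peaks(matrix, "A", "B")
        ba = run_differential_peaks(matrix, "B", "A")
        assert np.allclose(ab.p_raw, ba.p_raw)
        assert np.allclose(ab.effect, -ba.effect)

    def test_min_cells_enforced(self):
        access = {"A": np.array([0.5]), "B": np.array([0.5])}
        matrix = simulate_peak_matrix(access, {"A": 10, "B": 100}, seed=0)
        with pytest.raises(ValueError, match="cells"):
            run_differential_peaks(matrix, "A", "B", min_cells=20)

    def test_null_calibration(self):
        access = {"A": np.full(400, 0.3), "B": np.full(400, 0.3)}
        matrix = simulate_peak_matrix(access, {"A": 150, "B": 150}, seed=11)
        res = run_differential_peaks(matrix, "A", "B")
        se = np.sqrt(0.05 * 0.95 / len(res))
        assert res.significant.mean() <= 0.05 + 2 * se

    def test_lr_depth_detects_extreme_difference(self):
        pa = np.full(40, 0.3)
        pb = np.full(40, 0.3)
        pa[0], pb[0] = 0.9, 0.1
        matrix = simulate_peak_matrix({"A": pa, "B": pb}, {"A": 80, "B": 80}, seed=7)
        res = run_differential_peaks(matrix, "A", "B", method="lr_depth")
        assert res.p_raw.iloc[0] < 1e-6
        assert res.p_raw.iloc[1:].median() > 0.05  # null peaks stay flat
        assert ((res.p_raw >= 0) & (res.p_raw <= 1)).all()


class TestVicinity:
    def test_peak_inside_target_gene(self, tiny_annotation):
        genes, _ = tiny_annotation
        gene = min(genes, key=lambda g: g.interval.start)
        peak = GenomicInterval("chrS", gene.interval.start + 10, gene.interval.start + 200)
        ann = assign_vicinity([peak], genes, {gene.gene_id})
        assert ann.nearest_gene[0] == gene.gene_id
        assert ann.distance[0] == 0
        assert bool(ann.in_target[0])

    def test_beyond_max_dist_not_in_target(self, tiny_annotation):
        genes, _ = tiny_annotation
        last = max(genes, key=lambda g: g.interval.end)
        peak = GenomicInterval("chrS", last.interval.end + 60_000, last.interval.end + 60_500)
        ann = assign_vicinity([peak], genes, {g.gene_id for g in genes}, max_dist=50_000)
        assert ann.nearest_gene[0] == last.gene_id
        assert not bool(ann.in_target[0])

    def test_equidistant_tie_broken_by_tss(self, tiny_annotation):
        genes, _ = tiny_annotation
        ordered = sorted(genes, key=lambda g: g.interval.start)
        g1, g2 = ordered[0], ordered[1]
        gap_mid = (g1.interval.end + g2.interval.start) // 2
        peak = GenomicInterval("chrS", gap_mid - 10, gap_mid + 10)
        assert peak.distance(g1.interval) == peak.distance(g2.interval)
        ann = assign_vicinity([peak], genes, set())
        tss_d = {
            g.gene_id: min(abs(g.tss - peak.start), abs(g.tss - peak.end))
            for g in (g1, g2)
        }
        assert ann.nearest_gene[0] == min(tss_d, key=lambda k: (tss_d[k], k))

    def test_unknown_chromosome_gives_none(self, tiny_annotation):
        genes, _ = tiny_annotation
        ann = assign_vicinity([GenomicInterval("chrZ", 0, 100)], genes, {"G00000"})
        assert ann.nearest_gene[0] is None
        assert not bool(ann.in_target[0])


class TestCategorize:
    def test_precedence(self, tiny_annotation):
        genes, alt_exons = tiny_annotation
        gene = min(genes, key=lambda g: g.interval.start)
        first_exon = gene.transcripts[0].exons[0]  # doubles as annotated UTR
        utr_peak = GenomicInterval("chrS", first_exon.start, first_exon.end)
        assert categorize_peak(utr_peak, genes) == "UTR"
        internal = gene.transcripts[0].exons[-1]
        exon_peak = GenomicInterval("chrS", internal.start, internal.end)
        assert categorize_peak(exon_peak, genes) == "exon"
        # midpoint in a gene body gap between exons
        e1, e2 = gene.transcripts[0].exons[-2], gene.transcripts[0].exons[-1]
        intron_peak = GenomicInterval("chrS", e1.end + 2, e1.end + 12)
        assert categorize_peak(intron_peak, genes) == "intron"
        outside = GenomicInterval("chrS", 10, 30)
        assert categorize_peak(outside, genes) == "intergenic"

    def test_annotate_peaks_has_category_and_vicinity(self, tiny_annotation):
        genes, _ = tiny_annotation
        peaks = [GenomicInterval("chrS", 10, 30)]
        ann = annotate_peaks(peaks, genes, set())
        assert list(ann.columns) == ["nearest_gene", "distance", "in_target", "category"]


class TestJaccard:
    def test_identical_sets_unity(self):
        a = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr2", 50, 80)]
        assert jaccard(a, a) == pytest.approx(1.0)

    def test_half_overlap_one_third(self):
        a = [GenomicInterval("chr1", 0, 100)]
        b = [GenomicInterval("chr1", 50, 150)]
        assert jaccard(a, b) == pytest.approx(1 / 3)

    def test_disjoint_zero(self):
        a = [GenomicInterval("chr1", 0, 100)]
        b = [GenomicInterval("chr1", 200, 300)]
        assert jaccard(a, b) == 0.0
        assert jaccard(a, b, mode="count") == 0.0

    def test_symmetry_and_split_invariance(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            a = _random_intervals(rng)
            b = _random_intervals(rng)
            j1 = jaccard(a, b)
            assert j1 == pytest.approx(jaccard(b, a))
            assert j1 == pytest.approx(jaccard(_split(a, rng), b))

    def test_count_mode_symmetric_overlap_fraction(self):
        a = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300)]
        b = [GenomicInterval("chr1", 90, 110)]
        # one of two A peaks touches B; the single B peak touches A
        assert jaccard(a, b, mode="count") == pytest.approx(2 / 3)

    def test_both_empty_undefined(self):
        assert jaccard([], []) is None


def _random_intervals(rng, n_max=15):
    out = []
    for _ in range(int(rng.integers(1, n_max))):
        start = int(rng.integers(0, 5000))
        out.append(GenomicInterval("chr1", start, start + int(rng.integers(1, 400))))
    return out


def _split(intervals, rng):
    """Split intervals into adjacent pieces (bp content unchanged)."""
    out = []
    for iv in intervals:
        if len(iv) > 2 and rng.random() < 0.7:
            cut = int(rng.integers(iv.start + 1, iv.end))
            out.append(GenomicInterval(iv.chrom, iv.start, cut))
            out.append(GenomicInterval(iv.chrom, cut, iv.end))
        else:
            out.append(iv)
    return out
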