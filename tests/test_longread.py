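import itertools

import pytest

from scmultidiff.core_io import GenomicInterval
from scmultidiff.longread import (
    ExonStatus,
    LongReadRecord,
    Molecule,
    assign_gene,
    build_inclusion_table,
    call_exon,
    coinclusion_association,
    dedup_umis,
    edit_distance,
    extract_molecules,
    match_barcode,
    read_bed12,
    write_bed12,
    write_read_sidecar,
)

from conftest import brute_force_umi_clusters, fisher_oracle


def mkread(read_id, umi, blocks, chrom="chrS", barcode="ACGTACGTACGTACGT", strand="+"):
    return LongReadRecord(
        read_id=read_id,
        barcode_candidate=barcode,
        umi_candidate=umi,
        chrom=chrom,
        strand=strand,
        blocks=tuple(GenomicInterval(chrom, s, e, strand) for s, e in blocks),
    )


class TestMatchBarcode:
    def test_exact_match_accepted(self):
        assert match_barcode("ACGT", {"ACGT"}) == "ACGT"

    def test_single_mismatch_rejected_by_default(self):
        # conservative calling: only perfectly matching barcodes count
        assert match_barcode("ACGA", {"ACGT"}) is None

    def test_empty_candidate_rejected(self):
        assert match_barcode("", {"ACGT"}) is None

    def test_optional_rescue_requires_unique_hit(self):
        assert match_barcode("ACGA", {"ACGT"}, max_mismatch=1) == "ACGT"
        assert match_barcode("ACGA", {"ACGT", "ACGG"}, max_mismatch=1) is None


class TestAssignGene:
    def test_read_inside_single_gene(self, tiny_annotation):
        genes, _ = tiny_annotation
        gene = next(iter(genes))
        read = mkread(
            "r1",
            "A" * 10,
            [(gene.interval.start + 10, gene.interval.start + 110)],
            strand=gene.interval.strand,
        )
        assert assign_gene(read, genes) == gene.gene_id

    def test_read_outside_all_genes(self, tiny_annotation):
        genes, _ = tiny_annotation
        read = mkread("r1", "A" * 10, [(10_000_000, 10_000_100)])
        assert assign_gene(read, genes) is None

    def test_even_split_is_ambiguous(self, tiny_annotation):
        genes, _ = tiny_annotation
        ordered = sorted(genes, key=lambda g: g.interval.start)
        g1, g2 = (g for g in ordered[:2])
        # straddle the gap: equal aligned bases in each gene body
        read = mkread(
            "r1",
            "A" * 10,
            [(g1.interval.end - 50, g1.interval.end), (g2.interval.start, g2.interval.start + 50)],
            strand=g1.interval.strand,
        )
        # independent brute-force base counting
        ov1 = sum(
            max(0, min(b.end, g1.interval.end) - max(b.start, g1.interval.start))
            for b in read.blocks
        )
        ov2 = sum(
            max(0, min(b.end, g2.interval.end) - max(b.start, g2.interval.start))
            for b in read.blocks
        )
        assert ov1 == ov2 == 50
        assert assign_gene(read, genes) is None

    def test_wrong_strand_not_assigned(self, tiny_annotation):
        genes, _ = tiny_annotation
        gene = next(iter(genes))
        other = "-" if gene.interval.strand == "+" else "+"
        read = mkread(
            "r1",
            "A" * 10,
            [(gene.interval.start + 10, gene.interval.start + 110)],
            strand=other,
        )
        assert assign_gene(read, genes) is None


class TestDedupUmis:
    def test_distance_one_merges(self):
        reads = [
            mkread("r1", "AAAAAAAAAA", [(0, 100)]),
            mkread("r2", "AAAAAAAAAT", [(0, 100)]),
        ]
        mols = dedup_umis(reads, "BC", "G1")
        assert len(mols) == 1
        assert mols[0].n_reads == 2

    def test_distance_four_stays_distinct(self):
        reads = [
            mkread("r1", "AAAAAAAAAA", [(0, 100)]),
            mkread("r2", "TTTTAAAAAA", [(0, 100)]),
        ]
        assert edit_distance("AAAAAAAAAA", "TTTTAAAAAA") == 4
        assert len(dedup_umis(reads, "BC", "G1")) == 2

    def test_single_linkage_triple(self):
        umis = ["AAAAAAAAAA", "AAAAAAAAAT", "TTTTAAAAAA"]
        # pairwise distances: (1,2)=1 linked, (1,3)=4, (2,3)=5
        assert edit_distance(umis[0], umis[2]) == 4
        assert edit_distance(umis[1], umis[2]) == 5
        reads = [mkread(f"r{i}", u, [(0, 100)]) for i, u in enumerate(umis)]
        mols = dedup_umis(reads, "BC", "G1")
        assert sorted(m.n_reads for m in mols) == [1, 2]

    def test_order_invariance_and_read_conservation(self):
        umis = ["AAAAAAAAAA", "AAAAAAAATT", "GGGGGGGGGG", "GGGGGGGGGA", "ACGTACGTAC"]
        reads = [mkread(f"r{i}", u, [(0, 100 + 10 * i)]) for i, u in enumerate(umis)]
        reference = dedup_umis(reads, "BC", "G1")
        assert sum(m.n_reads for m in reference) == len(reads)
        for perm in itertools.permutations(reads):
            mols = dedup_umis(list(perm), "BC", "G1")
            assert [(m.umi, m.n_reads, m.blocks) for m in mols] == [
                (m.umi, m.n_reads, m.blocks) for m in reference
            ]

    def test_matches_brute_force_oracle(self):
        umis = ["AAAAAAAAAA", "AAAAAAATTT", "AAAATTTTTT", "TTTTTTTTTT", "AAAAAAAAAT"]
        reads = [mkread(f"r{i}", u, [(0, 100)]) for i, u in enumerate(umis)]
        mols = dedup_umis(reads, "BC", "G1")
        expected = brute_force_umi_clusters(umis)
        assert sorted(m.n_reads for m in mols) == sorted(len(c) for c in expected)

    def test_representative_umi_most_supported_then_lexicographic(self):
        reads = [
            mkread("r1", "AAAAAAAAAA", [(0, 100)]),
            mkread("r2", "AAAAAAAAAT", [(0, 150)]),
            mkread("r3", "AAAAAAAAAT", [(0, 50)]),
        ]
        (mol,) = dedup_umis(reads, "BC", "G1")
        assert mol.umi == "AAAAAAAAAT"  # supported by 2 reads
        assert mol.blocks[0].end == 150  # longest read's blocks

    def test_wrong_umi_length_is_error(self):
        with pytest.raises(ValueError, match="10"):
            dedup_umis([mkread("r1", "AAAA", [(0, 100)])], "BC", "G1")


EXON = GenomicInterval("chrS", 100, 200)


class TestCallExon:
    @pytest.mark.parametrize(
        "blocks,expected",
        [
            ([(0, 50), (100, 200), (300, 350)], ExonStatus.INCLUSION),
            ([(0, 50), (300, 350)], ExonStatus.EXCLUSION),
            ([(0, 150)], ExonStatus.UNINFORMATIVE),  # read ends inside the exon
            ([(100, 200)], ExonStatus.UNINFORMATIVE),  # no splice evidence
            ([(0, 50), (95, 200), (300, 350)], ExonStatus.UNINFORMATIVE),  # 5' off
            ([(0, 50), (60, 80), (300, 350)], ExonStatus.EXCLUSION),
            ([(0, 120), (180, 350)], ExonStatus.UNINFORMATIVE),  # partial overlap
        ],
    )
    def test_status(self, blocks, expected):
        ivs = [GenomicInterval("chrS", s, e) for s, e in blocks]
        assert call_exon(ivs, EXON) is expected

    def test_tolerance_rescues_near_boundaries(self):
        ivs = [GenomicInterval("chrS", s, e) for s, e in [(0, 50), (98, 201), (300, 350)]]
        assert call_exon(ivs, EXON, tol=0) is ExonStatus.UNINFORMATIVE
        assert call_exon(ivs, EXON, tol=2) is ExonStatus.INCLUSION

    def test_strand_agnostic(self):
        plus = [GenomicInterval("chrS", s, e, "+") for s, e in [(0, 50), (100, 200), (300, 350)]]
        minus = [GenomicInterval("chrS", s, e, "-") for s, e in [(0, 50), (100, 200), (300, 350)]]
        assert call_exon(plus, EXON) is call_exon(minus, EXON)

    def test_other_chromosome_uninformative(self):
        ivs = [GenomicInterval("chrX", 0, 50), GenomicInterval("chrX", 300, 350)]
        assert call_exon(ivs, EXON) is ExonStatus.UNINFORMATIVE


def _mol(barcode, blocks=((0, 50), (100, 200), (300, 350)), gene="G1"):
    return Molecule(
        barcode=barcode,
        umi="A" * 10,
        gene_id=gene,
        chrom="chrS",
        strand="+",
        blocks=tuple(GenomicInterval("chrS", s, e) for s, e in blocks),
    )


class TestInclusionTableBuilding:
    def test_counts_per_group(self):
        from scmultidiff.longread import ExonCall

        calls = [
            ExonCall(_mol("bcA"), EXON, ExonStatus.INCLUSION),
            ExonCall(_mol("bcA"), EXON, ExonStatus.INCLUSION),
            ExonCall(_mol("bcA"), EXON, ExonStatus.INCLUSION),
            ExonCall(_mol("bcA"), EXON, ExonStatus.EXCLUSION),
        ]
        table, dropped = build_inclusion_table(calls, {"bcA": "A"})
        assert dropped == 0
        assert table.counts(("G1", EXON), "A") == (3, 1)

    def test_uninformative_calls_ignored(self):
        from scmultidiff.longread import ExonCall

        calls = [ExonCall(_mol("bcA"), EXON, ExonStatus.UNINFORMATIVE)]
        table, _ = build_inclusion_table(calls, {"bcA": "A"})
        assert len(table) == 0

    def test_unresolvable_barcodes_dropped_and_counted(self):
        from scmultidiff.longread import ExonCall

        calls = [
            ExonCall(_mol("bcA"), EXON, ExonStatus.INCLUSION),
            ExonCall(_mol("????"), EXON, ExonStatus.INCLUSION),
        ]
        table, dropped = build_inclusion_table(calls, {"bcA": "A"})
        assert dropped == 1
        assert table.counts(("G1", EXON), "A") == (1, 0)

    def test_group_counts_conserve_total(self, small_dataset):
        genes, alt_exons, _, _, reads, truth = small_dataset
        from scmultidiff.longread import call_exons

        mols, _ = extract_molecules(reads, set(truth.cells.barcode), genes)
        exby = {g.gene_id: g.alternative_internal_exons() for g in genes}
        calls = call_exons(mols, exby)
        table, dropped = build_inclusion_table(calls, truth.barcode_to_group())
        assert dropped == 0
        for key in table.exons():
            total = sum(sum(table.counts(key, g)) for g in table.groups())
            informative = sum(
                1
                for c in calls
                if (c.molecule.gene_id, c.exon) == key
                and c.status is not ExonStatus.UNINFORMATIVE
            )
            assert total == informative


class TestCoinclusion:
    def test_perfect_coordination_phi_one(self):
        pairs = [(ExonStatus.INCLUSION, ExonStatus.INCLUSION)] * 5 + [
            (ExonStatus.EXCLUSION, ExonStatus.EXCLUSION)
        ] * 5
        res = coinclusion_association(pairs)
        assert res.phi == pytest.approx(1.0)
        assert res.n_molecules == 10

    def test_independence_flat_table(self):
        pairs = (
            [(ExonStatus.INCLUSION, ExonStatus.INCLUSION)] * 5
            + [(ExonStatus.INCLUSION, ExonStatus.EXCLUSION)] * 5
            + [(ExonStatus.EXCLUSION, ExonStatus.INCLUSION)] * 5
            + [(ExonStatus.EXCLUSION, ExonStatus.EXCLUSION)] * 5
        )
        res = coinclusion_association(pairs)
        assert res.phi == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_diagonal_table_matches_enumeration_oracle(self):
        pairs = [(ExonStatus.INCLUSION, ExonStatus.INCLUSION)] * 5 + [
            (ExonStatus.EXCLUSION, ExonStatus.EXCLUSION)
        ] * 5
        res = coinclusion_association(pairs)
        assert res.p_value == pytest.approx(fisher_oracle(5, 0, 0, 5), abs=1e-12)
        assert fisher_oracle(5, 0, 0, 5) == pytest.approx(2 / 252)

    def test_uninformative_molecules_excluded(self):
        pairs = [(ExonStatus.UNINFORMATIVE, ExonStatus.INCLUSION)] * 3
        assert coinclusion_association(pairs) is None


class TestBed12:
    def test_round_trip_with_sidecar(self, tmp_path, small_dataset):
        _, _, _, _, reads, _ = small_dataset
        subset = reads[:50]
        bed = tmp_path / "reads.bed12"
        sidecar = tmp_path / "meta.tsv"
        write_bed12(subset, bed)
        write_read_sidecar(subset, sidecar)
        back = read_bed12(bed, sidecar=sidecar)
        assert back == subset

    def test_name_delimiter_parsing(self, tmp_path):
        read = mkread("r1", "ACGTACGTAC", [(0, 50), (100, 200)])
        path = tmp_path / "r.bed12"
        with open(path, "w") as fh:
            fh.write(
                "chrS\t0\t200\tr1|ACGTACGTACGTACGT|ACGTACGTAC\t0\t+\t0\t200\t0\t2\t50,100\t0,100\n"
            )
        (back,) = read_bed12(path, name_delim="|")
        assert back == read
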