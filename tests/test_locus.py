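import numpy as np
import pytest

from popgenkit.locus import (
    AlignedLocus,
    AlignmentFormatError,
    AnnotationError,
    RegionAnnotation,
    Segment,
    classify_sites,
    effective_coding_sites,
    extract_indels,
    nei_gojobori_sites,
    read_alignment,
)
from tests.conftest import make_locus


class TestRegionAnnotation:
    def test_codon_map_simple(self, tiny_annotation):
        codons = list(tiny_annotation.codon_map(12))
        assert codons == [(0, (4, 5, 6)), (1, (7, 8, 9))]

    def test_codon_split_across_exons(self):
        ann = RegionAnnotation(
            [
                Segment("e1", 1, 4, "exon", 0),
                Segment("i1", 5, 6, "intron"),
                Segment("e2", 7, 11, "exon", 1),
            ]
        )
        # coding positions: 1,2,3,4 then 7..11 with phase 1 -> skip 2 leading
        # bases (9,10,11 usable): codons (1,2,3), (4,9,10); 11 is partial.
        assert list(ann.codon_map(11)) == [(0, (1, 2, 3)), (1, (4, 9, 10))]

    def test_overlapping_boundary_normalized(self, caplog):
        ann = RegionAnnotation(
            [
                Segment("i1", 1, 738, "intron"),
                Segment("e2", 738, 918, "exon", 0),
            ]
        )
        assert ann.segments[1].start == 739
        # phase advanced by the 1-base shift
        assert ann.segments[1].phase == 1

    def test_full_overlap_rejected(self):
        with pytest.raises(AnnotationError):
            RegionAnnotation(
                [
                    Segment("a", 1, 10, "intron"),
                    Segment("b", 2, 8, "exon", 0),
                ]
            )

    def test_bad_class_rejected(self):
        with pytest.raises(AnnotationError):
            Segment("x", 1, 5, "promoter")


class TestAlignedLocus:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(AlignmentFormatError):
            make_locus(["ACGT", "ACGA"], ids=["a", "a"])

    def test_invalid_symbols_rejected(self):
        with pytest.raises(AlignmentFormatError):
            make_locus(["ACGU", "ACGA"])

    def test_ingroup_indices_majority_species(self):
        locus = make_locus(
            ["ACGT", "ACGA", "ACGC"],
            species=["ingroup", "ingroup", "sister"],
        )
        assert locus.ingroup_indices().tolist() == [0, 1]

    def test_gap_free_mask(self):
        locus = make_locus(["AC-T", "ACGT"])
        assert locus.gap_free_mask().tolist() == [True, True, False, True]


class TestIndels:
    def test_minority_gap_is_deletion(self):
        ids = ["a", "b", "c"]
        m = np.array([list("AC--T"), list("ACGGT"), list("ACGGT")])
        reg = extract_indels(ids, m)
        assert len(reg) == 1
        ev = reg.events[0]
        assert (ev.start, ev.end, ev.kind) == (3, 4, "deletion")
        assert ev.carriers == frozenset({"a"})

    def test_majority_gap_is_insertion(self):
        ids = ["a", "b", "c"]
        m = np.array([list("ACGGT"), list("AC--T"), list("AC--T")])
        reg = extract_indels(ids, m)
        ev = reg.events[0]
        assert ev.kind == "insertion"
        assert ev.carriers == frozenset({"a"})

    def test_distinct_spans_distinct_events(self):
        ids = ["a", "b", "c"]
        m = np.array([list("A--GT"), list("A---T"), list("ACGGT")])
        reg = extract_indels(ids, m)
        assert len(reg) == 2


class TestClassifySites:
    def test_tiny_locus_classes(self, tiny_locus):
        sites = classify_sites(tiny_locus)
        by_pos = {s.position: s for s in sites.sites}
        assert set(by_pos) == {3, 4, 9, 12}
        assert by_pos[3].cls == "flanking"
        assert by_pos[4].cls == "nonsynonymous"   # ATG -> CTG (M -> L)
        assert by_pos[9].cls == "synonymous"      # AAA -> AAG (K)
        assert by_pos[12].cls == "intronic"
        assert all(s.singleton for s in sites.sites)
        assert sites.singleton_count() == 4

    def test_gap_column_excluded(self, tiny_annotation):
        rows = ["ACGATGAAATTT", "AC-ATGAAATTT", "ACTATGAAATTT",
                "ACGATGAAATTT"]
        sites = classify_sites(make_locus(rows, annotation=tiny_annotation))
        rec = [s for s in sites.sites if s.position == 3][0]
        assert rec.excluded
        assert sites.positions() == []

    def test_n_at_polymorphic_codon_position_ambiguous(self, tiny_annotation):
        # codon 2 (pos 7-9): AAA / AAG segregating, plus an N at pos 9
        rows = ["ACGATGAAATTT", "ACGATGAAGTTT", "ACGATGAANTTT",
                "ACGATGAAATTT"]
        sites = classify_sites(make_locus(rows, annotation=tiny_annotation))
        rec = [s for s in sites.sites if s.position == 9][0]
        assert rec.cls == "ambiguous"

    def test_multi_hit_codon_pathway(self, tiny_annotation):
        # codon 1 alleles: ATG, CTG, ATA.  Position 4 is nonsynonymous in
        # every pairwise pathway (M->L).  Position 6 is ambiguous: ATG->ATA
        # is nonsynonymous (M->I) but the CTG->ATA pathway via CTA makes the
        # third-position change synonymous (L->L).
        rows = ["ACGATGAAATTT", "ACGCTGAAATTT", "ACGATAAAATTT",
                "ACGATGAAATTT"]
        sites = classify_sites(make_locus(rows, annotation=tiny_annotation))
        by_pos = {s.position: s.cls for s in sites.sites}
        assert by_pos[4] == "nonsynonymous"
        assert by_pos[6] == "ambiguous"


class TestNeiGojobori:
    def test_known_codon_site_counts(self):
        # Phe TTT: pos3 T->C synonymous only change among 3 (TTC=F syn;
        # TTA,TTG = Leu nonsyn) -> syn fraction 1/3 at pos3, 0 elsewhere
        s, n = nei_gojobori_sites("TTT")
        assert s == pytest.approx(1.0 / 3.0)
        assert n == pytest.approx(8.0 / 3.0)

    def test_fourfold_codon(self):
        # GGG glycine: third position fully synonymous
        s, n = nei_gojobori_sites("GGG")
        assert s == pytest.approx(1.0)
        assert n == pytest.approx(2.0)

    def test_effective_sites_sum_to_coding_length(self, tiny_locus):
        s, n = effective_coding_sites(tiny_locus)
        assert s + n == pytest.approx(6.0)  # 2 complete codons


class TestIO:
    def test_round_trip(self, tmp_path, tiny_locus):
        fasta = tmp_path / "a.fasta"
        with open(fasta, "w") as fh:
            for i, sid in enumerate(tiny_locus.ids):
                fh.write(f">{sid}\n{''.join(tiny_locus.matrix[i])}\n")
        regions = tmp_path / "r.tsv"
        with open(regions, "w") as fh:
            fh.write("name\tstart\tend\tclass\tphase\n")
            for s in tiny_locus.annotation.segments:
                fh.write(f"{s.name}\t{s.start}\t{s.end}\t{s.cls}\t{s.phase}\n")
        locus = read_alignment(str(fasta), regions_path=str(regions))
        assert locus.ids == tiny_locus.ids
        assert (locus.matrix == tiny_locus.matrix).all()
        assert len(locus.annotation.segments) == 3

    def test_unequal_lengths_rejected(self, tmp_path):
        fasta = tmp_path / "bad.fasta"
        fasta.write_text(">a\nACGT\n>b\nACG\n")
        with pytest.raises(AlignmentFormatError):
            read_alignment(str(fasta))

    def test_labels_table(self, tmp_path):
        fasta = tmp_path / "a.fasta"
        fasta.write_text(">a\nACGT\n>b\nACGA\n")
        labels = tmp_path / "l.tsv"
        labels.write_text("id\tpopulation\tspecies\tgroup\n"
                          "a\tAfrica\tingroup\tA\nb\tEurope\tingroup\tB\n")
        locus = read_alignment(str(fasta), labels_path=str(labels))
        assert locus.populations == ["Africa", "Europe"]
        assert locus.groups == ["A", "B"]
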