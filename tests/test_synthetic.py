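import json

import numpy as np
import pytest

from popgenkit import synthetic
from popgenkit.codon import CODONS
from popgenkit.diversity import diversity_stats
from popgenkit.haplotypes import group_contrast
from popgenkit.locus import STOP_CODONS, read_alignment


class TestDefaultAnnotation:
    def test_layout_covers_locus(self):
        ann = synthetic.default_annotation(2000)
        segs = ann.segments
        assert [s.cls for s in segs] == [
            "flank", "exon", "intron", "exon", "flank"
        ]
        assert segs[0].start == 1 and segs[-1].end == 2000
        for a, b in zip(segs, segs[1:]):
            assert b.start == a.end + 1

    def test_exons_in_frame(self):
        ann = synthetic.default_annotation(1500)
        for seg in ann.segments:
            if seg.cls == "exon":
                assert (seg.end - seg.start + 1) % 3 == 0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            synthetic.default_annotation(50)


class TestGenNeutral:
    def test_determinism(self):
        l1, t1 = synthetic.gen_neutral(n=10, L=500, seed=7)
        l2, t2 = synthetic.gen_neutral(n=10, L=500, seed=7)
        assert (l1.matrix == l2.matrix).all()
        assert t1 == t2

    def test_seed_changes_output(self):
        l1, _ = synthetic.gen_neutral(n=10, L=500, seed=1)
        l2, _ = synthetic.gen_neutral(n=10, L=500, seed=2)
        assert not (l1.matrix == l2.matrix).all()

    def test_truth_matches_alignment(self):
        locus, truth = synthetic.gen_neutral(n=12, L=600, seed=3)
        # every truth site is variable in the matrix, and no other column is
        variable = {
            c + 1
            for c in range(600)
            if len(set(locus.matrix[:, c])) > 1
        }
        assert variable == set(truth["site_coords"])
        assert truth["segregating_sites"] == len(truth["site_coords"])
        for coord, allele in truth["derived_alleles"].items():
            col = locus.matrix[:, int(coord) - 1]
            assert allele in col

    def test_no_inframe_stops(self):
        locus, _ = synthetic.gen_neutral(n=8, L=900, seed=11)
        for _, positions in locus.annotation.codon_map(900):
            for row in locus.matrix:
                codon = "".join(row[p - 1] for p in positions)
                assert codon not in STOP_CODONS

    def test_defaults(self):
        locus, truth = synthetic.gen_neutral(seed=0)
        assert len(locus.ids) == 28
        assert locus.matrix.shape == (28, 2000)
        assert truth["theta_per_site"] == 0.005
        assert truth["rho_per_site"] == 0.006


class TestGenDimorphic:
    def test_fixed_differences_counted(self):
        locus, truth = synthetic.gen_dimorphic(seed=2)
        res = group_contrast(locus)
        assert res.fixed_differences == truth["n_fixed"] == 19

    def test_group_thetas_ordered(self):
        # group B is generated at ~5x the mutation rate of group A
        locus, _ = synthetic.gen_dimorphic(seed=4)
        rows_a = [i for i, g in enumerate(locus.groups) if g == "A"]
        rows_b = [i for i, g in enumerate(locus.groups) if g == "B"]
        pi_a = diversity_stats(locus, rows=np.array(rows_a)).pi
        pi_b = diversity_stats(locus, rows=np.array(rows_b)).pi
        assert pi_b > pi_a

    def test_conversion_tract_copies_donor(self):
        locus, truth = synthetic.gen_dimorphic(
            seed=6,
            conversion_tract={"start": 500, "end": 900, "recipients": 2},
        )
        tract = truth["conversion_tract"]
        assert tract["recipients"] == ["B01", "B02"]
        donor = locus.matrix[locus.ids.index("A01")]
        for rec in tract["recipients"]:
            row = locus.matrix[locus.ids.index(rec)]
            assert (row[499:900] == donor[499:900]).all()

    def test_indels_applied_and_recorded(self):
        locus, truth = synthetic.gen_dimorphic(
            seed=8, indel_spec=[{"start": 100, "end": 120, "group": "B"}]
        )
        rows_b = [i for i, g in enumerate(locus.groups) if g == "B"]
        assert (locus.matrix[rows_b, 99:120] == "-").all()
        assert truth["indels"] == [
            {"start": 100, "end": 120, "group": "B"}
        ]
        assert locus.indels  # gap spans extracted into the indel table

    def test_tract_outside_locus_rejected(self):
        with pytest.raises(ValueError):
            synthetic.gen_dimorphic(
                seed=1, L=500,
                conversion_tract={"start": 400, "end": 600},
            )

    def test_determinism(self):
        l1, t1 = synthetic.gen_dimorphic(seed=9)
        l2, t2 = synthetic.gen_dimorphic(seed=9)
        assert (l1.matrix == l2.matrix).all()
        assert t1 == t2


class TestGenCodon:
    def test_shape_and_truth(self):
        data, truth = synthetic.gen_codon(n_sites=80, seed=1)
        assert data.n_sites == 80
        assert data.codons.shape == (6, 80)
        assert len(truth["site_class_index"]) == 80
        assert truth["site_classes"] == [
            {"omega": 0.22, "proportion": 1.0}
        ]

    def test_class_proportions_respected(self):
        classes = [(0.05, 0.7), (1.5, 0.3)]
        data, truth = synthetic.gen_codon(
            n_sites=500, site_classes=classes, seed=2
        )
        idx = np.array(truth["site_class_index"])
        frac = np.mean(idx == 1)
        # binomial SD at n=500, p=0.3 is ~0.02
        assert abs(frac - 0.3) < 0.08

    def test_no_stop_codons_emitted(self):
        data, _ = synthetic.gen_codon(n_sites=60, seed=3)
        for row in data.codons:
            for state in row:
                assert CODONS[state] not in STOP_CODONS

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            synthetic.gen_codon(site_classes=[(0.2, 0.5), (1.0, 0.4)])

    def test_determinism(self):
        d1, t1 = synthetic.gen_codon(n_sites=40, seed=5)
        d2, t2 = synthetic.gen_codon(n_sites=40, seed=5)
        assert (d1.codons == d2.codons).all()
        assert t1 == t2


class TestWriteLocusBundle:
    def test_round_trip(self, tmp_path):
        locus, truth = synthetic.gen_dimorphic(seed=12, L=600)
        paths = synthetic.write_locus_bundle(locus, truth, tmp_path, "demo")
        back = read_alignment(
            paths["fasta"],
            regions_path=paths["regions"],
            labels_path=paths["labels"],
        )
        assert back.ids == locus.ids
        assert (back.matrix == locus.matrix).all()
        assert back.groups == locus.groups
        assert [s.cls for s in back.annotation.segments] == [
            s.cls for s in locus.annotation.segments
        ]
        with open(paths["truth"]) as fh:
            assert json.load(fh) == json.loads(json.dumps(truth))
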