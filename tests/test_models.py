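"""Gene-model assembly: clustering, spliced alignment, ORF assessment."""

import pytest

from lrcpipe import models as M
from lrcpipe import synth
from lrcpipe.scan import DomainHit
from lrcpipe.synth import GenePlan, LesionSpec, generate_locus, \
    single_gene_locus

from .conftest import best_reference_model


def make_hit(contig="c", strand="+", start=0, end=294, qid="IG_consensus",
             cls="IG"):
    return DomainHit(query_id=qid, domain_class=cls, contig=contig,
                     strand=strand, frame=0, start=start, end=end,
                     score=300.0, pct_identity=90.0, subject_aa="X",
                     has_internal_stop=False)


class TestClusterHits:
    def test_nearby_hits_chain_into_one_locus(self):
        hits = [make_hit(start=0, end=294),
                make_hit(start=1294, end=1588)]
        loci = M.cluster_hits(hits, max_gap=10_000)
        assert len(loci) == 1 and len(loci[0].member_hits) == 2

    def test_distant_hits_split_into_two_loci(self):
        hits = [make_hit(start=0, end=294),
                make_hit(start=50_294, end=50_588)]
        loci = M.cluster_hits(hits, max_gap=10_000)
        assert len(loci) == 2

    def test_opposite_strands_never_chain(self):
        hits = [make_hit(start=0, end=294, strand="+"),
                make_hit(start=0, end=294, strand="-")]
        loci = M.cluster_hits(hits, max_gap=10_000)
        assert len(loci) == 2
        assert {l.strand for l in loci} == {"+", "-"}

    def test_framing_context_annotated(self):
        hits = [make_hit(start=5000, end=5294)]
        framing = [("GP6", "c", 0, 2000), ("RDH13", "c", 9000, 11_000)]
        locus = M.cluster_hits(hits, framing=framing)[0]
        assert locus.context.between("GP6", "RDH13")
        assert locus.context.upstream == ("GP6", 3000)


class TestSplicedAlign:
    def test_clean_gene_maps_all_exons_gtag_no_lesions(self, references):
        truth = generate_locus(single_gene_locus(
            GenePlan("g", receptor_type="B", ig_count=4), seed=31))
        model = best_reference_model(truth, references)
        assert model.reference.name == "LILR_ref_4Ig_L"
        assert len(model.exon_alignments) == 7
        assert all(d == "GT" and a == "AG"
                   for d, a in model.splice_sites)
        assert model.lesions == []
        assert model.cds == truth.genes[0].cds

    def test_minus_strand_round_trip(self, references):
        truth = generate_locus(single_gene_locus(
            GenePlan("g", strand="-", receptor_type="A", ig_count=2),
            seed=32))
        model = best_reference_model(truth, references, strand="-")
        assert model.strand == "-"
        assert model.cds == truth.genes[0].cds
        assert M.extract_cds(model).seq == truth.genes[0].cds
        # exon coordinates are reported on the forward strand
        assert sorted(s for s, _, _ in model.exons) == \
            sorted(s for s, _, _ in truth.genes[0].exons)

    def test_donor_gt_to_gc_is_splice_disruption(self, references):
        truth = generate_locus(single_gene_locus(
            GenePlan("g", receptor_type="B", ig_count=4,
                     lesions=[LesionSpec("splice_disruption", 1)]),
            seed=33))
        model = best_reference_model(truth, references)
        kinds = [(l.kind, l.position) for l in model.lesions]
        assert kinds == [("splice_disruption", 1)]
        assert model.splice_sites[1][0] == "GC"

    def test_reference_with_more_ig_exons_records_missing_domains(
            self, references):
        truth = generate_locus(single_gene_locus(
            GenePlan("g", receptor_type="B", ig_count=2), seed=34))
        model = M.spliced_align(references["LILR_ref_4Ig_L"],
                                truth.sequence, 0, "+", truth.contig)
        missing = [l for l in model.lesions if l.kind == "missing_domain"]
        assert len(missing) == 2
        assert all(l.domain_class == "IG" for l in missing)

    def test_no_anchor_returns_none(self, references):
        import random

        rng = random.Random(1)
        seq = "".join(rng.choice("ACGT") for _ in range(10_000))
        assert M.spliced_align(references["LILR_ref_2Ig_L"], seq, 0, "+",
                               "rnd") is None


class TestAssessOrf:
    def run_with_lesions(self, references, lesions, seed=35,
                         receptor_type="B"):
        truth = generate_locus(single_gene_locus(
            GenePlan("g", receptor_type=receptor_type, ig_count=4,
                     lesions=lesions), seed=seed))
        return best_reference_model(truth, references)

    def test_single_bp_insertion_is_unrestored_frameshift(self, references):
        model = self.run_with_lesions(
            references, [LesionSpec("frameshift_ins", 1, 60, 1)])
        fs = [l for l in model.lesions if l.kind == "frameshift"]
        assert len(fs) == 1
        assert fs[0].restored_within_codons is None

    def test_three_bp_insertion_is_not_a_frameshift(self, references):
        model = self.run_with_lesions(
            references, [LesionSpec("frameshift_ins", 1, 60, 3)])
        assert [l for l in model.lesions if l.kind == "frameshift"] == []

    def test_two_deletions_nine_bp_apart_restore_frame_in_three_codons(
            self, references):
        """-1 bp then -2 bp, 9 bp apart: the frame is disrupted and
        restored with three codons affected (arithmetic checked on a
        constructed exon alignment, independent of the aligner)."""
        ref = references["LILR_ref_2Ig_L"]
        seg_len = 294 - 3
        a = M.ExonAlignment("IG", 1, 294, 45, 45 + seg_len,
                            [(30, -1), (39, -2)], 3)
        model = M.GeneModel(
            contig="c", strand="+", reference=ref,
            exons=[(45, 45 + seg_len, "IG")], exon_alignments=[a],
            splice_sites=[], cds="ATG" * (seg_len // 3), protein="")
        lesions = M.assess_orf(model, ref)
        fs = [l for l in lesions if l.kind == "frameshift"]
        assert len(fs) == 1
        assert fs[0].restored_within_codons == 3

    def test_compensated_lesion_end_to_end_is_tolerated(self, references):
        """Through the full spliced alignment the two compensating
        deletions surface either as a frameshift restored within a few
        codons or as one in-frame 3 bp deletion, whichever alignment is
        more parsimonious for the divergence draw; both are tolerated."""
        for seed in (0, 35):
            truth = generate_locus(single_gene_locus(
                GenePlan("g", receptor_type="B", ig_count=4,
                         lesions=[LesionSpec(
                             "compensated_double_frameshift", 1, 30, 3)]),
                seed=seed))
            model = best_reference_model(truth, references)
            fs = [l for l in model.lesions if l.kind == "frameshift"]
            if fs:
                assert fs[0].restored_within_codons <= 5
            else:
                assert model.lesions == []
            assert len(model.cds) == len(truth.genes[0].cds)

    def test_nonsense_is_premature_stop_at_planted_codon(self, references):
        model = self.run_with_lesions(
            references, [LesionSpec("nonsense", 1, 60)])
        stops = [l for l in model.lesions if l.kind == "premature_stop"]
        # codon 20 of the first Ig exon, after the 15-codon signal peptide
        assert [l.position for l in stops] == [35]

    def test_lesion_multiset_matches_planted_grid(self, references):
        grid = [
            ([LesionSpec("frameshift_del", 2, 90, 2)], {"frameshift"}),
            ([LesionSpec("nonsense", 3, 45)], {"premature_stop"}),
            ([LesionSpec("splice_disruption", 0)], {"splice_disruption"}),
            ([LesionSpec("frameshift_ins", 1, 12, 1),
              LesionSpec("nonsense", 2, 30)],
             {"frameshift", "premature_stop"}),
            ([], set()),
        ]
        for seed, (lesions, expected) in enumerate(grid, start=40):
            model = self.run_with_lesions(references, lesions, seed=seed)
            got = {l.kind for l in model.lesions}
            assert got == expected, (lesions, got)


class TestFeatures:
    def test_every_exon_lies_inside_its_locus(self, cat_models, cat_hits):
        loci = M.cluster_hits(cat_hits)
        for model in cat_models:
            locus = next(l for l in loci if l.strand == model.strand
                         and l.start - 2000 <= model.start
                         and model.end <= l.end + 2000)
            for s, e, _ in model.exons:
                assert locus.start - 2000 <= s and e <= locus.end + 2000

    def test_feature_extraction_on_activating_gene(self, references):
        truth = generate_locus(single_gene_locus(
            GenePlan("g", receptor_type="A", ig_count=4), seed=36))
        f = best_reference_model(truth, references).features
        assert f["sp_present"] and f["tm_present"]
        assert f["tm_has_arginine"]
        assert f["ig_count"] == 4
        assert f["tail_kind"] == "short"

    def test_frameshift_in_one_ig_exon_keeps_other_features(
            self, references):
        model = TestAssessOrf().run_with_lesions(
            references, [LesionSpec("frameshift_ins", 1, 60, 1)])
        f = model.features
        assert f["tm_present"] and f["tail_kind"] == "long"
        assert f["sp_present"]


def test_single_exon_cds_equals_exon_substring(references):
    ref = references["LILR_ref_2Ig_L"]
    model = M.GeneModel(
        contig="c", strand="+", reference=ref,
        exons=[(10, 55, "SP")],
        exon_alignments=[M.ExonAlignment("SP", 0, 45, 10, 55, [], 0)],
        splice_sites=[], cds="A" * 45, protein="K" * 15)
    assert str(M.extract_cds(model, "x").seq) == "A" * 45
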