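"""Gene-integrity screening: anchoring, exon mapping, lesion calling."""

import itertools

import pytest

import enac_decay as ed
from enac_decay.errors import (
    AnchorNotFound,
    InvalidAnchors,
    NomenclatureError,
)
from enac_decay.integrity import Anchor, _chain_hits
from enac_decay.simulate import FusionPlan, LesionPlan


# ---------------------------------------------------------------------------
# extract_target_region
# ---------------------------------------------------------------------------

class TestExtractRegion:
    def test_forward_strand_recovers_planted_segment(self, intact_locus):
        rec = ed.extract_target_region(intact_locus.chromosome,
                                       intact_locus.anchors)
        assert rec.sequence == intact_locus.locus.sequence
        assert rec.strand == "+"

    def test_reverse_strand_gives_identical_sequence(self):
        fwd = ed.generate_locus_set(ed.LocusSpec(seed=21, strand="+"))
        rev = ed.generate_locus_set(ed.LocusSpec(seed=21, strand="-"))
        rec_fwd = ed.extract_target_region(fwd.chromosome, fwd.anchors)
        rec_rev = ed.extract_target_region(rev.chromosome, rev.anchors)
        assert rec_rev.sequence == rec_fwd.sequence

    def test_missing_anchor_raises(self, intact_locus):
        only_one = [a for a in intact_locus.anchors if a.name == "UBE2J2"]
        with pytest.raises(AnchorNotFound):
            ed.extract_target_region(intact_locus.chromosome, only_one)

    def test_overlapping_anchors_raise(self):
        anchors = [Anchor("UBE2J2", 0, 500), Anchor("ACAP3", 400, 900)]
        with pytest.raises(InvalidAnchors):
            ed.extract_target_region("A" * 1000, anchors)


# ---------------------------------------------------------------------------
# map_exons
# ---------------------------------------------------------------------------

class TestMapExons:
    def test_intact_locus_maps_all_exons_perfectly(self, intact_locus,
                                                   intact_hits):
        ref = intact_locus.reference
        assert [h.label for h in intact_hits] == ref.labels
        assert all(h.identity == 100.0 for h in intact_hits)
        assert all(h.donor == "GT" for h in intact_hits[:-1])
        assert all(h.acceptor == "AG" for h in intact_hits[1:])
        for h in intact_hits:
            assert (h.start, h.end) == intact_locus.exon_coords[h.label]

    def test_deleted_exon_is_not_mapped(self):
        loc = ed.generate_locus_set(
            ed.LocusSpec(seed=22, lesions=(LesionPlan("exon_missing", "6"),))
        )
        hits = ed.map_exons(loc.locus, loc.reference)
        labels = [h.label for h in hits]
        assert "6" not in labels
        assert set(labels) == set(loc.reference.labels) - {"6"}

    def test_fused_locus_has_noncanonical_junction(self):
        loc = ed.generate_locus_set(ed.LocusSpec(seed=23, fusion=FusionPlan()))
        hits = {h.label: h for h in ed.map_exons(loc.locus, loc.reference)}
        gap = hits["12"].start - hits["11"].end
        assert gap == 15
        assert hits["11"].donor != "GT"
        assert hits["12"].acceptor != "AG"

    def test_chaining_matches_exhaustive_selection(self):
        # small synthetic loci: chained subset must equal the best-scoring
        # colinear non-overlapping subset found by brute force
        for seed in range(5):
            loc = ed.generate_locus_set(
                ed.LocusSpec(
                    seed=100 + seed,
                    exon_lengths=(90, 120, 96, 75),
                    exon_labels=("2", "3", "4", "5"),
                    intron_length=(80, 150),
                )
            )
            raw = [
                {"label": h.label, "start": h.start, "end": h.end,
                 "score": h.score}
                for h in ed.map_exons(loc.locus, loc.reference)
            ]
            order = {lab: i for i, lab in enumerate(loc.reference.labels)}
            best = 0.0
            for r in range(1, len(raw) + 1):
                for combo in itertools.combinations(raw, r):
                    c = sorted(combo, key=lambda h: order[h["label"]])
                    ok = all(
                        a["end"] <= b["start"] for a, b in zip(c, c[1:])
                    )
                    if ok:
                        best = max(best, sum(h["score"] for h in c))
            chained = _chain_hits(raw, order)
            assert sum(h["score"] for h in chained) == pytest.approx(best)


# ---------------------------------------------------------------------------
# classify_locus
# ---------------------------------------------------------------------------

class TestClassify:
    def test_intact_locus(self, intact_locus, intact_hits):
        rep = ed.classify_locus(intact_hits, intact_locus.locus,
                                intact_locus.reference)
        assert rep.status == "intact"
        assert rep.lesions == []
        assert rep.cds == intact_locus.cds
        assert rep.protein.endswith("*")
        assert "*" not in rep.protein[:-1]

    def test_planted_stop_and_frameshift_recovered_at_coords(self):
        spec = ed.LocusSpec(
            seed=24,
            lesions=(
                LesionPlan("premature_stop", "5", 30),
                LesionPlan("frameshift", "8", 20, -2),
            ),
        )
        loc = ed.generate_locus_set(spec)
        rep = ed.screen_locus(loc.locus, loc.reference)
        assert rep.status == "pseudogene"
        found = {(l.kind, l.exon) for l in rep.lesions}
        assert found == {("premature_stop", "5"), ("frameshift", "8")}
        truth = {(l.kind, l.exon): l for l in loc.lesions}
        for lesion in rep.lesions:
            t = truth[(lesion.kind, lesion.exon)]
            if lesion.kind == "premature_stop":
                assert (lesion.start, lesion.end) == (t.start, t.end)
            else:  # indel placement may shift within a repeat
                assert abs(lesion.start - t.start) <= 6

    @pytest.mark.parametrize("kind,exon", [
        ("premature_stop", "4"),
        ("frameshift", "7"),
        ("splice_donor_loss", "3"),
        ("splice_acceptor_loss", "10"),
        ("exon_missing", "6"),
    ])
    def test_each_lesion_kind_round_trips(self, kind, exon):
        loc = ed.generate_locus_set(
            ed.LocusSpec(seed=25, lesions=(LesionPlan(kind, exon, 12),))
        )
        rep = ed.screen_locus(loc.locus, loc.reference)
        assert rep.status == "pseudogene"
        assert {(l.kind, l.exon) for l in rep.lesions} == {(kind, exon)}

    def test_random_sequence_between_anchors_is_absent(self):
        loc = ed.generate_locus_set(ed.LocusSpec(seed=26, absent=True))
        rep = ed.screen_locus(loc.locus, loc.reference)
        assert rep.status == "absent"
        assert rep.lesions == []

    def test_frameshift_insertion_variant(self):
        loc = ed.generate_locus_set(
            ed.LocusSpec(seed=27,
                         lesions=(LesionPlan("frameshift", "5", 40, 4),))
        )
        rep = ed.screen_locus(loc.locus, loc.reference)
        assert ("frameshift", "5") in {(l.kind, l.exon) for l in rep.lesions}


# ---------------------------------------------------------------------------
# super-exon detection
# ---------------------------------------------------------------------------

class TestSuperExon:
    def test_planted_fusion_reports_five_residues(self):
        loc = ed.generate_locus_set(
            ed.LocusSpec(seed=28, fusion=FusionPlan(retained_length=15))
        )
        hits = ed.map_exons(loc.locus, loc.reference)
        fusion = ed.detect_super_exon(hits, loc.locus, loc.reference)
        assert fusion is not None
        assert fusion.labels == ("11", "12")
        assert fusion.retained_length == 15
        assert fusion.inserted_residues == 5
        assert (fusion.start, fusion.end) == loc.fusion_coords

    def test_intact_locus_has_no_fusion(self, intact_locus, intact_hits):
        assert ed.detect_super_exon(intact_hits, intact_locus.locus,
                                    intact_locus.reference) is None

    def test_unmapped_pair_returns_none(self, intact_locus, intact_hits):
        partial = [h for h in intact_hits if h.label != "12"]
        assert ed.detect_super_exon(partial, intact_locus.locus,
                                    intact_locus.reference) is None

    def test_fusion_neutrality(self):
        # a clean in-frame fusion is a feature, not a lesion
        loc = ed.generate_locus_set(ed.LocusSpec(seed=29, fusion=FusionPlan()))
        rep = ed.screen_locus(loc.locus, loc.reference)
        assert rep.status == "intact"
        assert rep.fusion is not None
        assert rep.lesions == []

    def test_fusion_plus_lesion_is_pseudogene_with_fusion(self):
        loc = ed.generate_locus_set(
            ed.LocusSpec(seed=30, fusion=FusionPlan(),
                         lesions=(LesionPlan("premature_stop", "4", 21),))
        )
        rep = ed.screen_locus(loc.locus, loc.reference)
        assert rep.status == "pseudogene"
        assert rep.fusion is not None
        assert {(l.kind, l.exon) for l in rep.lesions} == {
            ("premature_stop", "4")
        }


# ---------------------------------------------------------------------------
# nomenclature
# ---------------------------------------------------------------------------

class TestNomenclature:
    def test_single_upstream_exon(self):
        assert ed.assign_exon_nomenclature(13, 1) == [
            "1"] + [str(i) for i in range(2, 14)]

    def test_two_alternative_upstream_exons(self):
        labels = ed.assign_exon_nomenclature(14, 2)
        assert labels[:2] == ["1a", "1b"]
        assert labels[2:] == [str(i) for i in range(2, 14)]

    def test_fused_gene_labels(self):
        labels = ed.assign_exon_nomenclature(11, 0, fused_pair=(11, 12))
        assert labels == [str(i) for i in range(2, 11)] + ["11*", "13"]

    def test_too_many_core_exons(self):
        with pytest.raises(NomenclatureError):
            ed.assign_exon_nomenclature(14, 0)
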