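"""Novel-isoform collapse, classification and the three validation filters."""

from __future__ import annotations

import pytest
from intervaltree import IntervalTree

from scnaumi.isoforms import ExonStructure, TranscriptModel, load_annotation
from scnaumi.novel import (
    GeneAnnotationSets,
    NovelCandidate,
    classify,
    collapse,
    export_gtf,
    validate,
)


def struct(junctions, span=(100, 2000), strand="+"):
    return ExonStructure("chr1", strand, tuple(junctions), span)


@pytest.fixture()
def annotation():
    # gene with three exons [100,200) [300,400) [500,600): junctions
    # (200,300) and (400,500); plus a skipping isoform (200,500)
    models = [
        TranscriptModel("G", "G.t1", ExonStructure.from_exons("chr1", "+", [(100, 200), (300, 400), (500, 600)])),
        TranscriptModel("G", "G.t2", ExonStructure.from_exons("chr1", "+", [(100, 200), (500, 600)])),
    ]
    return GeneAnnotationSets.from_models(models)


class TestCollapse:
    def test_five_identical_kept(self, annotation):
        novel = ((200, 300), (400, 700))  # unannotated acceptor 700
        mols = [(f"m{i}", "G", struct(novel)) for i in range(5)]
        cands = collapse(mols, annotation)
        assert len(cands) == 1
        assert cands[0].n_umis == 5

    def test_four_discarded(self, annotation):
        novel = ((200, 300), (400, 700))
        mols = [(f"m{i}", "G", struct(novel)) for i in range(4)]
        assert collapse(mols, annotation) == []

    def test_different_ends_same_candidate(self, annotation):
        novel = ((200, 300), (400, 700))
        mols = [(f"m{i}", "G", struct(novel, span=(100 + 10 * i, 2000 + i))) for i in range(5)]
        cands = collapse(mols, annotation)
        assert len(cands) == 1 and cands[0].n_umis == 5

    def test_jitter_snapped_to_annotated_sites(self, annotation):
        # donors off by <=2 snap to 200/400 -> single candidate
        mols = [
            (f"m{i}", "G", struct(((200 + d, 300), (400, 700))))
            for i, d in enumerate((-2, -1, 0, 1, 2))
        ]
        cands = collapse(mols, annotation)
        assert len(cands) == 1 and cands[0].structure.junctions[0] == (200, 300)

    def test_chain_equal_to_annotation_not_novel(self, annotation):
        known = ((200, 300), (400, 500))
        mols = [(f"m{i}", "G", struct(known)) for i in range(6)]
        assert collapse(mols, annotation) == []


class TestClassify:
    def test_known_junctions_exon_skipping(self, annotation):
        # chain (200,300) alone: both junctions annotated, chain novel
        c = NovelCandidate("G", struct(((200, 300),), span=(100, 400)), {"a"} )
        assert classify(c, annotation) == "known_junctions"

    def test_novel_sites(self, annotation):
        c = NovelCandidate("G", struct(((200, 300), (400, 700))), {"a"})
        assert classify(c, annotation) == "novel_sites"

    def test_known_sites_cross_pairing(self):
        # annotation with two introns; candidate pairs donor1 with acceptor2
        models = [
            TranscriptModel("G", "t1", ExonStructure.from_exons("chr1", "+", [(0, 10), (20, 30), (40, 50)])),
        ]
        ann = GeneAnnotationSets.from_models(models)
        c = NovelCandidate("G", struct(((10, 40),), span=(0, 50)), {"a"})
        assert classify(c, ann) == "known_sites"


class TestValidate:
    def make_candidate(self, annotation, junctions=((200, 300), (400, 700)), span=(100, 2000)):
        c = NovelCandidate("G", struct(junctions, span=span), {"a", "b", "c", "d", "e"})
        classify(c, annotation)
        return c

    def test_tss_50nt_boundary(self, annotation):
        # single-point CAGE peak at 150; candidate 5' end at 100 -> 50 nt
        cage = {"chr1": IntervalTree.from_tuples([(150, 151)])}
        polya = {"chr1": IntervalTree.from_tuples([(1990, 2010)])}
        sr = {("chr1", 200, 300), ("chr1", 400, 700)}
        at_50 = self.make_candidate(annotation, span=(100, 2000))
        assert validate(at_50, sr, cage, polya, annotation)["tss_ok"] is True
        at_51 = self.make_candidate(annotation, span=(99, 2000))
        assert validate(at_51, sr, cage, polya, annotation)["tss_ok"] is False

    def test_polya_boundary(self, annotation):
        cage = {"chr1": IntervalTree.from_tuples([(60, 140)])}
        sr = {("chr1", 200, 300), ("chr1", 400, 700)}
        # single-point polyA site at 2050; 3' end 2000 -> exactly 50 nt
        polya = {"chr1": IntervalTree.from_tuples([(2050, 2051)])}
        ok = self.make_candidate(annotation, span=(100, 2000))
        assert validate(ok, sr, cage, polya, annotation)["polya_ok"] is True
        polya_far = {"chr1": IntervalTree.from_tuples([(2051, 2052)])}
        assert validate(ok, sr, cage, polya_far, annotation)["polya_ok"] is False

    def test_junctions_known_in_annotation_pass_without_short_read_support(self, annotation):
        c = self.make_candidate(annotation, junctions=((200, 300),), span=(100, 400))
        v = validate(c, set(), {"chr1": IntervalTree()}, {"chr1": IntervalTree()}, annotation)
        assert v["junctions_ok"] is True

    def test_unsupported_junction_fails(self, annotation):
        c = self.make_candidate(annotation)
        v = validate(c, set(), None, None, annotation)
        assert v["junctions_ok"] is False  # (400,700) neither annotated nor confirmed

    def test_missing_track_holds_candidate(self, annotation):
        c = self.make_candidate(annotation)
        v = validate(c, {("chr1", 400, 700)}, None, None, annotation)
        assert v["tss_ok"] is None and v["polya_ok"] is None
        assert c.passes is False

    def test_filters_are_independent_conjunction(self, annotation):
        cage = {"chr1": IntervalTree.from_tuples([(90, 110)])}
        polya = {"chr1": IntervalTree.from_tuples([(1990, 2010)])}
        sr = {("chr1", 400, 700)}
        c = self.make_candidate(annotation)
        v1 = dict(validate(c, sr, cage, polya, annotation))
        # recompute in a different order (fresh candidate): flags identical
        c2 = self.make_candidate(annotation)
        validate(c2, None, cage, polya, annotation)
        v2 = dict(validate(c2, sr, cage, polya, annotation))
        assert v1 == v2
        assert c.passes == all(v1.values())


class TestEngineeredFixture:
    def test_exact_pass_counts(self, annotation):
        """10 engineered candidate groups with known per-filter fates."""
        cage = {"chr1": IntervalTree.from_tuples([(150, 151)])}   # TSS ok in [100, 200]
        polya = {"chr1": IntervalTree.from_tuples([(2050, 2051)])}  # 3' ok in [2000, 2100]
        supported = {700, 715, 720, 725, 730, 745}
        sr = {("chr1", 400, a) for a in supported}
        # each group has a unique junction chain; spans set the end-filter fate
        fates = [  # (n_umis, junctions, span, expect_pass)
            (5, ((200, 300), (400, 700)), (100, 2000), True),
            (4, ((200, 300), (400, 705)), (100, 2000), False),  # < 5 UMIs
            (5, ((200, 300), (400, 710)), (100, 2000), False),  # junction unsupported
            (5, ((200, 300), (400, 715)), (99, 2000), False),   # TSS 51 nt away
            (5, ((200, 300), (400, 720)), (100, 2101), False),  # polyA 51 nt away
            (6, ((200, 300), (400, 725)), (200, 2000), True),   # TSS exactly 50
            (5, ((200, 300), (400, 730)), (100, 2100), True),   # polyA exactly 50
            (2, ((200, 300), (400, 735)), (100, 2000), False),  # < 5 UMIs
            (5, ((200, 300), (400, 740)), (100, 2000), False),  # junction unsupported
            (7, ((200, 300), (400, 745), (800, 900)), (100, 2000), False),  # extra bad junction
        ]
        mols = []
        for gi, (n, junc, span, _) in enumerate(fates):
            for i in range(n):
                mols.append((f"g{gi}m{i}", "G", struct(junc, span=span)))
        cands = collapse(mols, annotation)
        n_pass = 0
        for c in cands:
            classify(c, annotation)
            validate(c, sr, cage, polya, annotation)
            n_pass += c.passes
        expected_kept = sum(1 for n, _, _, _ in fates if n >= 5)
        assert len(cands) == expected_kept
        assert n_pass == sum(1 for f in fates if f[3])

    def test_passing_candidates_remain_novel(self, annotation):
        mols = [(f"m{i}", "G", struct(((200, 300), (400, 700)))) for i in range(5)]
        cands = collapse(mols, annotation)
        for c in cands:
            assert c.structure.junctions not in annotation["G"].chains if isinstance(annotation, dict) else True


class TestExportGtf:
    def test_roundtrip(self, tmp_path, annotation):
        c = NovelCandidate("G", struct(((200, 300), (400, 700))), {"a", "b", "c", "d", "e"})
        classify(c, annotation)
        p = str(tmp_path / "novel.gtf")
        export_gtf([c], p)
        models = load_annotation(p)
        assert len(models) == 1
        assert models[0].structure.junctions == ((200, 300), (400, 700))

    def test_empty_list_header_only(self, tmp_path):
        p = str(tmp_path / "novel.gtf")
        export_gtf([], p)
        content = open(p).read()
        assert content.startswith("#") and "exon" not in content
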