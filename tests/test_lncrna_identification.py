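"""Class codes, the ORF finder, the filter cascade and feature statistics."""

import numpy as np
import pytest

from lncforge.annotation_io import IntervalSet, TranscriptModel
from lncforge.lncrna_identification import (
    CATEGORY_OF_CODE,
    FilterConfig,
    apply_filter_cascade,
    assign_class_code,
    find_max_orf,
    transcript_features,
)

# ---------------------------------------------------------------------------
# independent brute-force ORF oracle
# ---------------------------------------------------------------------------

def brute_force_orf(seq: str) -> tuple[int, int | None]:
    stops = {"TAA", "TAG", "TGA"}
    best = (0, None)
    for start in range(len(seq) - 2):
        if seq[start:start + 3] != "ATG":
            continue
        i = start
        while i + 3 <= len(seq):
            if seq[i:i + 3] in stops:
                aa = (i - start) // 3
                # first ATG of the span wins; later ATGs of the same span are shorter
                if aa > best[0]:
                    best = (aa, start)
                break
            i += 3
    return best


def _t(tid, exons, strand="+", scaffold="chr1", **attrs):
    return TranscriptModel(tid, tid, scaffold, strand, exons, attributes=attrs)


class TestFindMaxOrf:
    @pytest.mark.parametrize("seq,expected", [
        ("ATGAAATAA", (2, 0, 0)),
        ("ATGAAAAAA", (0, None, None)),   # open ORF: not counted
        ("CCATGAAATAACC", (2, 2, 2)),
        ("", (0, None, None)),
        ("ATGTAA", (1, 0, 0)),
    ])
    def test_hand_cases(self, seq, expected):
        assert find_max_orf(seq) == expected

    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(200):
            n = int(rng.integers(10, 400))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            aa, start, frame = find_max_orf(seq)
            baa, bstart = brute_force_orf(seq)
            assert aa == baa
            if aa > 0:
                assert start == bstart and frame == start % 3


class TestAssignClassCode:
    # r1: + strand, exons (100,250) and (900,1100), intron (250,900)
    # r2: - strand, exons (2000,2200) and (2500,2700), intron (2200,2500)
    reference = [
        _t("ref1", ((100, 250), (900, 1100))),
        _t("ref2", ((2000, 2200), (2500, 2700)), strand="-"),
    ]

    @pytest.mark.parametrize("exons,strand,expected", [
        (((100, 200), (220, 260)), "+", "sense_exonic"),   # same-strand exon overlap
        (((100, 200), (220, 260)), "-", "x"),              # antisense exon overlap
        (((240, 320), (330, 360)), "+", "sense_exonic"),   # touches exon edge in sense
        (((400, 500), (600, 700)), "+", "i"),              # inside intron, same strand
        (((400, 500), (600, 700)), "-", "i"),              # inside intron, antisense
        (((260, 290), (2250, 2300)), "+", "u"),            # two introns of two genes
        (((5000, 5100), (5200, 5300)), "+", "u"),          # intergenic
        (((2100, 2150), (2550, 2650)), "+", "x"),          # antisense to minus-strand gene
        (((2100, 2150), (2550, 2650)), "-", "sense_exonic"),
        (((2250, 2300), (2350, 2450)), "-", "i"),          # inside minus-strand intron
        (((250, 300), (700, 900)), "+", "i"),              # exactly fills the intron
        (((90, 120), (260, 280)), "-", "x"),               # partial antisense overlap at 5' end
        (((950, 1050), (1200, 1300)), "+", "sense_exonic"),
        (((1150, 1250), (1300, 1400)), "+", "u"),          # downstream of the gene
    ])
    def test_geometric_fixtures(self, exons, strand, expected):
        t = _t("q", exons, strand=strand)
        assert assign_class_code(t, self.reference) == expected

    def test_gene_free_scaffold_is_intergenic(self):
        t = _t("q", ((0, 100), (200, 300)), scaffold="chr9")
        assert assign_class_code(t, self.reference) == "u"


class TestCascade:
    def test_planted_casualties_and_survivors(self, dataset, scorer, cascade_result):
        records, report = cascade_result
        truth = dataset.truth
        stage_of = {1: "sense_exonic", 2: "basic_filters", 3: "orf_length",
                    4: "coding_potential", 5: "homology", 6: "scaffold_end"}
        decoys = truth[truth["role"] == "decoy"]
        for tid, row in decoys.iterrows():
            assert report.casualty_stage.get(tid) == stage_of[row["decoy_stage"]], tid
        by_id = {r.transcript.transcript_id: r for r in records}
        clean = truth[truth["role"].isin(["lincRNA", "ilncRNA", "lncNAT"])]
        recovered = sum(1 for tid, row in clean.iterrows()
                        if tid in by_id and by_id[tid].category == row["role"])
        assert recovered >= 0.95 * len(clean)

    def test_report_telescopes_and_partitions(self, dataset, cascade_result):
        records, report = cascade_result
        frame = report.to_frame()
        for k in range(len(frame) - 1):
            assert frame.loc[k, "retained_n"] == frame.loc[k + 1, "input_n"]
        n_candidates = frame.loc[0, "input_n"]
        assert len(records) + len(report.casualty_stage) == n_candidates

    def test_category_mapping_is_a_bijection(self, cascade_result):
        records, _ = cascade_result
        for r in records:
            assert r.category == CATEGORY_OF_CODE[r.class_code]
            assert r.max_orf_aa <= 100

    def test_short_transcript_fails_basic_filters(self, scorer):
        genome = {"chr1": "ACGTT" * 2000}
        cand = _t("short", ((3000, 3075), (3200, 3275)), coverage=5.0, fpkm=2.0)
        records, report = apply_filter_cascade(
            [cand], [], genome, FilterConfig(), scorer=None,
            scaffolds={"chr1": 10000})
        assert records == [] and report.casualty_stage["short"] == "basic_filters"

    def test_missing_fpkm_names_transcript(self):
        genome = {"chr1": "ACGT" * 2500}
        cand = _t("t_nofpkm", ((3000, 3300), (3500, 3800)), coverage=5.0)
        with pytest.raises(ValueError, match="t_nofpkm"):
            apply_filter_cascade([cand], [], genome, FilterConfig())

    def test_missing_scaffold_length_is_an_error(self):
        genome = {"chr1": "ACGT" * 2500}
        cand = _t("t1", ((3000, 3300), (3500, 3800)), coverage=5.0, fpkm=2.0)
        with pytest.raises(KeyError, match="scaffold"):
            apply_filter_cascade([cand], [], genome, FilterConfig(),
                                 scaffolds={"chr2": 10000})

    def test_external_score_alone_can_kill(self, dataset, scorer):
        import pandas as pd

        truth = dataset.truth
        clean = [tid for tid, row in truth.iterrows() if row["role"] == "lincRNA"][:1]
        external = pd.DataFrame({"cpc": [1.0]}, index=clean)
        records, report = apply_filter_cascade(
            dataset.candidates, dataset.reference, dataset.genome, FilterConfig(),
            scorer=None, homology_hits=dataset.homology_hits,
            scaffolds=dataset.scaffolds, expression=dataset.fpkm.values,
            external_scores=external)
        assert report.casualty_stage[clean[0]] == "coding_potential"


class TestFeatures:
    def test_gc_and_orf_and_splice_sites(self, dataset):
        truth = dataset.truth
        lnc_ids = truth.index[truth["role"] == "lincRNA"][:10]
        models = [dataset.transcripts_by_id()[tid] for tid in lnc_ids]
        feats = transcript_features(models, dataset.genome)
        assert ((feats["gc_fraction"] >= 0) & (feats["gc_fraction"] <= 1)).all()
        assert (feats["max_orf_nt"] <= 300).all()
        # intergenic transcripts were planted with canonical GT/AG introns
        assert (feats["canonical_splice_fraction"] == 1.0).all()

    def test_repeat_overlap_fraction(self):
        genome = {"chr1": "ACGT" * 100}
        t = _t("t1", ((0, 10), (20, 30)))
        repeats = IntervalSet()
        repeats.add("chr1", 5, 25, None, "LINE")
        feats = transcript_features([t], genome, repeats)
        assert feats.loc["t1", "repeat_fraction"] == pytest.approx(0.5)
        empty = transcript_features([t], genome, IntervalSet())
        assert empty.loc["t1", "repeat_fraction"] == 0.0

    def test_minus_strand_splice_dinucleotides(self):
        # genomic intron "CT..AC" reads GT..AG on the minus strand
        seq = "AAAA" + "CTGGAC" + "TTTT" + ("A" * 20)
        genome = {"chr1": seq}
        t = _t("t1", ((0, 4), (10, 14)), strand="-")
        feats = transcript_features([t], genome)
        assert feats.loc["t1", "splice_sites"] == "GT-AG"
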