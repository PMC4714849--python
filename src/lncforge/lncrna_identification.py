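"""The lncRNA identification cascade and transcript feature statistics.

Candidates from the merged consensus set pass through seven ordered stages:

1. remove transcripts overlapping a coding exon in the sense orientation;
2. remove short (< 200 nt), single-exon, low-coverage (< 0.8) or
   low-expression (FPKM < 0.1, maximum across tissues) transcripts;
3. remove transcripts with a predicted ORF longer than 100 aa;
4. remove transcripts called coding by the coding-potential scorer
   (probability > 0.345) or by any supplied external scorer column (> 0);
5. remove transcripts with a protein/domain homology hit at E-value < 1e-6
   in a precomputed hit table;
6. remove transcripts within 2 kb of a scaffold end (assembly-truncation risk);
7. classify the survivors by class code: i -> ilncRNA, u -> lincRNA,
   x -> lncNAT.

Stages 2-6 are pure per-transcript predicates, so the surviving set does not
depend on their order; stage attribution follows the fixed order above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation_io import IntervalSet, TranscriptModel, reverse_complement, spliced_sequence
from .orf import find_max_orf  # noqa: F401  (re-exported: part of this module's surface)

__all__ = [
    "ClassCode",
    "ReferenceIndex",
    "assign_class_code",
    "find_max_orf",
    "FilterConfig",
    "FilterReport",
    "LncRNARecord",
    "apply_filter_cascade",
    "transcript_features",
    "CATEGORY_OF_CODE",
]

# class code -> lncRNA category (a bijection on the retained codes)
CATEGORY_OF_CODE = {"i": "ilncRNA", "u": "lincRNA", "x": "lncNAT"}

ClassCode = str  # one of {"sense_exonic", "i", "u", "x"}

STAGE_NAMES = (
    "sense_exonic",      # 1
    "basic_filters",     # 2: length / exon count / coverage / FPKM
    "orf_length",        # 3
    "coding_potential",  # 4
    "homology",          # 5
    "scaffold_end",      # 6
    "classification",    # 7 (classification only; removes nothing)
)


class ReferenceIndex:
    """Exon and intron interval indexes over a reference coding annotation."""

    def __init__(self, reference: list[TranscriptModel]):
        self.exons: dict[str, IntervalTree] = {}
        self.introns: dict[str, IntervalTree] = {}
        for t in reference:
            et = self.exons.setdefault(t.scaffold, IntervalTree())
            for s, e in t.exons:
                et.addi(s, e, t.strand)
            it = self.introns.setdefault(t.scaffold, IntervalTree())
            for s, e in t.introns:
                it.addi(s, e, t.strand)

    def exon_overlap_strands(self, t: TranscriptModel) -> set[str]:
        tree = self.exons.get(t.scaffold)
        if tree is None:
            return set()
        strands = set()
        for s, e in t.exons:
            for iv in tree.overlap(s, e):
                strands.add(iv.data)
        return strands

    def contained_in_intron(self, t: TranscriptModel) -> bool:
        tree = self.introns.get(t.scaffold)
        if tree is None:
            return False
        for iv in tree.overlap(t.start, t.end):
            if iv.begin <= t.start and t.end <= iv.end:
                return True
        return False


def assign_class_code(t: TranscriptModel, reference) -> ClassCode:
    """Class of ``t`` relative to the coding annotation.

    ``sense_exonic`` — >= 1 bp exonic overlap with a reference exon on the same
    strand; ``x`` — exonic overlap on the opposite strand only; ``i`` — lies
    entirely within a single intron of some reference transcript (either
    strand); ``u`` — intergenic.
    """
    index = reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference)
    strands = index.exon_overlap_strands(t)
    if t.strand in strands:
        return "sense_exonic"
    if strands:
        return "x"
    if index.contained_in_intron(t):
        return "i"
    return "u"


@dataclass
class FilterConfig:
    """Cascade thresholds; defaults are the published silkworm-study values."""

    min_length_nt: int = 200
    min_exons: int = 2
    min_coverage: float = 0.8
    min_fpkm: float = 0.1
    max_orf_aa: int = 100
    coding_prob_threshold: float = 0.345
    homology_evalue: float = 1e-6
    scaffold_end_margin_nt: int = 2000

    def __post_init__(self) -> None:
        for name in ("min_length_nt", "min_exons", "min_coverage", "min_fpkm",
                     "max_orf_aa", "coding_prob_threshold", "homology_evalue",
                     "scaffold_end_margin_nt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"FilterConfig.{name} must be positive")


@dataclass
class LncRNARecord:
    transcript: TranscriptModel
    category: str  # ilncRNA / lincRNA / lncNAT
    class_code: str
    max_orf_aa: int
    coding_probability: float
    passed_stages: tuple[str, ...] = STAGE_NAMES


@dataclass
class FilterReport:
    """Telescoping per-stage accounting: retained(k) == input(k+1)."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)
    casualty_stage: dict[str, str] = field(default_factory=dict)

    def add(self, stage: str, n_in: int, n_kept: int) -> None:
        if self.stages and self.stages[-1][2] != n_in:
            raise ValueError("stage counts do not telescope")
        self.stages.append((stage, n_in, n_kept))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "input_n", "retained_n"])


def _max_fpkm(t: TranscriptModel, expression: pd.DataFrame | None) -> float:
    if expression is not None and t.transcript_id in expression.index:
        return float(np.max(expression.loc[t.transcript_id].to_numpy()))
    if "fpkm" in t.attributes:
        return float(t.attributes["fpkm"])
    raise ValueError(f"transcript {t.transcript_id!r}: no FPKM value available")


def apply_filter_cascade(
    candidates: list[TranscriptModel],
    reference: list[TranscriptModel],
    genome,
    cfg: FilterConfig,
    scorer=None,
    homology_hits: pd.DataFrame | None = None,
    scaffolds: dict[str, int] | None = None,
    expression: pd.DataFrame | None = None,
    external_scores: pd.DataFrame | None = None,
) -> tuple[list[LncRNARecord], FilterReport]:
    """Run the seven-stage cascade; see the module docstring for the stages.

    ``expression`` is a transcripts x samples FPKM table (the maximum entry per
    transcript feeds the stage-2 filter); ``homology_hits`` needs columns
    ``query_id`` and ``evalue``; ``external_scores`` is indexed by transcript id
    with one column per external scorer (positive = called coding).
    ``scorer`` is an object with ``score(seq) -> CodingPotentialScore`` or
    ``None`` to skip the internal coding-potential call.
    """
    index = ReferenceIndex(reference)
    report = FilterReport()

    hit_queries: dict[str, float] = {}
    if homology_hits is not None and len(homology_hits):
        best = homology_hits.groupby("query_id")["evalue"].min()
        hit_queries = best.to_dict()

    survivors = list(candidates)

    # stage 1: sense-exonic overlap
    n_in = len(survivors)
    class_codes = {t.transcript_id: assign_class_code(t, index) for t in survivors}
    nxt = []
    for t in survivors:
        if class_codes[t.transcript_id] == "sense_exonic":
            report.casualty_stage[t.transcript_id] = "sense_exonic"
        else:
            nxt.append(t)
    survivors = nxt
    report.add("sense_exonic", n_in, len(survivors))

    # stage 2: length / exon count / coverage / FPKM
    n_in = len(survivors)
    nxt = []
    for t in survivors:
        fpkm = _max_fpkm(t, expression)
        coverage = t.attributes.get("coverage")
        if coverage is None:
            raise ValueError(f"transcript {t.transcript_id!r}: no read-coverage value available")
        if (t.spliced_length < cfg.min_length_nt or t.n_exons < cfg.min_exons
                or float(coverage) < cfg.min_coverage or fpkm < cfg.min_fpkm):
            report.casualty_stage[t.transcript_id] = "basic_filters"
        else:
            nxt.append(t)
    survivors = nxt
    report.add("basic_filters", n_in, len(survivors))

    # stage 3: ORF length
    n_in = len(survivors)
    seqs = {t.transcript_id: spliced_sequence(t, genome) for t in survivors}
    orf_aa = {tid: find_max_orf(s)[0] for tid, s in seqs.items()}
    nxt = []
    for t in survivors:
        if orf_aa[t.transcript_id] > cfg.max_orf_aa:
            report.casualty_stage[t.transcript_id] = "orf_length"
        else:
            nxt.append(t)
    survivors = nxt
    report.add("orf_length", n_in, len(survivors))

    # stage 4: coding potential (internal scorer OR any external score > 0)
    n_in = len(survivors)
    probs: dict[str, float] = {}
    nxt = []
    for t in survivors:
        prob = 0.0
        if scorer is not None:
            prob = scorer.score(seqs[t.transcript_id]).coding_probability
        probs[t.transcript_id] = prob
        external_coding = False
        if external_scores is not None and t.transcript_id in external_scores.index:
            external_coding = bool((external_scores.loc[t.transcript_id] > 0).any())
        if prob > cfg.coding_prob_threshold or external_coding:
            report.casualty_stage[t.transcript_id] = "coding_potential"
        else:
            nxt.append(t)
    survivors = nxt
    report.add("coding_potential", n_in, len(survivors))

    # stage 5: homology hits
    n_in = len(survivors)
    nxt = []
    for t in survivors:
        if hit_queries.get(t.transcript_id, float("inf")) < cfg.homology_evalue:
            report.casualty_stage[t.transcript_id] = "homology"
        else:
            nxt.append(t)
    survivors = nxt
    report.add("homology", n_in, len(survivors))

    # stage 6: scaffold-end margin
    n_in = len(survivors)
    nxt = []
    for t in survivors:
        if scaffolds is None:
            nxt.append(t)
            continue
        if t.scaffold not in scaffolds:
            raise KeyError(f"transcript {t.transcript_id!r}: scaffold {t.scaffold!r} "
                           "missing from scaffold-length table")
        length = scaffolds[t.scaffold]
        if t.start < cfg.scaffold_end_margin_nt or length - t.end < cfg.scaffold_end_margin_nt:
            report.casualty_stage[t.transcript_id] = "scaffold_end"
        else:
            nxt.append(t)
    survivors = nxt
    report.add("scaffold_end", n_in, len(survivors))

    # stage 7: retain class codes i/u/x and attach categories
    n_in = len(survivors)
    records = []
    for t in survivors:
        code = class_codes[t.transcript_id]
        records.append(LncRNARecord(
            transcript=t.with_attributes(class_code=code,
                                         category=CATEGORY_OF_CODE[code]),
            category=CATEGORY_OF_CODE[code],
            class_code=code,
            max_orf_aa=orf_aa[t.transcript_id],
            coding_probability=probs.get(t.transcript_id, 0.0),
        ))
    report.add("classification", n_in, len(records))
    return records, report


# ---------------------------------------------------------------------------
# Descriptive feature statistics
# ---------------------------------------------------------------------------

def _repeat_fraction(t: TranscriptModel, repeats: IntervalSet | None) -> float:
    if repeats is None:
        return 0.0
    covered = 0
    for s, e in t.exons:
        tree = IntervalTree()
        for rs, re_, _strand, _name in repeats.overlaps(t.scaffold, s, e):
            tree.addi(max(rs, s), min(re_, e))
        tree.merge_overlaps()
        covered += sum(iv.end - iv.begin for iv in tree)
    return covered / t.spliced_length


def _splice_dinucleotides(t: TranscriptModel, genome) -> list[tuple[str, str]]:
    """(donor, acceptor) per intron, in transcript orientation."""
    seq = genome[t.scaffold]
    pairs = []
    introns = t.introns if t.strand == "+" else tuple(reversed(t.introns))
    for s, e in introns:
        if t.strand == "+":
            pairs.append((seq[s : s + 2], seq[e - 2 : e]))
        else:
            pairs.append((reverse_complement(seq[e - 2 : e]), reverse_complement(seq[s : s + 2])))
    return pairs


def transcript_features(transcripts, genome, repeats: IntervalSet | None = None) -> pd.DataFrame:
    """Per-transcript descriptive features (the basis of the genomic-feature
    statistics: lengths, exon/intron sizes, isoforms per locus, max ORF, GC,
    repeat overlap, splice-site dinucleotides)."""
    models = [r.transcript if isinstance(r, LncRNARecord) else r for r in transcripts]
    columns = ["locus_id", "spliced_length", "n_exons", "exon_lengths",
               "intron_lengths", "isoforms_per_locus", "max_orf_nt", "gc_fraction",
               "repeat_fraction", "splice_sites", "canonical_splice_fraction"]
    if not models:
        return pd.DataFrame(columns=columns,
                            index=pd.Index([], name="transcript_id"))
    isoforms_per_locus: dict[str, int] = {}
    for t in models:
        isoforms_per_locus[t.locus_id] = isoforms_per_locus.get(t.locus_id, 0) + 1
    rows = []
    for t in models:
        seq = spliced_sequence(t, genome)
        aa, _s, _f = find_max_orf(seq)
        acgt = sum(seq.count(b) for b in "ACGT")
        gc = (seq.count("G") + seq.count("C")) / acgt if acgt else 0.0
        sites = _splice_dinucleotides(t, genome)
        canonical = sum(1 for d, a in sites if d == "GT" and a == "AG")
        rows.append({
            "transcript_id": t.transcript_id,
            "locus_id": t.locus_id,
            "spliced_length": t.spliced_length,
            "n_exons": t.n_exons,
            "exon_lengths": ",".join(str(e - s) for s, e in t.exons),
            "intron_lengths": ",".join(str(e - s) for s, e in t.introns),
            "isoforms_per_locus": isoforms_per_locus[t.locus_id],
            "max_orf_nt": 3 * aa,
            "gc_fraction": gc,
            "repeat_fraction": _repeat_fraction(t, repeats),
            "splice_sites": ",".join(f"{d}-{a}" for d, a in sites),
            "canonical_splice_fraction": canonical / len(sites) if sites else float("nan"),
        })
    return pd.DataFrame(rows).set_index("transcript_id")
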